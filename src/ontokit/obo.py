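"""Reading and writing ontologies in the OBO 1.2 flat-file format.

Only the tags the downstream index consumes are retained: ``id``, ``name``,
``alt_id``, ``is_a``, ``relationship``, ``is_obsolete`` and ``replaced_by``.
Everything else (``def``, ``xref``, ``synonym``, ...) is discarded on read,
and non-``[Term]`` stanzas (``[Typedef]`` etc.) are skipped and counted.

Trailing OBO comments are introduced by ``" ! "`` (space, bang, space); the
split happens on the first such occurrence only, so names containing a bare
``!`` survive intact.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .errors import OboParseError

__all__ = ["OboTerm", "OboDocument", "parse_obo", "write_obo", "read_obo_file"]


@dataclass
class OboTerm:
    """One ``[Term]`` stanza.

    ``is_a_parents`` holds plain is-a parents; ``relationships`` holds
    ``(relation_type, target_id)`` pairs for every ``relationship:`` tag.
    Relationship edges are inert until the index is told to propagate
    that relation type.
    """

    id: str
    name: str = ""
    is_a_parents: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)
    is_obsolete: bool = False
    replaced_by: str | None = None


@dataclass
class OboDocument:
    """A parsed OBO file: header tag/value pairs plus ordered terms."""

    header: list[tuple[str, str]] = field(default_factory=list)
    terms: list[OboTerm] = field(default_factory=list)
    #: number of non-[Term] stanzas skipped during parsing
    n_skipped_stanzas: int = 0

    def __eq__(self, other: object) -> bool:  # stanza-count bookkeeping excluded
        if not isinstance(other, OboDocument):
            return NotImplemented
        return self.header == other.header and self.terms == other.terms


def _strip_comment(value: str) -> str:
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    return value.rstrip()


def _split_tag(line: str, lineno: int) -> tuple[str, str]:
    tag, sep, value = line.partition(":")
    if not sep:
        raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
    return tag.strip(), _strip_comment(value.strip())


def parse_obo(source: str | TextIO | Iterable[str]) -> OboDocument:
    """Parse OBO 1.2 text into an :class:`OboDocument`.

    Parameters
    ----------
    source
        A string of OBO text, an open text file, or any iterable of lines.
        Windows and Unix line endings are both accepted.

    Raises
    ------
    OboParseError
        On a ``[Term]`` stanza lacking an ``id:`` tag, on a duplicate
        primary id, or on an ``alt_id`` colliding with a primary id.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    doc = OboDocument()
    seen_ids: set[str] = set()

    in_header = True
    stanza_kind: str | None = None  # None until the first stanza header
    stanza_start = 0
    current: OboTerm | None = None

    def finish_term(term: OboTerm | None, start_line: int) -> None:
        if term is None:
            return
        if not term.id:
            raise OboParseError(f"[Term] stanza starting at line {start_line} has no id: tag")
        if term.id in seen_ids:
            raise OboParseError(
                f"duplicate term id {term.id!r} in stanza starting at line {start_line}"
            )
        if term.replaced_by is not None and not term.is_obsolete:
            warnings.warn(
                f"term {term.id!r} has replaced_by but is not obsolete",
                stacklevel=3,
            )
        seen_ids.add(term.id)
        doc.terms.append(term)

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n").rstrip()
        if line.startswith("[") and line.endswith("]"):
            finish_term(current, stanza_start)
            current = None
            in_header = False
            stanza_kind = line[1:-1]
            stanza_start = lineno
            if stanza_kind == "Term":
                current = OboTerm(id="")
            else:
                doc.n_skipped_stanzas += 1
            continue
        if not line:
            continue
        if in_header:
            tag, value = _split_tag(line, lineno)
            doc.header.append((tag, value))
            continue
        if stanza_kind != "Term":
            continue  # body of a skipped stanza
        assert current is not None
        tag, value = _split_tag(line, lineno)
        if tag == "id":
            current.id = value
        elif tag == "name":
            current.name = value
        elif tag == "is_a":
            if value not in current.is_a_parents:
                current.is_a_parents.append(value)
        elif tag == "relationship":
            parts = value.split(None, 1)
            if len(parts) != 2:
                raise OboParseError(
                    f"line {lineno}: relationship needs 'type target', got {value!r}"
                )
            current.relationships.append((parts[0], parts[1]))
        elif tag == "alt_id":
            if value not in current.alt_ids:
                current.alt_ids.append(value)
        elif tag == "is_obsolete":
            current.is_obsolete = value.lower() == "true"
        elif tag == "replaced_by":
            current.replaced_by = value
        # unknown tags within [Term] stanzas are ignored

    finish_term(current, stanza_start)

    primary = {t.id for t in doc.terms}
    for term in doc.terms:
        for alt in term.alt_ids:
            if alt in primary:
                raise OboParseError(
                    f"alt_id {alt!r} of term {term.id!r} collides with a primary id"
                )
    return doc


def write_obo(doc: OboDocument) -> str:
    """Serialize an :class:`OboDocument` back to OBO text.

    Tag order within a stanza is fixed (id, name, alt_id*, is_a*,
    relationship*, is_obsolete, replaced_by) so serialization is
    deterministic and ``parse_obo(write_obo(doc)) == doc``.
    """
    out: list[str] = []
    for tag, value in doc.header:
        out.append(f"{tag}: {value}")
    for term in doc.terms:
        out.append("")
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.name:
            out.append(f"name: {term.name}")
        for alt in term.alt_ids:
            out.append(f"alt_id: {alt}")
        for parent in term.is_a_parents:
            out.append(f"is_a: {parent}")
        for rel_type, target in term.relationships:
            out.append(f"relationship: {rel_type} {target}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        if term.replaced_by is not None:
            out.append(f"replaced_by: {term.replaced_by}")
    return "\n".join(out) + "\n"


def read_obo_file(path: str) -> OboDocument:
    """Parse the OBO file at *path* (UTF-8)."""
    with open(path, encoding="utf-8") as handle:
        return parse_obo(handle)
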