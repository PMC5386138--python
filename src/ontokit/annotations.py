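"""Object-to-term annotation tables, ancestor propagation and information content.

An annotation corpus is a mapping from object IDs (genes, patients, ...) to
sets of ontology term IDs.  Propagation closes every object's term set under
ancestors (the true-path rule), after which a term's annotation frequency is
the fraction of objects carrying it, and its information content is

    IC(t) = -ln(n_t / N)

in nats, where ``n_t`` is the propagated count and ``N`` the number of
objects in the corpus.  Terms never used (propagated count zero) have no IC;
asking for one raises :class:`~ontokit.errors.NoFrequencyError`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

from .errors import AnnotationParseError, EmptyCorpusError, NoFrequencyError
from .index import OntologyIndex

__all__ = [
    "AnnotationTable",
    "ICTable",
    "read_annotations",
    "propagate",
    "information_content",
    "write_annotations",
    "write_ic",
]


@dataclass
class AnnotationTable:
    """Ordered mapping from object IDs to term-ID sets."""

    objects: list[str]
    terms_of: dict[str, set[str]]
    propagated: bool = False
    #: rows dropped on read because their term could not be resolved
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.objects)


@dataclass(frozen=True)
class ICTable:
    """Per-term information content (nats) from a propagated corpus."""

    ic: Mapping[str, float]
    counts: Mapping[str, int]
    n_objects: int

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise NoFrequencyError(term_id) from None

    def get(self, term_id: str, default: float | None = None) -> float | None:
        return self.ic.get(term_id, default)


def read_annotations(
    source: str | TextIO | Iterable[str], index: OntologyIndex
) -> AnnotationTable:
    """Read a two-column TSV (``object<TAB>term``) into an annotation table.

    Repeated object IDs accumulate terms.  Term IDs are resolved through the
    index (alternate IDs and replaced_by included); rows whose term cannot
    be resolved are dropped, counted in ``n_dropped`` and summarized in a
    single warning.  Lines starting with ``#`` are comments.

    Raises
    ------
    AnnotationParseError
        On a row that does not have exactly two tab-separated columns.
    """
    if isinstance(source, str):
        source = source.splitlines()
    objects: list[str] = []
    terms_of: dict[str, set[str]] = {}
    dropped = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise AnnotationParseError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(cols)}"
            )
        obj, term = cols[0].strip(), cols[1].strip()
        if obj not in terms_of:
            objects.append(obj)
            terms_of[obj] = set()
        if term in index:
            terms_of[obj].add(index.resolve(term))
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} annotation row(s) with unresolvable terms")
    return AnnotationTable(objects=objects, terms_of=terms_of, n_dropped=dropped)


def propagate(index: OntologyIndex, table: AnnotationTable) -> AnnotationTable:
    """Close every object's term set under ancestors.

    Idempotent: propagating an already-propagated table returns an equal
    table.  Objects with empty term sets stay empty.
    """
    new_terms: dict[str, set[str]] = {}
    for obj in table.objects:
        acc: set[str] = set()
        for t in table.terms_of[obj]:
            acc |= index.ancestors_of[t]
        new_terms[obj] = acc
    return replace(table, terms_of=new_terms, propagated=True)


def information_content(index: OntologyIndex, table: AnnotationTable) -> ICTable:
    """Compute per-term information content from annotation frequency.

    The table is propagated internally if it is not already.  Terms with a
    propagated count of zero are absent from the result.

    Raises
    ------
    EmptyCorpusError
        If the table has no objects.
    """
    if len(table) == 0:
        raise EmptyCorpusError("cannot compute information content of an empty corpus")
    if not table.propagated:
        table = propagate(index, table)
    n = len(table)
    counts: dict[str, int] = {}
    for obj in table.objects:
        for t in table.terms_of[obj]:
            counts[t] = counts.get(t, 0) + 1
    # "+ 0.0" normalizes the -0.0 that -log(1) would otherwise produce
    ic = {t: -math.log(c / n) + 0.0 for t, c in counts.items()}
    return ICTable(ic=ic, counts=counts, n_objects=n)


def write_annotations(table: AnnotationTable) -> str:
    """Serialize a table to the two-column TSV format (terms sorted per object)."""
    lines = []
    for obj in table.objects:
        for t in sorted(table.terms_of[obj]):
            lines.append(f"{obj}\t{t}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_ic(ictable: ICTable) -> str:
    """Serialize an IC table as ``term<TAB>count<TAB>ic`` (6 decimal places)."""
    lines = [
        f"{t}\t{ictable.counts[t]}\t{ictable.ic[t]:.6f}" for t in sorted(ictable.ic)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
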