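"""The indexed ontology: precomputed closures and structure-aware set ops.

The index is built once from a parsed document and is immutable thereafter.
Ancestor and descendant sets follow the *reflexive* convention — every term
is its own ancestor and descendant.  This is what makes the three set
operations below compose cleanly:

* ``minimal_set`` maps a term set onto its non-redundant antichain,
* ``exclude_descendants(A, B)`` removes ``B`` and everything below it from
  ``A``,
* ``prune_descendants(A, B)`` additionally keeps members of ``B`` that sit
  above something in ``A``.

Obsolete terms carry no edges; querying one resolves through its
``replaced_by`` target when present and raises otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping

from .errors import CycleError, DanglingReferenceError, ObsoleteTermError, UnknownTermError
from .obo import OboDocument

__all__ = [
    "OntologyIndex",
    "build_index",
    "ancestors",
    "descendants",
    "minimal_set",
    "exclude_descendants",
    "prune_descendants",
    "read_term_list",
]


@dataclass(frozen=True)
class OntologyIndex:
    """Immutable indexed DAG over non-obsolete terms.

    ``parents``/``children`` are mutually inverse adjacency maps;
    ``ancestors_of``/``descendants_of`` are reflexive-transitive closures
    precomputed at build time so repeated queries are dictionary lookups.
    """

    terms: tuple[str, ...]
    names: Mapping[str, str]
    parents: Mapping[str, frozenset[str]]
    children: Mapping[str, frozenset[str]]
    ancestors_of: Mapping[str, frozenset[str]]
    descendants_of: Mapping[str, frozenset[str]]
    alt_id_map: Mapping[str, str]
    obsolete: frozenset[str]
    replaced_by: Mapping[str, str] = field(default_factory=dict)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents[t])

    def resolve(self, term_id: str) -> str:
        """Map *term_id* to a primary, non-obsolete term ID.

        Alternate IDs resolve to their primary term; obsolete terms resolve
        through ``replaced_by`` (transitively).  Raises
        :class:`UnknownTermError` or :class:`ObsoleteTermError`.
        """
        seen: set[str] = set()
        tid = term_id
        while True:
            if tid in self.alt_id_map:
                tid = self.alt_id_map[tid]
            if tid in self.obsolete:
                if tid in seen:  # replaced_by loop among obsolete terms
                    raise ObsoleteTermError(term_id)
                seen.add(tid)
                replacement = self.replaced_by.get(tid)
                if replacement is None:
                    raise ObsoleteTermError(term_id)
                tid = replacement
                continue
            if tid not in self.ancestors_of:
                raise UnknownTermError(term_id)
            return tid

    def resolve_all(self, term_ids: Iterable[str]) -> set[str]:
        return {self.resolve(t) for t in term_ids}

    def __contains__(self, term_id: str) -> bool:
        try:
            self.resolve(term_id)
        except (UnknownTermError, ObsoleteTermError):
            return False
        return True


def _find_cycle(parents: Mapping[str, set[str]], candidates: Collection[str]) -> list[str]:
    """Return one directed cycle among *candidates* (all on cycles or paths to them)."""
    # Walk parent edges from any unresolved node; a repeat closes a cycle.
    start = next(iter(candidates))
    path: list[str] = []
    pos: dict[str, int] = {}
    node = start
    while node not in pos:
        pos[node] = len(path)
        path.append(node)
        node = next(iter(p for p in parents[node] if p in candidates))
    return path[pos[node] :]


def build_index(
    doc: OboDocument, propagate_relations: Collection[str] = ()
) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from a parsed document.

    Parameters
    ----------
    doc
        A valid :class:`~ontokit.obo.OboDocument`.
    propagate_relations
        Relation types (e.g. ``{"part_of"}``) whose edges are treated as
        parent edges in addition to is-a.  Empty by default: the structure
        the toolkit reasons over is the is-a hierarchy unless told otherwise.

    Raises
    ------
    DanglingReferenceError
        If any parent edge targets a term not defined in the document.
    CycleError
        If the parent edges contain a directed cycle.
    """
    rel_types = set(propagate_relations)
    active = [t for t in doc.terms if not t.is_obsolete]
    defined = {t.id for t in doc.terms}
    active_ids = {t.id for t in active}
    obsolete_ids = frozenset(t.id for t in doc.terms if t.is_obsolete)

    parents: dict[str, set[str]] = {t.id: set() for t in active}
    missing: set[str] = set()
    for term in active:
        targets = list(term.is_a_parents)
        targets += [tgt for rel, tgt in term.relationships if rel in rel_types]
        for target in targets:
            if target not in defined:
                missing.add(target)
            elif target in active_ids:
                # edges to obsolete terms are dropped: obsolete terms carry no edges
                parents[term.id].add(target)
    if missing:
        raise DanglingReferenceError(sorted(missing))

    children: dict[str, set[str]] = {t: set() for t in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)

    # Kahn's algorithm: topological order with parents before children,
    # doubling as cycle detection.
    n_unmet = {t: len(parents[t]) for t in parents}
    queue = [t.id for t in active if n_unmet[t.id] == 0]
    topo: list[str] = []
    while queue:
        node = queue.pop()
        topo.append(node)
        for child in children[node]:
            n_unmet[child] -= 1
            if n_unmet[child] == 0:
                queue.append(child)
    if len(topo) != len(parents):
        stuck = {t for t, n in n_unmet.items() if n > 0}
        raise CycleError(_find_cycle(parents, stuck))

    anc: dict[str, frozenset[str]] = {}
    for node in topo:
        acc: set[str] = {node}
        for p in parents[node]:
            acc |= anc[p]
        anc[node] = frozenset(acc)
    desc: dict[str, set[str]] = {t: {t} for t in parents}
    for node in reversed(topo):
        for p in parents[node]:
            desc[p] |= desc[node]

    alt_id_map: dict[str, str] = {}
    for term in doc.terms:
        for alt in term.alt_ids:
            alt_id_map[alt] = term.id
    replaced = {
        t.id: t.replaced_by for t in doc.terms if t.is_obsolete and t.replaced_by
    }

    return OntologyIndex(
        terms=tuple(t.id for t in active),
        names={t.id: t.name for t in doc.terms},
        parents={t: frozenset(ps) for t, ps in parents.items()},
        children={t: frozenset(cs) for t, cs in children.items()},
        ancestors_of=anc,
        descendants_of={t: frozenset(ds) for t, ds in desc.items()},
        alt_id_map=alt_id_map,
        obsolete=obsolete_ids,
        replaced_by=replaced,
    )


def ancestors(index: OntologyIndex, term_id: str) -> set[str]:
    """Reflexive ancestor set of *term_id* (the term plus everything above it)."""
    return set(index.ancestors_of[index.resolve(term_id)])


def descendants(index: OntologyIndex, term_id: str) -> set[str]:
    """Reflexive descendant set of *term_id* (the term plus everything below it)."""
    return set(index.descendants_of[index.resolve(term_id)])


def minimal_set(index: OntologyIndex, terms: Iterable[str]) -> set[str]:
    """Map a term set onto its non-redundant subset.

    Drops every term that is a strict ancestor of another member, leaving
    an antichain: the most specific representatives of the input.
    """
    resolved = index.resolve_all(terms)
    return {
        t
        for t in resolved
        if not any(u != t and u in index.descendants_of[t] for u in resolved)
    }


def exclude_descendants(
    index: OntologyIndex, a: Iterable[str], b: Iterable[str]
) -> set[str]:
    """Remove terms in *b* and their descendants from *a*."""
    a_resolved = index.resolve_all(a)
    banned: set[str] = set()
    for t in index.resolve_all(b):
        banned |= index.descendants_of[t]
    return a_resolved - banned


def prune_descendants(
    index: OntologyIndex, a: Iterable[str], b: Iterable[str]
) -> set[str]:
    """Like :func:`exclude_descendants`, but keep members of *b* that are
    ancestors of something in *a*."""
    a_resolved = index.resolve_all(a)
    b_resolved = index.resolve_all(b)
    kept = {
        t for t in b_resolved if any(t in index.ancestors_of[x] for x in a_resolved)
    }
    return exclude_descendants(index, a_resolved, b_resolved) | kept


def read_term_list(source: str | Iterable[str]) -> list[str]:
    """Read a plain-text term list: one ID per line, ``#`` comments allowed."""
    if isinstance(source, str):
        source = source.splitlines()
    out: list[str] = []
    for raw in source:
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
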