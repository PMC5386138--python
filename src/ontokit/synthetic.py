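"""Seeded generators for random ontologies and annotation corpora.

These generators make every other part of the toolkit testable without
external ontology downloads.  Two emulation targets:

* :func:`random_dag` — a single-rooted random DAG serialized as a standard
  OBO document.  Term ``i`` (in topological order) draws
  ``min(1 + Poisson(mean_parents - 1), i - 1)`` parents uniformly from the
  earlier terms, so acyclicity and single-rootedness hold by construction.
* :func:`random_annotations` — objects annotated with uniformly drawn
  terms; the resulting corpus is exchangeable across objects, which is
  exactly the null the permutation test assumes.  An optional planted group
  makes its first ``size`` objects share one deep (leaf) term, providing a
  detectable signal for power checks.

Both are deterministic given their seed, and the OBO/TSV they write is
indistinguishable from real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotations import AnnotationTable
from .index import OntologyIndex
from .obo import OboDocument, OboTerm

__all__ = ["DagSpec", "PlantedGroup", "CorpusSpec", "random_dag", "random_annotations"]


@dataclass(frozen=True)
class DagSpec:
    """Shape parameters for a random single-rooted DAG."""

    n_terms: int
    mean_parents: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.mean_parents < 1.0:
            raise ValueError("mean_parents must be >= 1")


@dataclass(frozen=True)
class PlantedGroup:
    """A planted similar group: the first *size* objects share a deep term.

    When *term* is None the shared term is drawn uniformly from the
    ontology's leaves.
    """

    size: int
    term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("planted group size must be >= 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Shape parameters for a random annotation corpus."""

    n_objects: int
    terms_per_object: int = 3
    planted_group: Optional[PlantedGroup] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.terms_per_object < 1:
            raise ValueError("terms_per_object must be >= 1")


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def random_dag(spec: DagSpec) -> OboDocument:
    """Generate a random single-rooted DAG as an :class:`OboDocument`.

    Terms are ``T:0000001 .. T:<n>`` in topological order; term 1 is the
    unique root and every later term has at least one parent among the
    earlier terms.
    """
    rng = np.random.default_rng(spec.seed)
    doc = OboDocument(header=[("format-version", "1.2"), ("ontology", "synthetic")])
    for i in range(1, spec.n_terms + 1):
        term = OboTerm(id=_term_id(i), name=f"synthetic term {i}")
        if i > 1:
            k = min(1 + rng.poisson(spec.mean_parents - 1.0), i - 1)
            choices = rng.choice(i - 1, size=int(k), replace=False)
            term.is_a_parents = [_term_id(int(j) + 1) for j in sorted(choices)]
        doc.terms.append(term)
    return doc


def random_annotations(index: OntologyIndex, spec: CorpusSpec) -> AnnotationTable:
    """Generate a random (raw, unpropagated) annotation corpus over *index*.

    Each object draws ``terms_per_object`` terms uniformly with replacement
    from the non-obsolete terms and keeps the distinct ones.  With a planted
    group, its members additionally share one leaf term.
    """
    rng = np.random.default_rng(spec.seed)
    terms = list(index.terms)
    if not terms:
        raise ValueError("index has no non-obsolete terms to annotate with")

    shared: str | None = None
    if spec.planted_group is not None:
        if spec.planted_group.term is not None:
            shared = index.resolve(spec.planted_group.term)
        else:
            leaves = [t for t in terms if not index.children[t]]
            shared = leaves[int(rng.integers(len(leaves)))]

    width = max(4, len(str(spec.n_objects)))
    objects = [f"O:{i:0{width}d}" for i in range(1, spec.n_objects + 1)]
    terms_of: dict[str, set[str]] = {}
    for i, obj in enumerate(objects):
        draws = rng.integers(len(terms), size=spec.terms_per_object)
        chosen = {terms[int(d)] for d in draws}
        if shared is not None and i < spec.planted_group.size:  # type: ignore[union-attr]
            chosen.add(shared)
        terms_of[obj] = chosen
    return AnnotationTable(objects=objects, terms_of=terms_of, propagated=False)
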