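"""Semantic similarity at term, object and group level, with permutation tests.

Term level implements the two classical corpus-based measures:

* Resnik: IC of the most informative common ancestor (MICA),
  ``resnik(t1, t2) = max { IC(a) : a ∈ anc(t1) ∩ anc(t2) }``;
* Lin: ``2·resnik(t1, t2) / (IC(t1) + IC(t2))``, with the 0/0 case
  (both terms at zero IC) defined as 0.

Object (term-set) level uses the symmetric best-match average: each term is
matched to its best counterpart in the other set, averaged within each
direction, and the two directions are averaged.  Group level averages the
pairwise object similarities over all unordered pairs inside the group, and
its significance is assessed against a null of uniformly drawn same-size
groups with the add-one permutation estimator ``p = (1 + #{null ≥ obs}) /
(1 + n_permutations)``.

Four cache modes trade memory for speed without ever changing values:
``none`` recomputes everything, ``term_matrix`` precomputes the dense
term-term similarity matrix, ``set_matrix`` memoizes set-pair results, and
``lookup_index`` builds a per-set ancestor index from which best matches are
read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotations import ICTable
from .errors import (
    DegenerateGroupError,
    DegenerateNullError,
    EmptySetError,
    NoFrequencyError,
)
from .index import OntologyIndex

__all__ = [
    "METHODS",
    "CACHE_MODES",
    "SimSpec",
    "SimPResult",
    "term_similarity",
    "set_similarity",
    "pairwise_set_matrix",
    "group_similarity",
    "sim_p",
    "write_matrix",
    "write_sim_p",
]

METHODS = ("resnik", "lin")
CACHE_MODES = ("none", "term_matrix", "set_matrix", "lookup_index")


@dataclass(frozen=True)
class SimSpec:
    """Similarity method plus caching strategy."""

    method: str = "lin"
    cache_mode: str = "none"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.cache_mode not in CACHE_MODES:
            raise ValueError(
                f"cache_mode must be one of {CACHE_MODES}, got {self.cache_mode!r}"
            )


@dataclass(frozen=True)
class SimPResult:
    """Observed group similarity with its permutation p-value."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _ic_checked(ic: ICTable, term: str) -> float:
    if term not in ic:
        raise NoFrequencyError(term)
    return ic[term]


def _resnik(index: OntologyIndex, ic: ICTable, t1: str, t2: str) -> float:
    common = index.ancestors_of[t1] & index.ancestors_of[t2]
    best = 0.0
    for a in common:
        v = ic.get(a)
        if v is not None and v > best:
            best = v
    return best


def term_similarity(
    index: OntologyIndex, ic: ICTable, t1: str, t2: str, method: str = "lin"
) -> float:
    """Similarity between two terms under *method* (``resnik`` or ``lin``)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    t1, t2 = index.resolve(t1), index.resolve(t2)
    ic1, ic2 = _ic_checked(ic, t1), _ic_checked(ic, t2)
    res = _resnik(index, ic, t1, t2)
    if method == "resnik":
        return res
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0  # root-vs-root carries no information
    return 2.0 * res / denom


def _best_match(
    index: OntologyIndex, ic: ICTable, a: str, other: Iterable[str], method: str
) -> float:
    return max(term_similarity(index, ic, a, b, method) for b in other)


def set_similarity(
    index: OntologyIndex,
    ic: ICTable,
    a: Iterable[str],
    b: Iterable[str],
    method: str = "lin",
) -> float:
    """Symmetric best-match-average similarity between two term sets."""
    sa = sorted(index.resolve_all(a))
    sb = sorted(index.resolve_all(b))
    if not sa or not sb:
        raise EmptySetError("set similarity requires two non-empty term sets")
    fwd = float(np.mean([_best_match(index, ic, x, sb, method) for x in sa]))
    rev = float(np.mean([_best_match(index, ic, y, sa, method) for y in sb]))
    return 0.5 * (fwd + rev)


class _SetLookupIndex:
    """Per-set ancestor index for direct best-match reads.

    For a set ``B``, stores for every ancestor ``a`` of any ``b ∈ B`` (with
    IC) the minimum IC over the members ``b`` it subsumes.  The best Resnik
    match of a query term ``t`` against ``B`` is then the maximum IC over
    the stored ancestors of ``t``; the best Lin match is the maximum of
    ``2·IC(a) / (IC(t) + min_b IC(b))`` over the same ancestors — the pair
    achieving it is exactly the optimal (MICA, member) pair.
    """

    def __init__(self, index: OntologyIndex, ic: ICTable, members: Sequence[str]):
        self.min_member_ic: dict[str, float] = {}
        for b in members:
            icb = _ic_checked(ic, b)
            for a in index.ancestors_of[b]:
                if a in ic:
                    prev = self.min_member_ic.get(a)
                    if prev is None or icb < prev:
                        self.min_member_ic[a] = icb

    def best_match(self, index: OntologyIndex, ic: ICTable, t: str, method: str) -> float:
        ict = _ic_checked(ic, t)
        best = 0.0
        for a in index.ancestors_of[t]:
            entry = self.min_member_ic.get(a)
            if entry is None:
                continue
            ica = ic[a]
            if method == "resnik":
                cand = ica
            else:
                denom = ict + entry
                cand = 2.0 * ica / denom if denom > 0.0 else 0.0
            if cand > best:
                best = cand
        return best


def _bma_from_lookup(
    index: OntologyIndex,
    ic: ICTable,
    sa: Sequence[str],
    sb: Sequence[str],
    la: _SetLookupIndex,
    lb: _SetLookupIndex,
    method: str,
) -> float:
    fwd = float(np.mean([lb.best_match(index, ic, x, method) for x in sa]))
    rev = float(np.mean([la.best_match(index, ic, y, method) for y in sb]))
    return 0.5 * (fwd + rev)


def _bma_from_term_matrix(
    sim: np.ndarray, rows: Sequence[int], cols: Sequence[int]
) -> float:
    block = sim[np.ix_(rows, cols)]
    return 0.5 * (float(np.mean(block.max(axis=1))) + float(np.mean(block.max(axis=0))))


def pairwise_set_matrix(
    index: OntologyIndex,
    ic: ICTable,
    sets: Sequence[Iterable[str]],
    spec: SimSpec = SimSpec(),
) -> np.ndarray:
    """Symmetric matrix of set similarities; entry (i, j) = sim(sets[i], sets[j]).

    The cache mode only changes how entries are computed, never their values.
    """
    resolved = [sorted(index.resolve_all(s)) for s in sets]
    for i, s in enumerate(resolved):
        if not s:
            raise EmptySetError(f"set {i} is empty")
    n = len(resolved)
    out = np.zeros((n, n))

    if spec.cache_mode == "term_matrix":
        universe = sorted(set().union(*map(set, resolved)))
        pos = {t: k for k, t in enumerate(universe)}
        m = len(universe)
        sim = np.zeros((m, m))
        for i, t1 in enumerate(universe):
            for j in range(i, m):
                v = term_similarity(index, ic, t1, universe[j], spec.method)
                sim[i, j] = sim[j, i] = v
        idx = [[pos[t] for t in s] for s in resolved]
        for i in range(n):
            for j in range(i, n):
                out[i, j] = out[j, i] = _bma_from_term_matrix(sim, idx[i], idx[j])
        return out

    if spec.cache_mode == "lookup_index":
        lookups = [_SetLookupIndex(index, ic, s) for s in resolved]
        for i in range(n):
            for j in range(i, n):
                out[i, j] = out[j, i] = _bma_from_lookup(
                    index, ic, resolved[i], resolved[j], lookups[i], lookups[j], spec.method
                )
        return out

    memo: dict[tuple[tuple[str, ...], ...], float] = {}
    for i in range(n):
        for j in range(i, n):
            if spec.cache_mode == "set_matrix":
                # identical (unordered) set pairs share one cached value
                canon = tuple(sorted((tuple(resolved[i]), tuple(resolved[j]))))
                if canon not in memo:
                    memo[canon] = set_similarity(
                        index, ic, resolved[i], resolved[j], spec.method
                    )
                v = memo[canon]
            else:
                v = set_similarity(index, ic, resolved[i], resolved[j], spec.method)
            out[i, j] = out[j, i] = v
    return out


def group_similarity(matrix: np.ndarray, group: Sequence[int]) -> float:
    """Mean pairwise similarity over all unordered pairs inside *group*."""
    group = list(group)
    if len(group) < 2:
        raise DegenerateGroupError("group similarity needs at least 2 members")
    if len(set(group)) != len(group):
        raise ValueError("group indices must be distinct")
    n = matrix.shape[0]
    if any(i < 0 or i >= n for i in group):
        raise ValueError("group index out of range")
    # sorted indices make the float summation order, hence the statistic,
    # independent of how the group was enumerated — ties then break identically
    idx = np.sort(np.asarray(group))
    block = matrix[np.ix_(idx, idx)]
    k = len(group)
    return float((block.sum() - np.trace(block)) / (k * (k - 1)))


def sim_p(
    matrix: np.ndarray,
    group: Sequence[int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> SimPResult:
    """Permutation p-value for the within-group similarity statistic.

    Null groups are uniform random subsets of the same size drawn from the
    whole population (observed members included).  Ties count as extreme, and
    the add-one estimator keeps the p-value strictly positive.
    """
    group = list(group)
    n = matrix.shape[0]
    if len(group) >= n:
        raise DegenerateNullError(
            "group is the whole population; no null groups to draw"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = group_similarity(matrix, group)
    rng = np.random.default_rng(seed)
    k = len(group)
    n_ge = 0
    for _ in range(n_permutations):
        null_group = rng.choice(n, size=k, replace=False)
        if group_similarity(matrix, null_group) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return SimPResult(
        statistic=observed, p_value=p, n_permutations=n_permutations, seed=seed
    )


def write_matrix(matrix: np.ndarray, ids: Sequence[str]) -> str:
    """Serialize a pairwise matrix as TSV with IDs on both axes (6 dp)."""
    lines = ["\t" + "\t".join(ids)]
    for i, oid in enumerate(ids):
        lines.append(oid + "\t" + "\t".join(f"{v:.6f}" for v in matrix[i]))
    return "\n".join(lines) + "\n"


def write_sim_p(result: SimPResult) -> str:
    """Serialize a permutation-test result as a single TSV line."""
    return (
        f"{result.statistic:.6f}\t{result.p_value:.6g}"
        f"\t{result.n_permutations}\t{result.seed}\n"
    )
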