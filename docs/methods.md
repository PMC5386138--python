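# Methods

## The ontology model

An ontology is modelled as a rooted directed acyclic graph of terms joined
by is-a edges (child → parent). Other relation types (`part_of`,
`regulates`, …) are parsed and stored but inert unless the caller names
them in `build_index(..., propagate_relations={...})`, in which case their
edges join the parent relation. This keeps the default semantics to pure
subsumption, which is what every operation in the toolkit is defined over,
while letting users opt in to mixed closures.

Ancestor and descendant sets are **reflexive**: every term is its own
ancestor and descendant. This convention is load-bearing. With it,
`exclude_descendants(A, B) = A \ ⋃_{b∈B} desc(b)` removes the members of
`B` themselves as well as everything below them, `minimal_set` is "drop
every term with a strict descendant in the set", and
`prune_descendants(A, B) = exclude_descendants(A, B) ∪ {b ∈ B : b ∈
anc(a) for some a ∈ A}` — all one-liners over the precomputed closures.

Closures are precomputed once at build time in a single topological pass
(O(V · average closure size) memory). The design optimizes for the
workload these tools see in practice — thousands of repeated
ancestor/descendant queries during propagation, similarity and plotting —
at the cost of a modestly larger index. Cycle detection happens during the
same pass (Kahn's algorithm); the error names one complete cycle so the
offending OBO input can be fixed. Dangling parent references are collected
exhaustively and reported in one error rather than one at a time.

Obsolete terms are parsed and retained, but carry no edges and are
excluded from `index.terms`. A query against an obsolete term follows its
`replaced_by` chain when present and raises `ObsoleteTermError` otherwise:
silently treating an obsolete term as current would corrupt downstream
frequencies. Alternate IDs resolve to their primary term everywhere
(queries, annotation reading, plotting).

## OBO input and output

The parser retains exactly the tags the index consumes (`id`, `name`,
`alt_id`, `is_a`, `relationship`, `is_obsolete`, `replaced_by`); `def`,
`xref`, `synonym` and the rest play no role in any operation here and are
discarded. Trailing comments are stripped at the first `" ! "` (space,
bang, space) only, so term names containing a bare `!` survive. Parsing is
insensitive to line-ending style and trailing whitespace. `write_obo`
emits tags in a fixed order, making serialization byte-stable and
`parse ∘ write` the identity on the retained tag set — a property the test
suite checks on randomly generated documents.

## Information content

For a corpus of N annotated objects, each object's term set is closed
under ancestors (the true-path rule) and a term annotated to n_t ≥ 1
objects gets

    IC(t) = −ln(n_t / N)   [nats]

Conventions fixed here, since only the ratio (Lin) or the argmax (Resnik)
is consumed downstream but reproducibility demands a single definition:
the natural logarithm; the denominator is the number of objects, not
term-token counts; and zero-frequency terms get *no* IC rather than +∞ or
a pseudo-count — downstream lookups raise `NoFrequencyError` explicitly.
Propagated counts can only shrink walking down the DAG, so IC is monotone
non-decreasing from root to leaves; the suite asserts this on every
synthetic corpus.

## Semantic similarity

Term level implements the two classical corpus-based measures. Resnik
similarity is the IC of the most informative common ancestor (MICA); Lin
similarity is `2·IC(MICA) / (IC(t₁) + IC(t₂))`. The 0/0 case — both terms
at IC 0, which happens for root-level terms — is defined as 0: root-vs-root
similarity carries no information, and returning 1 would inflate every
group statistic built on top.

The object (term-set) level uses the symmetric best-match average:

    sim(A, B) = ½ · [ mean_{a∈A} max_{b∈B} s(a,b) + mean_{b∈B} max_{a∈A} s(a,b) ]

Term-level measures do not determine a set-level combination rule; the
best-match average is the convention of the surrounding ecosystem of
similarity packages, and its symmetrized form is what makes the pairwise
object matrix well-defined. Sets are used as given — adding a redundant
ancestor to a set can legitimately change the value.

The group level is the mean of pairwise object similarities over unordered
pairs. Its significance comes from a permutation null: `n_permutations`
same-size groups drawn uniformly without replacement (within a draw) from
the whole population, observed members included — the simplest
exchangeable null. The estimator is add-one,

    p = (1 + #{null ≥ observed}) / (1 + n_permutations),

which is a valid Monte-Carlo p-value and strictly positive; ties count as
extreme (conservative). The RNG is seeded and the seed recorded in the
result, so every stochastic output is reproducible bit for bit.

### Cache modes

Four modes trade memory for speed with guaranteed value equivalence
(asserted to ≤ 1e-12 in the suite): `none` recomputes everything;
`term_matrix` precomputes the dense term–term matrix over the union of
used terms; `set_matrix` memoizes results per unordered pair of term sets;
`lookup_index` builds, per set B, a map from each IC-bearing ancestor `a`
of B's members to `min {IC(b) : b ∈ B, a ∈ anc(b)}`. From that map the
best Resnik match of a query term t against B is the max of IC(a) over the
stored ancestors of t, and the best Lin match is the max of
`2·IC(a) / (IC(t) + minIC(a))` over the same ancestors — the maximizing
(ancestor, member) pair is exactly the optimal MICA/member pair, so the
lookup route is value-identical for both measures, not an approximation.
(A plain max-IC ancestor set would suffice for Resnik but cannot recover
Lin's denominator; storing the minimum member IC alongside closes that
gap.)

### Numerical determinism

`group_similarity` sorts the group indices before summing matrix entries,
so the float summation order — and therefore tie behaviour in the
permutation comparison — is independent of the order in which a group was
enumerated or drawn.

## Visualization

A plotted graph shows a chosen term set, not the whole ontology. Edges are
the transitive reduction (Hasse diagram) of the ancestor relation
*restricted to the plotted set*: scattered term sets stay connected
through their nearest in-set ancestor, where raw is-a edges would orphan
most nodes. The reduction is delegated to `networkx.transitive_reduction`;
the test suite checks it against a brute-force "remove every edge implied
by a 2-step path" oracle on random subsets.

`remove_uninformative_terms` drops a term when some child — any child in
the full ontology, plotted or not, since the criterion is about annotation
structure rather than the plotted subset — is annotated to exactly the
same objects after propagation. Such a term adds a node without separating
any objects. The alternative reading (compare against the union over all
children) would prune more aggressively; the single-child reading adopted
here is the conservative one. The table must be propagated first; passing
a raw table raises.

Styling is deterministic: node width is `min(0.3 + 0.25·IC, 2.5)` inches
(an arbitrary but fixed affine map — only monotone scaling is meaningful),
labels wrap at 20 characters, and fill colors are assigned to
membership patterns in sorted order from a fixed named-color palette, with
the all-objects pattern always light blue. DOT identifiers are sanitized
(non-alphanumeric → `_`, collisions suffixed) with the original term ID
kept in a `tooltip`; nodes and edges are emitted sorted, so serialization
is byte-stable. Layout and rasterization are left entirely to external
DOT consumers.

## Synthetic data

`random_dag(DagSpec(n_terms, mean_parents, seed))` emits terms
`T:0000001..T:n` in topological order; term i > 1 draws
`min(1 + Poisson(mean_parents − 1), i − 1)` parents uniformly from earlier
terms. Acyclicity and single-rootedness hold by construction (term 1 is
the unique root, mirroring a GO namespace or the HPO). The default
`mean_parents = 1.5` gives a mix of tree-like and diamond-like multiple
inheritance comparable to real biomedical ontologies.

`random_annotations(index, CorpusSpec(n_objects, terms_per_object,
planted_group, seed))` draws each object's terms uniformly with
replacement from the non-obsolete terms and deduplicates (default 3 per
object, a deliberately sparse corpus). Uniform sampling makes objects
exchangeable — exactly the null hypothesis of the permutation test, which
is what the calibration check requires. A planted group additionally gives
its first `size` objects one shared leaf term: a deep, high-IC signal for
power checks, chosen uniformly among leaves unless pinned explicitly.

What the generators do **not** emulate: real ontologies' fitted
depth/branching distributions, multi-rooted ontologies, leaf-biased
annotation (real curation annotates specific terms more often), annotation
evidence codes, and corpus sizes in the tens of thousands. Passing tests
therefore demonstrate correctness of the algorithms and calibration under
exchangeability at desk scale, not performance or power on a specific real
ontology.

## Problem sizes in the test suite

The suite's global checks run on 20–100 random DAGs of 25–80 terms and
corpora of 8–30 objects: closure correctness against BFS on 100 DAGs of
50 terms; 1000 random set-operation draws; 1000 random similarity pairs;
cache equivalence on a 30-object corpus; permutation exactness against
full enumeration of C(8,3) = 56 groups at 50,000 Monte-Carlo draws;
calibration of 200 replicate p-values (99 permutations each, population
30, group 5) against the discrete uniform via a Kolmogorov–Smirnov test
whose null is itself simulated from the discrete distribution; and
transitive-reduction checks on subsets of ≤ 15 nodes. These sizes keep the
whole suite in the tens of seconds while leaving each property's failure
modes (diamonds, skipped generations, ties, obsolete/alt IDs) well
covered.

## Known limitations

* OBO 1.4 constructs (`intersection_of`, `union_of`, typedef semantics)
  are ignored; OWL inputs must be converted externally.
* IC is corpus-based only; structure-based (descendant-count) IC is not
  offered.
* Jiang–Conrath, Wang and other term measures are out of scope, as are
  asymptotic approximations to the permutation p-value.
* The annotation format is a two-column TSV; GAF/GPAD must be projected
  down to object/term pairs first.
* `remove_uninformative_terms` compares each child separately (see above);
  corpora engineered so that only the union of children matches a parent's
  objects will not be pruned.
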