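# ontokit

Query, compare and draw arbitrary biomedical ontologies.

Ontological annotation — genes tagged with Gene Ontology terms, patients
described by Human Phenotype Ontology abnormalities — carries structure:
terms form a rooted directed acyclic graph of is-a relations, and an
annotation with a term implies all of its ancestors (the true-path rule).
Ignoring that structure corrupts downstream statistics and produces
cluttered figures. `ontokit` gives analysts one consistent toolset for
working with *any* ontology distributed in OBO format:

* **Indexing** — parse OBO 1.2 into an immutable index with precomputed
  reflexive ancestor/descendant closures, alternate-ID resolution and
  obsolete-term handling, so repeated queries are dictionary lookups.
* **Structure-aware set operations** — `minimal_set` (reduce a term set to
  its most specific antichain), `exclude_descendants(A, B)` (remove `B` and
  everything below it from `A`) and `prune_descendants(A, B)` (ditto, but
  keep members of `B` ancestral to `A`).
* **Information content & semantic similarity** — corpus-based
  IC(t) = −ln(n_t/N) in nats; Resnik (IC of the most informative common
  ancestor) and Lin (2·IC(MICA)/(IC(t₁)+IC(t₂))) term similarity; symmetric
  best-match-average similarity between annotated objects; mean pairwise
  similarity within groups; and a seeded permutation test
  p = (1 + #{null ≥ observed}) / (1 + n_permutations) against uniformly
  drawn same-size groups. Four cache modes (`none`, `term_matrix`,
  `set_matrix`, `lookup_index`) trade memory for speed without changing a
  single value.
* **Visualization** — subgraphs of term sets connected by the transitive
  reduction of their ancestor relation, node size scaled by IC, fill color
  by annotation membership pattern, pruned with
  `remove_uninformative_terms`, serialized to Graphviz DOT (and GraphML).
* **Synthetic data** — seeded generators for random single-rooted DAGs
  (written as standard OBO) and random annotation corpora, with an optional
  planted similar group, so everything above is testable offline.

## Worked example

The 5-term "diamond": `T:0000000` at the top, two branches `T:0000001` /
`T:0000002`, their junction `T:0000003`, and a leaf `T:0000004` below it.
Three objects are annotated: X with the junction, Y with the leaf, Z with
the left branch.

```python
import ontokit as ok

index = ok.build_index(ok.read_obo_file("diamond.obo"))
table = ok.read_annotations(open("annotations.tsv"), index)
ic = ok.information_content(index, table)

ic["T:0000004"]                                            # 1.0986122886681098
ok.term_similarity(index, ic, "T:0000003", "T:0000004", "resnik")
                                                           # 0.40546510810816444
ok.term_similarity(index, ic, "T:0000003", "T:0000004", "lin")
                                                           # 0.5391542381177845
```

The leaf is annotated (after propagation) to 1 of 3 objects, so its IC is
−ln(1/3) ≈ 1.0986 nats. The most informative common ancestor of the
junction and the leaf is the junction itself (2 of 3 objects, IC ≈ 0.4055),
which is their Resnik similarity; Lin normalizes it by the two terms' own
IC: 2·0.4055/(0.4055 + 1.0986) ≈ 0.5392.

The same analysis from the shell:

```sh
ontokit ic --obo diamond.obo --annotations annotations.tsv
ontokit sim --obo diamond.obo --annotations annotations.tsv --method lin
ontokit simp --obo diamond.obo --annotations annotations.tsv \
    --group X --group Y --n-perm 1000 --seed 1
ontokit plot --obo diamond.obo --annotations annotations.tsv \
    --remove-uninformative T:0000000 T:0000001 T:0000003 T:0000004 | dot -Tpng > fig.png
```

`ontokit plot --remove-uninformative` drops terms whose children are
annotated to exactly the same objects (here the root and the right branch),
leaving the three nodes that actually separate X, Y and Z. `ontokit fixture
dag` / `ontokit fixture corpus` write seeded synthetic OBO and annotation
files for experimentation.

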