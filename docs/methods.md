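# Methods

## Model

An ontology is a directed acyclic graph over terms; edges run from a
child term to its parents through a configurable set of traversable
relations, `{is_a, part_of}` by default (the community convention for
structural GO analyses — other relation types such as `regulates` cross
sub-ontology boundaries and are excluded). The ancestor closure
`A(t)` contains `t` and everything reachable upward; all set-level
similarity and all hierarchical evaluation operate on closures (the
true-path rule). Closure never crosses aspect boundaries, and multiple
roots per aspect are allowed.

Obsolete terms are kept in the term index but carry no edges: they are
disconnected, contribute nothing to structural metrics, and are tracked
only by the obsolescence metric and the cleanup operation. Replacement
hints count both `replaced_by` and the weaker `consider` links by
default; a flag (`consider_as_replacement=False`) restricts
alternatives to `replaced_by` for users who consider `consider` hints
too weak to rescue an annotation.

A functional annotation maps each gene of a fixed reference set to a
term set per aspect; a gene with an empty set is equivalent to an
unannotated gene. Genes appearing in annotation files but not in the
reference are excluded with a counted warning — the reference defines
the population, so silently growing it would corrupt coverage.
NOT-qualified GAF rows are dropped: a negated assignment is not an
annotation.

## Metric conventions

* **Coherence of a singleton is 1** by convention: similarity against
  an empty remainder is otherwise undefined, and a single term cannot
  disagree with itself.
* **Redundancy** counts a term as redundant only if it is an ancestor
  of a *different* term in the set; since every term is in its own
  closure, the self-inclusive reading would make redundancy
  identically 1.
* **Compactness** averages each annotation set's mean similarity to
  the other sets. Similarity across aspects is undefined, so the pooled
  `ALL` value averages within-aspect comparisons only, weighting each
  aspect by its number of annotation sets; aspects with a single set
  contribute nothing.
* **Information content** defaults to the descendant-propagated corpus
  frequency: `p(i)` is the fraction of annotated genes whose
  ancestor-closed set contains `i`. This is the standard Resnik-style
  estimate; it guarantees `IC(root) = 0` and child→parent monotonicity.
  An alternative `as-printed` variant sums *direct* annotation counts
  over a term's ancestors; under it, terms whose ancestor line is never
  directly annotated have `p = 0` and an undefined IC, and such terms
  are excluded from averages with a count. Both variants are exposed
  because the two readings of "frequency of a term and of its
  ancestors" differ and neither is universally used; the propagated
  form is the default as the one with the clean information-theoretic
  properties. The IC corpus defaults to the analysed FA itself; any FA
  can be passed as an external corpus.
* **Obsolescence** is the fraction of annotation *instances*
  (gene–term pairs) pointing at obsolete terms with no live
  alternative. Obsolete terms with proposed replacements still carry
  information and are not counted.
* **Hierarchical precision/recall** scores each term by the best
  fractional overlap of its own closure with any single term's closure
  on the other side: predictions are normalised by their own ancestor
  count for precision, gold terms for recall. This reproduces the
  "proportion of annotations also found in the other set" reading and
  yields the duality `hRecall(F, G) = hPrecision(G, F)` exactly. It
  also makes the asymmetry visible that shallow predictions inflate
  precision (a root-only prediction has precision 1) while deflating
  recall. Aggregation is per gene (each gene's mean, then the mean
  over genes), restricted to genes annotated on both sides; one-sided
  genes are counted and reported but not scored. Means come with the
  standard error of the mean (sample SD / √n, undefined for n < 2).
* **Resnik** set similarity aggregates pairwise MICA information
  content by best-match-average by default (`max` available); ties for
  the MICA are broken by term id for determinism. A normalised [0, 1]
  form divides by the corpus's maximal IC so Resnik can be injected
  wherever a bounded measure is expected.
* The similarity used inside coherence, compactness and all
  comparisons is injected (any `(graph, s1, s2) → float`); GS2 is the
  default throughout because it is computable for k sets in one pass
  over a shared term-count table rather than by a pairwise loop.
* Metrics with an empty domain (compactness of a one-gene FA, richness
  of an empty aspect) raise an explicit undefined-metric signal;
  reports show `None`, never a fabricated 0.

## Null models

`randomize_terms` preserves the gene list and every set size exactly
and redraws terms uniformly without replacement within the aspect's
live vocabulary — so coverage and per-gene N are invariant by
construction and only the *relatedness* of the terms is destroyed.
`sample_fa` annotates every reference gene with sizes from an explicit
distribution. Empirical p-values use the add-one correction
`p = (1 + #{null ≥ obs}) / (n_perm + 1)`, which cannot be 0 or exceed
1; draws are seeded `seed, seed+1, …` so one integer reproduces the
experiment.

## Synthetic data

The generators emulate what the metrics need to discriminate, not GO's
full scale: balanced per-aspect trees (optionally with extra `part_of`
cross-links to shallower terms, which keeps acyclicity by
construction), obsolete stanzas with and without replacements, and FAs
with a positively skewed set-size distribution (default
`{1: .5, 2: .25, 3: .15, 4: .1}`) mirroring the strong skew of real
array annotations. The `planted` option draws each gene's terms from a
single random subtree, giving the high within-set coherence of real
curated sets; the uniform option is the noise reference. Generated
objects are serialised to real OBO/GAF text and re-parsed, so the
readers are exercised on every generated fixture.

What the toy scale does *not* capture: annotation bias (real term
usage is highly non-uniform), evidence-code structure, term depth
heterogeneity, and inter-aspect correlations. Passing tests therefore
demonstrate correctness of the computations and the expected ordering
of structured vs random annotations, not calibration against any real
release.

The canonical worked fixture (6 live terms, 2 obsolete, 5 genes, an FA
and a gold standard) is fixed forever; every hand-derived reference
value on it is frozen in `gofa/fixture_constants.py` and independently
regenerated by `scripts/fixture_oracle.py` using naive fixpoint
closures and plain set arithmetic.

## Problem sizes

The null-separation experiment uses a 40-term DAG (depth 3, branching
3), 30 genes with planted 2–4-term sets, 100 separation draws and 199
permutations — large enough that the structured/random coherence
separation is essentially deterministic while the whole experiment
runs in seconds. The bounds/monotonicity fuzz suite runs 200 generated
fixtures at depth 2 / branching 2 / 6 genes.

## Known limitations

* The OBO readers cover the fields the analyses need (`id`, `name`,
  `namespace`, `is_a`, `relationship`, `is_obsolete`, `replaced_by`,
  `consider`); they are not general OBO 1.4 round-trippers.
* Affymetrix annotation headers vary across array releases; the reader
  keys on header names matching `Gene Ontology *` rather than column
  positions, and on a `Probe Set ID`-style id column.
* Venn partitions are exact for 2–4 FAs; beyond 4 the CLI falls back
  to the first four (the region table, not a diagram, is the primary
  output).
* No significance machinery beyond permutation p-values is provided;
  hPrec/hRec differences between FAs are reported as mean ± SEM only.
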