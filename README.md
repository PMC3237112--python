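# gofa — analysis and inter-comparison of GO functional annotations

Functional annotations (FAs) map each gene product of a reference set —
a proteome, a microarray's target sequences — to a set of Gene Ontology
terms per aspect (Biological Process, Molecular Function, Cellular
Component). Annotations for the same organism come from many pipelines
(vendor files, BLAST-transfer tools, curated databases) and differ
widely in how many genes they cover, how specific their terms are, and
how often they simply disagree. `gofa` is a library and CLI for anyone
who produces or consumes such annotations and needs to quantify those
differences before trusting a downstream enrichment or similarity
analysis.

## What it computes

For one FA `F : G_Ω → 2^T` over an ontology DAG with ancestor closure
`A(t)` (a term plus all its ancestors via `is_a`/`part_of`):

* **coverage** `|{g : F(g) ≠ ∅}| / |G_Ω|` and **richness**
  `|{t used}| / |T|` — quantity;
* per-gene **annotation counts** `N(g) = |F(g)|`;
* **coherence** `(1/N) Σ_i sim({i}, F(g)−{i})` and **compactness**
  (mean between-gene set similarity) — diversity;
* **specificity** `(1/N) Σ_i |A(i)|`, **redundancy** (fraction of terms
  that are ancestors of another term in the same set), **information
  content** `IC(i) = −log₂ p(i)` from corpus usage, and
  **obsolescence** (fraction of annotation instances pointing at
  retired terms with no proposed replacement) — informativeness.

Between FAs: coverage Venn partitions, per-gene semantic similarity
(GS2, Czekanowski–Dice, Resnik/MICA — all on ancestor-closed sets),
and hierarchical precision/recall against a gold standard,
`hPrec(g) = (1/|F(g)|) Σ_{s∈F(g)} max_{t∈G(g)} |A(t)∩A(s)|/|A(s)|`
(recall is the mirror image), which credits near misses in the DAG.
Permutation null models (term randomization, sampling FAs from the
ontology) give empirical p-values for any scalar metric.

Readers exist for OBO flat 1.2 and OBO-XML ontologies, GAF 2.0,
Affymetrix tabular annotation CSV, generic gene→term mappings, FASTA
and id-list references. FA algebra (union, intersection,
obsolete-term cleanup, evidence-code filtering, an "≥ k experimental
codes" gold-standard reducer) is built in, as are deterministic
synthetic ontology/FA generators so everything is testable offline.

## Worked example

```python
from gofa import canonical_fixture, summarize, gold_comparison

fx = canonical_fixture()          # 6-term DAG, 5 genes, FA + gold
report = summarize(fx.fa, fx.graph)
block = report.aspects["generic"]
print(f"coverage    {block.coverage:.3f}")
print(f"richness    {block.richness:.3f}")
print(f"compactness {block.compactness:.3f}")
gc = gold_comparison(fx.fa, fx.gold, fx.graph, "generic").summary()
print(f"hPrec {gc['hPrecision']:.3f}  hRec {gc['hRecall']:.3f}")
```

prints

```
coverage    0.600
richness    0.500
compactness 0.819
hPrec 0.741  hRec 0.889
```

Three of five reference genes are annotated (coverage 0.6) using three
of the six live terms (richness 0.5); the three annotation sets are
mutually similar (compactness 0.82). Against the gold standard the FA's
predictions are 74% supported (one gene predicts a sibling of the true
term, scoring 2/3 instead of 0 thanks to the shared parent) while 89%
of the gold annotations are recovered.

The same workflows are available from a shell:

```
gofa simulate --out bundle --seed 3 --planted
gofa analyze --obo bundle/ontology.obo \
     --fa sim=bundle/annotations.gaf:gaf \
     --reference bundle/reference.fasta:fasta --out results
```

plus `compare`, `evaluate` (`--gold LABEL`) and `evolve` for Venn/
similarity comparison, gold-standard evaluation and release time
series.

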