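# etglink

Enhancer–target-gene (ETG) pair prediction from four genomic features, with
the evaluation harness to judge the predictions against chromatin-contact
data.

## The problem

Enhancers regulate genes through chromatin looping and can sit megabases
away from their targets, with non-target genes interleaved between an
enhancer and the genes it actually controls.  Given only enhancer locations
(e.g. P300 ChIP-seq peaks) and a gene annotation, the task is to decide,
for every gene whose TSS lies within 2 Mb of an enhancer *e*, whether the
pair (*e*, *g*) is a true regulatory pair.

`etglink` scores each candidate pair with a 500-tree random forest over
four features and calls a target when the forest probability reaches 0.95:

- **distance** — minimum bp distance between the enhancer's endpoints and
  the gene's TSS;
- **CSS** (conserved synteny score) — whether enhancer and promoter stay
  near each other in other species' genomes.  With per-species lifted
  distance *d*ₛ and phylogenetic distance φ(r, s) from the reference:

  CSS(e, g) = Σₛ φ(r, s)·max(0, 1 − *d*ₛ/Θ) / Σₛ φ(r, s),  Θ = 2 Mb;

- **FSS** (function similarity score) — GO-term similarity between the
  gene's annotations and terms inferred for the enhancer through the motif
  modules (significantly co-occurring motif sets) it carries.  Term pairs
  are compared by Lin similarity 2·IC(MICA)/(IC(t₁) + IC(t₂)) and
  aggregated by best-match average;
- **correlation** — Spearman correlation of DNase-hypersensitivity signal
  between the enhancer and the promoter across a cell-type panel.

The promoter is the strand-aware window 1 kb upstream to 100 bp downstream
of the TSS.  The evaluation side implements region-overlap confusion
counts, recall/precision/F1, ROC AUC, support by 5-kb Hi-C contact
matrices at a read cutoff (with a ≥5 kb separation rule), random-pair
binomial nulls, and the inconsecutiveness of an enhancer's target set.

Because the method's real inputs (genome alignments, GO, DNase panels,
contact matrices) are bulky, the package ships a seeded generator that
emits a complete miniature dataset in all the real file formats — BED,
GTF, FASTA, MEME-style PWMs, OBO, GAF, bedGraph, contact triplets — with
planted true pairs expressing all four signals.

## Worked example

```python
import pathlib, tempfile
from etglink import FixtureConfig, generate
from etglink.pipeline import load_bundle, bundle_feature_table, train_and_evaluate

workdir = pathlib.Path(tempfile.mkdtemp())
generate(FixtureConfig(seed=1), workdir / "fixture")
bundle = load_bundle(workdir / "fixture")
table = bundle_feature_table(bundle)       # four features per candidate pair
bench = train_and_evaluate(table, seed=1)  # enhancer-level split, balanced fit
print(bench.summary())
```

prints

```
Enhancer-target pair model (random forest)
============================================
training pairs:      240 (120 positive)
trees:               500
score cutoff:        0.95
features:            distance, css, fss, correlation
seed:                1

impurity importance:
  distance     0.4994
  css          0.3321
  correlation  0.0895
  fss          0.0790

held-out evaluation
--------------------------------------------
test pairs:          960 (120 positive)
ROC AUC:             0.977
predicted targets:   85
recall:              0.633
precision:           0.894
F1 score:            0.741
```

The forest separates planted true pairs from the other genes in the same
2 Mb windows (AUC 0.977 on enhancers never seen in training), and at the
0.95 cutoff it calls 85 targets of which 89% are correct.  Distance is the
most important feature and correlation among the least — the planted
ordering of the generator.

The same workflow is available from the shell:

```sh
etglink simulate --outdir fx --seed 1
etglink features --bundle fx --out pairs.tsv
etglink train    --features pairs.tsv --model-out model.joblib --seed 1
etglink predict  --features pairs.tsv --model model.joblib --out targets.tsv
etglink evaluate --predictions targets.tsv --bundle fx --out report.json
etglink rank-features --features pairs.tsv --out ranking.tsv
```

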