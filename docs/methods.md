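# Methods

## Model

A candidate pair is any (enhancer, gene) with the gene's TSS within the
candidate window (default 2 Mb, inclusive) of the enhancer on the same
chromosome; trans pairs are never considered.  Each pair carries four
features, and a random forest of 500 trees (scikit-learn
`RandomForestClassifier`, library defaults beyond the tree count, which are
recorded in the fitted results) maps them to a score in [0, 1] — the
fraction of trees voting positive, read as the probability the gene is a
true target.  Pairs scoring ≥ 0.95 are called targets; the cutoff, window
and tree count are fields of `ParameterSet` and were fixed as the defaults
of the published configuration this package re-implements.

All internal coordinates are 0-based half-open (BED convention); GTF/GFF
input is converted on read.  The enhancer's "endpoints" are its first and
last covered base, so the distance feature is
min(|start − tss|, |end − 1 − tss|), zero when the TSS falls inside the
enhancer, and infinite (never a candidate) across chromosomes.  The 1-bp
ambiguity between coordinate conventions is immaterial to the forest.

### Conserved synteny score

Enhancer region and promoter (1 kb upstream to 100 bp downstream of the
TSS, strand aware, clamped at 0) are lifted through per-species alignment
blocks.  Lifting interpolates linearly within a block, honours block
orientation, and when several target chromosomes are hit keeps the one
with the largest total reference overlap.  A species contributes

c_s = max(0, 1 − d_s/Θ)

with d_s the gap in bp between the two lifted spans (0 on overlap) and
Θ = 2 Mb; species where either region fails to lift, or lifts to different
chromosomes, contribute 0.  The score is the φ-weighted mean
Σ φ(r, s)·c_s / Σ φ(r, s).  The published description fixes the
ingredients (φ, d_s, Θ) but not the printed functional form, which was
unrecoverable from the source; the linear decay above is this package's
documented reconstruction, and an indicator kernel (c_s = [d_s ≤ Θ]) is
selectable instead.  The score is invariant under uniform rescaling of φ
and monotone non-increasing in every d_s.  Phylogenetic distances load
from a two-column TSV or as patristic distances from a Newick tree.

### Function similarity score

Motif occurrences: per-PWM log-odds scan of both strands against a uniform
0.25 background with pseudocount 1e-3; a motif occurs in an enhancer when
its best window reaches 80% of the motif's maximal attainable log-odds.
Non-ACGT bases contribute zero log-odds.

Motif modules: level-wise (Apriori) enumeration of motif sets of size 2–5
with support ≥ max(3, 5% of enhancers); each set is tested with an exact
one-sided binomial upper tail against the independence null p₀ = product
of member marginal frequencies, Bonferroni-corrected over all tested sets,
kept at corrected p ≤ 0.01, and reduced to maximal sets.  This miner is a
deliberate simplification of dedicated motif-module discovery tools; module
and instance lists produced externally can be supplied as TSV instead.
Note the independence null makes small co-occurrence counts with high
marginals unremarkable — a set must co-occur well above the product of its
members' frequencies to survive.

Enhancer GO terms: for each module, the enhancers carrying it are pooled,
every gene within the candidate window of any of them is collected and
de-duplicated, and each propagated GO term is tested for over-representation
in that list against the annotated gene universe (hypergeometric upper
tail, Benjamini–Hochberg at 0.05; namespace roots are excluded as
uninformative).  An enhancer's terms are the union of its modules'
significant terms — the union rather than intersection is this package's
choice where the published account is silent.

Term similarity is Lin's measure 2·IC(MICA)/(IC(t₁)+IC(t₂)) with
IC(t) = −ln(n_t/n_root) after propagating annotation counts (as distinct
gene sets, so n_child ≤ n_parent exactly) to all ancestors; raw Resnik
IC(MICA) is selectable.  Similarity is computed within a namespace; terms
from different namespaces score 0.  FSS aggregates the two term sets by
best-match average (mean of each term's best counterpart, averaged over
both directions); the aggregator is likewise a documented package choice.
The gene side uses direct annotations, the enhancer side the enrichment
output; either side empty gives 0.

### Activity correlation

Region activity in a cell type is the mean per-bp bedGraph signal
(uncovered bases are 0).  The feature is Spearman's rho between the
enhancer's and the promoter's activity vectors across the panel (≥ 3 cell
types required; ties get average ranks).  A constant vector would make rho
undefined; it is reported as 0 so the feature is always populated rather
than silently missing, which would bias the forest.  Panel membership is
configuration, not hard-coded.

### Training and ranking

Negative pairs are drawn uniformly without replacement from (enhancer,
candidate non-target) combinations, seeded.  The benchmark protocol splits
by enhancer (50/50) so no enhancer contributes to both sides, balances the
training side by subsampling, fits, and scores the held-out side.  Feature
ranking: native information gain (label-entropy reduction in bits after
10-bin equal-frequency discretization; constant features gain 0 and rank
last) and random-forest impurity importance; standardized linear-SVM
weights and the Lasso regularization-path entry order are optional hooks
through scikit-learn.  Distance is fed raw in bp by default (trees are
scale-insensitive); a log10 transform is available for scale-sensitive
consumers.

## Evaluation harness

Predictions and known pairs match by dual region overlap (≥ 1 shared bp,
half-open, in either orientation of the known pair).  A prediction
matching several known pairs counts once and a known pair recovered by
several predictions is recovered once, keeping recall ≤ 1.  Undefined
ratios (e.g. precision with no predictions) are reported as `None`, never
0-divided.  ROC AUC is the rank-statistic (Mann–Whitney) value, computed
via scikit-learn and cross-checked in the tests against an exhaustive
concordant/discordant/tied pair count.  Hi-C support requires ≥ 5 kb
enhancer–promoter separation and a contact-matrix triplet with count ≥ the
read cutoff whose two 5-kb bins overlap enhancer and promoter (either
order); support is monotone non-increasing in the cutoff.  The random-pair
null draws a uniform enhancer, then a uniform gene within the window;
enrichment of support among predictions over the null rate uses the exact
one-sided binomial upper tail.  An enhancer with ≥ 2 predicted targets is
"inconsecutive" when a non-target candidate lies strictly between two of
its targets in TSS order; single-target enhancers are excluded from the
denominator.

## Synthetic benchmark

The generator lays out one enhancer (500 bp) every 5 Mb with its candidate
genes placed around it, so every gene is a candidate of exactly one
enhancer and the planted labels are exact.  Promoters are kept ≥ 3.2 kb
apart and ≥ 6 kb from the enhancer so bedGraph segments never overlap and
every pair passes the 5-kb Hi-C separation rule.  Defaults: 120 enhancers
on 2 chromosomes, 16 genes per window, 2 true targets per enhancer
(~1 920 candidate pairs, 12.5% positive).

Planted signals, per feature:

- *distance* — true-pair distances exponential with an 80 kb scale; false
  pairs uniform within the window;
- *CSS* — five species (chimpanzee, mouse, chicken, frog, zebrafish at
  φ = 0.03/0.45/0.95/1.6/2.1 from the reference); a promoter stays near
  its enhancer in a species with probability 0.50 (true) vs 0.12 (false),
  otherwise it is unmapped or moved to a decoy chromosome; enhancers lift
  with probability 0.95;
- *FSS* — six 8-bp motifs; two two-motif modules planted alternately in
  enhancers, two background motifs at 5%; a toy GO tree (root, two
  function branches and a decoy branch, three leaves each); true targets
  carry a leaf of their enhancer's branch with probability 0.65, false
  genes 0.10, and any gene a decoy leaf with probability 0.6;
- *correlation* — latent standard-normal activity per cell type across a
  13-cell panel; true promoters mix the enhancer's latent signal with
  weight 0.20, false promoters are independent; tracks store exp(z);
- *contacts* — Poisson reads with mean 30 (true) vs 1 (false) on the
  enhancer/TSS bin pair, plus sparse Poisson(1) background.

The signal strengths were set once so that the planted effect sizes
decrease in the order distance > CSS > FSS > correlation — the qualitative
importance ordering the method is known for — while keeping held-out AUC
comfortably above 0.9; they are study conditions, not tuning knobs.  A
`zero_effects()` variant equalizes every true/false parameter, making
labels exchangeable, and is the chance-level control.  Every output
artifact draws from its own child stream of the master seed
(`numpy.random.SeedSequence.spawn`), so regeneration is byte-identical and
adding, say, a cell type cannot perturb the gene layout.

What the generator does *not* emulate: realistic genome composition (the
written FASTA covers enhancer sequences only, keyed by enhancer id, since
the neighbourhood layout would otherwise be ~100 Mb of padding), shared
genes between enhancer windows, cell-type-specific regulation, alignment
micro-structure (blocks are 1:1), GO DAGs with multiple parents, and
contact-matrix normalization artefacts.  Passing tests therefore show the
pipeline recovers the statistical structure it assumes, not performance on
real chromatin data.

## Problem sizes and numerical choices

The default benchmark (~1 920 pairs) and the 160-enhancer zero-effect
control (~2 560 pairs) are sized so a full suite run and the acceptance
script each finish in minutes on one core.  PWM columns must sum to 1
within 1e-6; oracle equivalence for Spearman and information gain is
asserted to 1e-12; ROC AUC against the pair-count oracle to 1e-12 on ≤ 50
points.  Ranking ties break lexicographically by feature name so orderings
are deterministic.  Model bundles are versioned joblib files that refuse
to score feature sets differing from training.

## Known limitations

The module miner is not a faithful re-implementation of dedicated
motif-module discovery; its product-of-marginals null over-penalizes
correlated subsets of true modules and the Bonferroni correction is
conservative.  Enhancer GO assignment inherits any incompleteness of the
annotation table.  The CSS kernel is a reconstruction (see above).  The
forest's hyperparameters beyond tree count follow scikit-learn defaults;
no hyperparameter search is performed, matching the published setup.
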