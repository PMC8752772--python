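# Methods

## The model

`cnvimpact` treats CNV interpretation as binary classification with
abstention. A CNV is represented only by its interval and type; all biology
enters through overlap counts against categorized element tracks. The
working assumption is that clinical impact correlates with *how much*
functionally annotated sequence a CNV disturbs, not *which* specific
elements — an assumption that fails for small CNVs hitting a single critical
gene (see Limitations).

Counts use any-overlap semantics: an element counts if it shares at least one
base with the CNV, each element at most once, with no reciprocal-overlap
fraction. Coordinates are 0-based half-open (BED convention) throughout; VCF
`POS` is converted on input by subtracting 1. Counting is implemented with a
sorted-endpoint identity (elements overlapping a query = all elements on the
chromosome minus those ending at/before its start minus those starting
at/after its end; the two excluded sets are disjoint), which is exact for
any-overlap semantics and O(log n) per query. The test suite checks it
against an O(n·m) all-pairs oracle on randomized inputs.

Dosage-sensitivity tracks (haploinsufficient genes/regions for losses,
triplosensitive regions for gains) are filtered to elements with evidence
score **exactly 3** — the code for "sufficient evidence of a dosage
mechanism". The filter is equality, not ≥, because higher codes (e.g. 40)
mark qualitatively different evidence categories.

### Feature schema

Losses use 19 attributes, gains 18: the shared gene and regulatory
categories, plus haploinsufficient genes and regions (losses only) or
triplosensitive regions (gains only). Attribute order is fixed and hashed
into saved model metadata; prediction on mismatched schemas is an error. CNV
length is deliberately **not** a feature: genomic content is unevenly
distributed and length alone is a poor predictor, so only counts enter the
model.

### Preprocessing

The training regime is restricted to canonical CNVs:

* length strictly between 1 kbp and 5 Mbp. Both bounds are strict; CNVs at
  or above 5 Mbp are routed to a separate long-CNV evaluation set (they are
  almost always pathogenic and would distort training), and CNVs at or below
  1 kbp are dropped as out of scope.
* multiplicity 1 for losses and 3 for gains; homozygous deletions
  (multiplicity 0) and double duplications (4+) go to a separate "multiple"
  evaluation set. Records without a multiplicity annotation count as
  canonical, since most public records omit it.
* unambiguous benign/pathogenic labels; likely-benign, likely-pathogenic and
  uncertain-significance records are held out for five-tier evaluation.

Train/validation/test partitioning is a stratified random 70/15/15 split
with a required seed. The split procedure is this package's own choice; the
filters above are part of the method.

### Classifier

One XGBoost binary-logistic boosted-tree ensemble per CNV type. Defaults:
`max_depth=8`, `eta=0.3`, `gamma=1`, `subsample=1`, `lambda=0.1`,
`colsample_bytree=0.8`, up to 100 rounds with early stopping after 15 rounds
without improvement. The early-stopping objective is validation log-loss;
validation MCC at the 0.5 cut is used only to rank configurations in
`grid_search` (ties broken by higher accuracy, then lower `max_depth`, then
grid order — a deterministic stand-in for manual inspection of candidate
models). Class imbalance is handled by
`scale_pos_weight = sqrt(n_benign / n_pathogenic)`, derived from the
training counts unless overridden; the square root keeps the reweighting
gentle because the raw probabilities feed the abstention policy directly.
Training runs single-threaded, making fitted models bit-reproducible for a
fixed seed.

### Call policy

With threshold `p_ct` (presets 0.5, 0.95, 0.99; default 0.95): pathogenic if
`P >= p_ct`, benign if `P <= 1 - p_ct`, otherwise uncertain significance.
Both comparisons are inclusive; at the degenerate preset 0.5 the pathogenic
rule wins at exactly 0.5. The policy is monotone in `P`, and lowering `p_ct`
never produces more abstentions.

### Evaluation

Three-way calls against binary truth form a 3×2 confusion table. Two
denominator conventions are kept as separately named fields rather than
options:

* **uncertain-excluded** accuracy, sensitivity, specificity, per-class
  precision and MCC, computed from the four committed-call cells
  (`MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`);
* **discovery rates**, `correct calls / full column total` including
  abstentions — the yield of correct committed calls among all truly
  benign (resp. pathogenic) variants.

Percentages are rounded half-up to two decimals where printed. Metrics with
zero denominators are reported as explicit `None`, never silently as 0.
ROC–AUC is the rank-based Mann–Whitney statistic (ties share rank), with an
optional mode that drops abstained variants first, since either convention
is defensible. Per-label probability summaries (quartiles plus fractions
committed each way) support strip-plot views over the five-tier label range.

### Explanation

Attributions are exact path-dependent Shapley values for tree ensembles: the
conditional expectations follow the training cover recorded at each split
(no interventional background dataset), and the base value is the
cover-weighted expectation of the ensemble margin. The package computes them
in double precision from the parsed tree dump (`_treeshap.py`), so the
additive identity `base + Σ contributions = margin` holds to ~1e-12; the
booster's built-in single-precision contribution predictor computes the same
algorithm and serves as a fast path for batch importance scans and as an
independent cross-check in the tests. Attribution is exact and additive only
on the log-odds scale; the probability-scale view rescales contributions
proportionally between the sigmoid-transformed endpoints and is a display
transform, not a Shapley decomposition. Waterfall export orders attributes
by |contribution| and collapses the remainder into an "other" row so the
cumulative endpoint still equals the output value.

## Synthetic data

Two generators replace the non-redistributable clinical training data.

**Moment-matched count sampler.** Each attribute × class (benign/pathogenic)
pair carries a target mean and standard deviation taken from descriptive
statistics of clinically classified CNV collections; pathogenic CNVs overlap
roughly ten times more elements of nearly every category. Counts are drawn
from a negative binomial parameterized by moment matching
(`size = m²/(v−m)`, `p = m/v`) because the targets are overdispersed
(variance ≫ mean) for almost every attribute; a Poisson is used when
`v ≤ m`, a constant column when `std = 0`, and an all-zero column when the
target mean is 0 (a printed mean of 0.0 is treated as a point mass for
fixture purposes). Attributes are sampled **independently** by default. Real
count attributes co-vary strongly (a CNV spanning many genes spans many
promoters), so passing tests on these fixtures demonstrates the mechanics
and the separability of the count representation, not performance on real
data — with independent attributes the classes are in fact more separable
than in reality (validation MCC ≈ 1.0, versus the 0.93–0.97 range the metric
suite derives from the reference clinical confusion tables). A Gaussian-copula option (`rank_correlation`) adds uniform rank
correlation for sensitivity analyses; it is off by default.

**Toy genome.** Chromosomes (defaults: 10 Mbp + 8 Mbp) are split into an
element-dense first half (enrichment 10×) and a sparse second half
(2 elements/Mbp/category); elements are placed uniformly with lengths
200–5,000 bp. Pathogenic CNVs (lengths 50–500 kbp) are placed in dense
regions, benign in sparse ones. The generator records ground-truth overlap
counts by exhaustive all-pairs checking at generation time, giving the
annotation path an independent oracle. The toy genome does not emulate
chromosome banding, syndrome regions, segmental duplications or realistic
track size distributions.

## Problem sizes and numerical choices

Default experiment sizes — 2,000 + 2,000 sampled feature vectors per CNV
type (split 70/15/15), 100 + 100 toy-genome CNVs, 1,000 × 500 random
intervals for the overlap oracle, 50 explained vectors for the additivity
check — were chosen so the full suite and the acceptance run complete in
seconds while keeping sampling error well inside the asserted margins
(e.g. the 50,000-draw moment checks use 3–5% relative tolerances).

Other numerical choices: probabilities compared to thresholds with inclusive
inequalities; percentage rounding is half-up via `decimal`; waterfall and
importance sorts are stable (mergesort) so ties preserve schema order;
`split_train_val_test` derives its second-stage seed as `seed + 1`;
undefined metrics surface as `None` and are listed by
`MetricsReport.undefined_metrics()`.

## Limitations

* Count features ignore the identity, severity and interactions of
  overlapped elements; a CNV deleting one critical haploinsufficient gene
  can be under-called. Pairing predictions with criteria-based review (e.g.
  ACMG scoring) is recommended before clinical use.
* Breakend-style SV records are not parsed; only DEL/DUP with `INFO/END`.
* No liftover between assemblies, gene-name resolution or database
  querying; element tracks are opaque interval sets supplied by the user.
* Synthetic fixtures are not biologically realistic (see above); reported
  synthetic metrics are upper bounds on real-data behavior.
* Probability-scale explanation views are proportional approximations; only
  the log-odds decomposition is exact.
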