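# Methods

## Model

The package represents a segment of RR intervals symbolically and
classifies segments by the statistics of symbol transitions.

**Dynamic thresholds.**  For a segment with mean interval r̄, odd
vocabulary size V and relative step t, the threshold list is
{ r̄·(1 − t·(1+k)), r̄·(1 + t·(1+k)) : k = 0 … (V−3)/2 } — V−1 strictly
increasing positive values, symmetric about r̄.  V must be odd so that a
middle bin straddles the mean; V is capped at 25 so symbols stay within
the lowercase alphabet.  t defaults to 0.05 (5% of the mean per step) and
is configurable; underflow (1 − t·(V−1)/2 ≤ 0) is rejected rather than
clamped.  Thresholds are recomputed per segment from that segment's own
mean — this is what makes the assignment *dynamic* and amplitude-invariant;
an external reference mean can be pinned explicitly for experimentation.

**Symbolization.**  Bins are half-open, T_{i−1} ≤ r < T_i, completed with
T_0 = 0 and T_V = +∞, so every positive interval receives exactly one
symbol and a value exactly on a threshold falls into the upper bin.
Out-of-range values therefore take the edge symbols rather than being
clamped or dropped.

**Co-occurrence features.**  The word size W (2–5) is the *total* window
length: a (W−1)-symbol row pattern followed by one symbol.  Windows
overlap with stride 1, so a sequence of length L yields L−W+1 counts.
Rows enumerate all V^(W−1) patterns lexicographically, including
never-observed ones, giving every segment — whatever its length — a
feature vector of fixed dimension V^W.  Normalization is global
(every cell divided by the grand total), so P is a joint distribution over
(pattern, symbol), not a per-row conditional Markov matrix; no smoothing
or pseudocounts are applied.  The scalar *max co-occurrence* feature is
the largest cell of P: 1.0 for a constant sequence, approaching 1/V^W for
a uniform i.i.d. one.  Both feature modes (full vector, scalar) are
supported; the vector is the default for classification.

## Classifiers

Defaults (each overridable, with declared grid-search ranges):

| name | defaults |
|------|----------|
| SVM  | linear kernel, C = 0.01 (gamma 0.1 carried but inert under the linear kernel) |
| kNN  | 5 neighbors, uniform weights, Euclidean metric |
| RF   | 100 trees, sqrt features, min_samples_split 10, min_samples_leaf 1, no depth cap |
| RoF  | rotation forest: 10 rotations, feature groups of 3, PCA projection, 10-tree forest per rotation |
| EL   | error-weighted voting committee of SVM, RF, RoF |

**Rotation forest.**  Each ensemble member randomly partitions the
features into disjoint groups of 3 (last group smaller if needed), fits a
full-rank PCA per group on a bootstrap drawn from a random ~75% subset of
the classes, assembles the loadings block-diagonally into an orthonormal
rotation of the whole feature space, and fits a small forest on the
rotated data; prediction averages member probabilities.  Degenerate
subsamples (fewer than two distinct rows) fall back to an identity block;
rank-deficient PCAs are padded to an orthonormal basis by QR.  The
ensemble geometry (10 rotations × 10 trees) keeps the total tree count
comparable to the plain RF configuration.

**Voting ensemble.**  Each member is fitted on the training set and
weighted by its training error via the boosting weight ln((1−err)/err),
clipped to [0, 10]; an error-free member takes the clip value and a
worse-than-chance member is silenced (if all members are silenced the
vote falls back to unweighted).  Prediction is the weight-majority label;
exact ties resolve to PAF, the positive class — a screening tool should
err toward the pathological rhythm.  Plain majority voting is available
as a config option.

## Validation harness

Stratified 5-fold cross-validation, repeated 10 times with a fresh
seed-derived shuffle per repeat (stratification is needed because per-class
counts are small).  Confusion counts are pooled over the folds of a repeat,
converted to precision/recall/F/accuracy (PAF positive; zero-denominator
metrics report 0 and are flagged), and averaged over repeats.  ROC curves
from all folds are reduced to their vertices (unique FPR, highest TPR),
linearly interpolated onto a common 101-point FPR grid — the standard
convention under tied scores, and exact for a perfect classifier — then
averaged; AUC is the trapezoid of the mean curve.  Folds whose test split
contains one class are excluded from ROC averaging with a warning.
Hyperparameter grids, when enabled, are tuned by nested cross-validation
inside each training fold and never leave the declared ranges.

Group separation of scalar features uses the Wilcoxon signed-rank test for
paired samples (explicit pairing ids required; all-zero differences are
rejected as degenerate) and the rank-sum (Mann–Whitney) test otherwise,
two-sided, exact where scipy provides it.  No multiple-testing correction
is applied by default; a Bonferroni option exists for (V, W) sweeps.

## Synthetic data

The generator emulates the *statistical contrast* between the two rhythm
classes, not their electrophysiology:

- **SR**: r_j = 0.85 + 0.03·sin(2π·0.1·j) + ε_j, ε_j ~ N(0, 0.01²),
  floored at 0.2 s — a ~70 bpm rhythm whose slow modulation and jitter
  stay inside the middle symbol bin at t = 0.05, giving near-constant
  symbol sequences.
- **PAF**: i.i.d. Uniform(0.40, 1.20) s — serially uncorrelated, high
  variance, spanning all bins of any vocabulary.  A gamma alternative with
  matched mean/variance is available.

Segments append beats until 60 s of cumulative time by default; datasets
are balanced with 60 segments per class.  Every segment's random stream is
derived from (config seed, segment id), so individual segments, datasets
and written CSV bytes are reproducible.

What passing tests show — and do not show: the pipeline separates
regular from serially uncorrelated RR series essentially perfectly at
these settings.  Real PAF is much harder: real recordings contain ectopic
beats, detection errors, non-stationary SR variability and AF episodes
that are not white noise, none of which the generator models.  Synthetic
results validate the machinery, not clinical performance.

## Numerical choices

- Binning uses `searchsorted(..., side="right")`, which implements the
  half-open threshold rule exactly; a brute-force bin scan cross-checks it.
- Probability normalization must sum to 1 within 1e−12; feature tables are
  written with `%.17g` and read with round-trip float parsing so
  write→read is bit-identical.
- CV fold partitions derive from `seed·1000 + repeat`; per-fold estimator
  seeds add the fold index.  All derived seeds stay below 2³¹.
- Problem sizes used throughout the tests (60 segments/class, 60-second
  segments, 10 CV repeats, 1000-draw null simulations) were chosen as the
  package's standard study conditions; they run on a single CPU in a few
  minutes.

## Limitations

- R-peak detection is out of scope: inputs are RR intervals or R-peak
  sample indices from existing annotations.
- The co-occurrence features discard the absolute time scale entirely
  (by design); pathologies expressed in mean rate rather than pattern
  irregularity are invisible to them.
- The voting ensemble is a single-round committee, not a full boosting
  schedule with iterative reweighting.
- With strongly tied discrete scores and very small folds, fold-averaged
  AUC carries small-sample bias of a few percent in either direction;
  pooled AUC over folds would reduce it but is not the reported metric.
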