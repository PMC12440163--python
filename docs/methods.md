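# Methods

`mobilegait` implements a markerless gait-impairment classification pipeline
operating on 33-landmark pose time series of short overground walks, together
with a synthetic data generator that emulates the recording protocol such
pipelines are built for: 10 m walks filmed by two asynchronous mobile-phone
cameras (frontal and sagittal), seven gait patterns — normal (NOR) and six
impairments (circumduction CIR, Trendelenburg TRE, antalgic ANT, crouch CRO,
Parkinsonian PAR, vaulting VAU) — with asymmetric impairments performed on
the right side.

## The synthetic gait generator

### Walker model

The walker is a parametric sinusoidal gait model, not a dynamical
simulation. Per gait cycle the pelvis advances one stride `S` at cadence `f`
(cycles/s); each foot alternates a ground-fixed stance phase (duty factor
0.6 of the cycle) with a smooth swing whose forward profile
`s(u) = u − sin(2πu)/(2π)` has zero end velocity and whose heel lift
`h·sin(πu)` has exactly one maximum per cycle. Knees are placed by two-link
inverse kinematics between hip and ankle in the vertical plane containing
them, so thigh and shank lengths are exactly constant; leg segments are
sized once per subject for the subject's normal stride, because the
calibrated strides (below) exceed anatomical leg reach. Arms swing antiphase
to the ipsilateral leg; face and hand landmarks are rigid offsets. The
normal walker is exactly symmetric under mirror + half-period shift, which
the suite asserts.

### Impairments

Each class modifies the base cycle through one or two control parameters,
all multiplied by an impairment magnitude in [0, 1] (default 1.0):

| class | modifier | default (magnitude 1) |
|---|---|---|
| CIR | lateral semicircular arc of affected swing foot | 0.18 m |
| TRE | contralateral pelvic drop during affected stance | 0.055 m |
| ANT | affected stance-time fraction reduced | −30% |
| CRO | pelvis lowered by sustained knee/hip flexion | 0.12 m |
| PAR | stride ×0.44, cadence ×1.30, arm swing ×0.15, trunk pitch 0.35 rad | — |
| VAU | body lift on unaffected stance during affected swing | 0.07 m |

At magnitude 0 every class collapses onto the identical normal walker — the
null condition used to verify that the pipeline cannot classify where no
kinematic signal exists.

### Stride calibration

Per-class stride factors are calibrated so that the expected number of gait
cycles over the 10 m path matches clinically observed per-class means
(ANT 7.6, CIR 5.8, CRO 7.2, NOR 4.6, PAR 10.4, TRE 6.4, VAU 5.4): the factor
for class c is `4.6 / cycles(c)`, applied to the subject's normal stride
(drawn from 2.05–2.30 m) and interpolated with magnitude. Because walking
speed differs by class, slower classes produce more analysis windows per
video — the class imbalance that SMOTE later corrects, with PAR the majority
class. `count_gait_cycles` (peak counting on the heel's vertical channel
after stature normalization, jitter smoothing and rolling-median detrending)
recovers these counts to within roughly one cycle; it exists for calibration
checks only.

### Cameras and noise

The sagittal camera sits 4 m from the line at its midpoint: a true pinhole
projection whose scale is near-constant. The frontal camera sits on the path
axis 4 m behind the start, so the walker's apparent size changes by up to
3.5x over the walk. The z channel is each landmark's camera depth relative
to the hip centre, scaled like the pixel channels. Gaussian jitter
(default 2 px) corrupts x/y; a larger noise (default 6 units) corrupts z,
reflecting the poor depth estimates of monocular pose estimators. Occlusion
is an independent Bernoulli per landmark-frame (default 0.03) — real
occlusion is temporally and anatomically correlated, which this generator
deliberately does not model (a known limitation: interpolation is easier
here than on real data). Walking direction flips the world by 180° about the
path's midpoint. All draws descend from a single seed; a fixed configuration
reproduces byte-identical datasets.

### What passing tests do and do not show

The generator produces the statistical structure the pipeline assumes
(class-specific periodic kinematics, view geometry, depth noise, occlusion,
window imbalance), so green end-to-end tests show the pipeline's machinery
is sound and can recover class structure that is present. They do not show
that real clinical accuracy would match: real gait has inter-subject
variability, compensation, mixed severity and correlated noise far beyond
this model, and the synthetic classes are cleanly separable by design.

## Preprocessing

Fixed order: drop frames with no observed landmarks → linear interpolation
of missing landmarks over time (nearest-value fill at the edges, where
interpolation is undefined) → downsampling to 30 fps by linear interpolation
onto a uniform grid (robust to non-integer ratios; upsampling is refused) →
hip-centring → frontal-only rescaling → 30-frame windows with 50% overlap
(starts 0, 15, 30, …; partial tails dropped).

Hip-centring subtracts, per frame and channel, the median of the hip-centre
point (midpoint of the two hips) over the 2-second window [t−30, t+30],
truncated at the sequence ends; using a rolling median rather than the
per-frame hip keeps natural hip sway in the signal. Frontal rescaling
divides each frame by a body-height estimate — the vertical nose-to-ankle-
midpoint extent, median-smoothed over the same 2 s window — and multiplies
by a fixed reference stature of 170 px (roughly a subject's pixel height at
the sagittal camera's distance, keeping both views on comparable scales).
The z channel is centred and rescaled like x/y. Re-running preprocessing on
its own output is idempotent to within ~2% of scale: the stature estimate
intentionally retains the gait's own height oscillation, so the second
rescale is not an exact no-op. No stage reads the gait label.

## Feature bank

Every catalog entry is evaluated on each of the 99 keypoint-channel series
(33 landmarks × x/y/z) of every window, with canonical column names
`<landmark>_<channel>__<type>__<param>=<value>…` so importances can later be
aggregated per channel and per feature type. Two pinned catalogs exist:

* **full-mirror** — 783 entries per channel across 37 feature types
  (77,517 candidate features per window). Parameter grids are pinned in
  `features/catalog.py`; the Fourier coefficient order is capped at
  k ≤ 15 = ⌊30/2⌋ because windows are 30 samples.
* **reduced** — 82 entries per channel over the same types except the
  Langevin fixed point (the one calculator with no vectorized form, of
  marginal discriminative value at this series length); the default for
  model fitting and tests.

Numerical conventions, applied consistently and covered by a naive
per-series reference implementation in the test suite (agreement to 1e-6
relative on 50 random series for every pinned entry):

* population variance (divide by n); variation coefficient = std/mean with
  0 when the mean is 0. The variation coefficient is deliberately std/mean,
  the conventional definition, rather than standard error/mean.
* autocorrelation `R(l) = Σ(x_t−μ)(x_{t+l}−μ) / ((n−l)σ²)`, 0 when σ² = 0.
* approximate entropy: Chebyshev distance, tolerance r·std; sample entropy:
  m = 2, r = 0.2·std, −ln(A/B), 0 when A or B is 0.
* permutation entropy: Shannon entropy (nats) of ordinal-pattern
  frequencies, patterns encoded by Lehmer rank (ties resolved by stable
  sort order).
* Welch PSD for the Fourier entropy uses segment length min(n, 30) — one
  segment for 30-sample windows — and the spectrum is max-normalized before
  binning.
* spectral aggregates treat the magnitude spectrum as a distribution over
  bin index; skew/kurtosis are 0 when the spectral variance is 0.
* the Ricker-wavelet CWT uses the closed-form wavelet on min(10w, n) points
  and same-mode convolution.
* FFT phase (`attr="angle"`) is reported in radians.
* any non-finite feature value is replaced by 0 (and counted in a log
  message) so the matrix stays finite.

Calculators are batch functions over a (series × samples) matrix; entries of
one type share precomputation (one FFT for all Fourier coefficients, one
convolution per wavelet width, one pairwise-distance matrix for both
entropies), which keeps extraction of ~8k features × ~3k windows around half
a minute on one core.

## Selection and balancing

Relevance filtering follows the scalable-hypothesis-testing recipe: for each
feature and each class, a two-sided Mann-Whitney U test (normal
approximation with tie and continuity correction; ranks computed once per
feature) of the one-vs-rest split; constant features get p = 1. The
Benjamini-Yekutieli step-up — threshold `k·q/(m·c(m))`, `c(m) = Σ 1/i`,
valid under arbitrary dependence — is applied jointly across the flattened
feature × class p-matrix at q = 0.05 (the FDR level is a pinned default, as
is one-vs-rest multiclass handling and keep-if-any-class), and a feature
survives if rejected for at least one class. Survivor counts are also
reported per feature type. An empty selection falls back to keeping all
features, with a warning, so downstream models still receive a matrix.

SMOTE then grows each minority class to the majority count: each synthetic
row is `x + λ(nn − x)`, λ ~ U(0,1), with `nn` one of the k = 5 nearest
same-class neighbours (Euclidean; k reduced to n−1 in small classes,
singletons duplicated). Selection runs first, SMOTE interpolates in the
reduced space. Both are fitted strictly inside training folds; the
evaluation driver asserts that no held-out row reaches them.

## Evaluation protocol

Outer loop: leave-one-subject-out over subjects (both walking directions of
a subject pooled as training windows). Per fold: selection → SMOTE →
hyperparameter tuning → fit → predictions for the held-out subject. Inner
tuning is a seeded random search (default budget 25 draws; a budget of 1
simply takes the drawn configuration) over pinned spaces for three families
— RBF/linear SVM (C, gamma, kernel), random forest (trees, depth, split/leaf
minima, feature fraction) and gradient-boosted trees (depth, learning rate,
rounds, child weight, row/column subsampling) — scored by mean validation
accuracy on subject-wise 5-fold splits (3-fold below 5 training subjects),
ties keeping the first-sampled candidate. Synthetic SMOTE rows inherit their
base row's subject for grouping. Random search replaces the Bayesian
optimizer sometimes used for this task: it is reproducible under a seed and
dependency-free.

Window predictions are aggregated by majority vote to video labels, and
pooled across the frontal and sagittal videos of one subject × class ×
direction for the fused label (a view contributing more windows carries more
weight; a missing view degrades to the single-view vote). Ties break by
highest mean class score, then lexicographic class code. Metrics are
accuracy and weighted precision/recall/F1 (test sets are nearly
class-balanced by design, so weighted ≈ macro) plus one-vs-rest per-class
reports; the whole procedure is repeated for several trials differing only
in seed (inner folds, sampler and SMOTE draws), summarized as mean ± 1.96·SE
across trial × fold scores.

`max_features` on the drivers optionally caps the post-selection feature set
to the most significant survivors (smallest per-class p, ties by name). It
is a compute budget for the model fit — selection statistics are unaffected
— and is used by the test suite and the acceptance script to keep boosted-
tree fits tractable on one core.

## Interpretation

Permutation importance: shuffle one feature column, re-score accuracy,
repeat (default 10, seeded); importance = baseline − mean permuted score
with a 95% normal CI over repeats. Positive means the model relied on the
feature. Under the LOSO driver, importance is computed per outer fold on the
held-out subject's windows (the leakage-safe choice; scoring on held-out
data is a pinned decision the original analysis leaves open) and averaged
across folds, features outside a fold's selected set contributing exactly 0.
Per-feature records aggregate to keypoint-channel totals (sign-preserving
sums) and to a top-k × top-k channel/feature-type table for heatmaps.

## Problem sizes in tests and the acceptance script

End-to-end checks use the default study conditions — 10 subjects × 7 classes
× 2 views × 2 directions, reduced catalog, boosted trees, 2 trials of nested
LOSO with tuning budget 1 and a feature cap of 800 — about 3.4k windows and
8.1k candidate features per fold. Null-control, monotonicity and importance
checks use 6 subjects. These sizes were chosen so the full pipeline runs
end-to-end in minutes on one core while keeping every fold statistically
meaningful (≥ 280 videos in the main study).

## Known limitations

* The walker is kinematic and sinusoidal: no dynamics, ground-reaction
  forces or within-subject variability beyond noise; classes are far more
  separable than real pathology (end-to-end accuracies near 1.0 should be
  read as "the machinery works", not as clinical performance).
* Occlusions are independent Bernoulli draws; real occlusion is correlated.
* Frontal rescaling is only approximately idempotent (see above).
* The exact parameter grids behind the 783-entry catalog are a pinned
  choice; other grids of the same size over the same 37 types are equally
  defensible.
* Window-level inner validation scores include SMOTE-synthetic rows; they
  guide tuning only and are never reported.
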