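# Methods

This note documents the models, parameter choices and limitations behind
`gaitbalance`. It is written for someone who wants to judge what the
package's simulated results do and do not say about real cohorts.

## Study design being emulated

The target setting is a tabular gait dataset from a single lumbar IMU
(tri-axial acceleration at 100 Hz): a small minority class of people with
primary hereditary cerebellar ataxia (pwCA, n = 30 by default) against a
healthy majority (HS, n = 100). Seven features survive selection: stance
phase (%), cadence (steps/min), stride length (m), pelvic rotation (deg),
HR_AP, CV_steplength (%) and sLLE_AP (1/stride). Class-conditional means
and SDs of these features are the calibration defaults of the simulator
(`simdata.COHORT_MEANS` / `COHORT_SDS`). An a-priori power analysis for a
two-sided two-sample t-test (|d| ≥ 0.51, α = 0.05, power = 0.95, 1:1)
motivates the augmentation target of ~100 subjects per class, i.e.
N = 200 balanced rows; N = 1000 is the stress-test alternative.

## Synthetic data

### Signals

`simulate_trunk_signal` is a phenomenological, not biomechanical, model: a
sum of the first 20 stride-frequency harmonics with random phases and 1/f
amplitude decay. Design choices:

* **Symmetry** is the even-harmonic energy share in the AP and V axes (the
  ML axis gets the complementary split). This is exactly the quantity the
  harmonic ratio measures, so the parameter→index mapping is monotone by
  construction and verified by test.
* **Timing variability**: stride durations are i.i.d. Gaussian around the
  nominal period with the configured CV (%).
* **Instability**: the instantaneous stride phase is perturbed by the
  standardised x-coordinate of a Lorenz trajectory (σ = 10, ρ = 28,
  β = 8/3; RK4, one Lorenz time unit per stride), scaled by
  `instability_gain` × 0.02 cycles. The Lorenz system is a well-understood
  positive-Lyapunov driver, giving a tunable and testable route from
  "instability dial" to sLLE.
* Ground-truth stride boundaries are emitted directly; there is no event
  detection, by design — spatiotemporal features and stride events are
  inputs in the emulated protocol, not something this package estimates.

Class presets (`SIGNAL_PRESETS`) fix stride frequency, symmetry, timing CV,
step-length CV and instability gain once per class; step-length CVs equal
the cohort defaults (43.2% pwCA, 23.6% HS), the remaining values were
chosen once so the healthy preset is smoother, less variable and more
stable, and are not tuned further.

### Feature tables

`simulate_feature_table` draws per class from a multivariate normal with an
exchangeable correlation (ρ = 0.2 unless a matrix is supplied — only the
marginals are known from the cohort), optionally applies a monotone
sinh-arcsinh skew (standardised by Gauss–Hermite quadrature so target
means/SDs survive the transform), and rescales to the class means/SDs.

Outlier injection: when `outlier_rate` > 0 the base sample is first redrawn
inside the 1.5×IQR fences and outliers are planted 0.5–1.5 IQR beyond them.
This truncation is deliberate: it makes the injected set exactly
recoverable by an IQR detector, which turns the preprocessing test into a
ground-truth check instead of a statistical one. Real data have no such
guarantee.

What the simulator does **not** model: gyroscope channels, walking-direction
drift, sensor noise spectra, inter-feature nonlinear structure, missing
data, and any dependence of the feature table on the raw signal of the same
subject (tables and signals are generated independently). Tests passing on
this generator show the pipeline's algebra and logic are right; they do not
validate clinical performance.

## Gait indexes

* **HR**: each stride is cubically resampled to 100 samples (one exact
  period), Fourier amplitudes at harmonics 1–20 are taken from the DFT, and
  HR = Σ(first 10 even)/Σ(first 10 odd), inverted for ML; per-stride values
  are averaged. Before HR the signal is low-pass filtered (4th-order
  zero-phase Butterworth, 20 Hz): with ~1 Hz stride rates all 20 harmonics
  live below 20 Hz, so a high-pass at that cutoff would remove the entire
  gait band; the filter direction is configurable.
* **CV**: 100·SD/mean with sample SD (n−1) — per-subject step counts are
  small.
* **Embedding parameters**: delay from the first local minimum of
  histogram-AMI (16 equal-width bins) searched over τ 7–18 (argmin
  fallback); dimension from Kennel's false-nearest-neighbour test
  (Rtol = 17, Atol = 2) with acceptance at < 1% false neighbours.
  Near-duplicate embedded states (distance below 1e-10 of attractor size)
  count as true neighbours when the extra coordinate also coincides —
  needed for exactly periodic test signals.
* **RQA**: Euclidean recurrence at a radius chosen as the distance quantile
  that attains a 2.5% recurrence rate among considered pairs (the direct
  fixed point of bisecting to a target rate; a fixed-fraction-of-mean-
  distance rule is available). The main diagonal and the Theiler band
  |i−j| ≤ τ(m−1) are excluded by default; a `literal` mode keeps them,
  matching the textbook N² normalisation in which a constant series scores
  %rec = 100. %det uses l_min = 2. For long trials the RQA series is capped
  at 1200 embedded points (memory is quadratic in N; the statistics are
  rate-normalised and stable under the cap).
* **sLLE**: the unfiltered series is time-normalised to 100 samples per
  stride, embedded (m = 5, τ = 10 by default), nearest neighbours are
  constrained outside a one-stride Theiler window, and the mean log
  divergence is fitted over 0–0.5 stride; the slope is reported per stride.
  Window and units are a convention choice — the short-term variant used in
  gait work — and the periodic-limit and chaos-monotonicity tests pin its
  behaviour. On the Lorenz benchmark (dt = 0.01, m = 3) the generic
  estimator is fitted over the linear scaling region (1–3 time units) and
  agrees with a Benettin tangent-space oracle within a few percent.

## Preprocessing

IQR outlier replacement uses whole-column fences and medians (per-class
mode available). A single pass is the default, mirroring the emulated
protocol; note it is not idempotent (replacement tightens the fences), so a
`max_passes=None` fixed-point mode exists and is the one with a clean
idempotence guarantee. Yeo-Johnson lambdas are fitted by maximum
likelihood. Standardisation stores means/SDs for exact inversion and for
leakage-free train/test application. Collinearity filtering drops, per
offending pair, the non-preferred member (domain preferences: stance phase
over the other support phases; HR_AP and sLLE_AP kept for clinical
relevance), else the member with the larger mean |r|.

RF-importance selection appends a uniform-random noise column, averages
impurity importances over stratified CV folds and drops features not
exceeding the noise importance. Feature selection runs on the full dataset
by default — faithful to the emulated protocol and flagged here as a known
leakage caveat; the evaluation module's fold-scoped balancing is the
leakage-free path. One honest caveat found by simulation: a feature with no
signal is *exchangeable* with the noise column, so it falls at or below
noise only about half the time in any single run; the noise baseline
screens features reliably only on average, not per run.

## Balancing strategies

Undersampling deletes majority rows without replacement; oversampling
duplicates rows to N/2 per class; SMOTE interpolates x_i + u(x_nn − x_i)
toward one of the k = 4 minority nearest neighbours (majority topped up by
plain resampling when needed, e.g. at N = 1000). All augmentation
strategies keep every real row, and every output row carries provenance and
the indices of the real rows it derives from.

The GAN generator is noise(32) → dense(128) → LeakyReLU(0.01) → batch-norm
→ dense(d) → tanh; the discriminator is dense(64) → LeakyReLU → dense(1) →
sigmoid; binary cross-entropy, Adam (lr 2e-4, β1 = 0.5), batch 16, 2000
epochs by default (500 in tests and the acceptance script to bound
runtime). Features are min-max scaled to [−1, 1] (the tanh range) and
inverse-scaled after sampling. The GAN trains on minority rows only; the
ctGAN trains on the full table with the one-hot class label concatenated to
both the generator noise and the discriminator input, so sampling is
per-class by construction. Mode-specific normalisation from the broader
conditional-tabular-GAN literature is intentionally not implemented — the
architecture here is the plain conditional one. A single seed drives
weight initialisation, batch order and noise; identical seeds give
bit-identical loss histories.

## Evaluation

Stratified k = 4 CV with fold assignment computed in a canonical row order
(sorted by subject id), making all metrics invariant to table row order.
Two augmentation scopes: the default balances each training split only and
scores on real held-out rows (no synthetic row can descend from a test-fold
row — asserted via provenance); `pooled_augmentation` balances the whole
table before splitting, mirroring the emulated protocol at the cost of
synthetic rows in test folds. The classification threshold is 0.5; metrics are
computed from first-principles formulas (verified exhaustively against
scikit-learn over all small confusion tables), AUC by the rank statistic
(ties = 1/2, equal to concordant-pair counting). Bayesian optimisation uses
a Matern-5/2 GP with expected improvement over 256 random candidates per
iteration, 25 iterations / 5 random initial points by default.

## Consistency and explainability

KS tests compare real minority rows against synthetic minority rows
(asymptotic p by default, exact mode available), at α = 0.05. Shapley
attributions of the forest's minority-class probability are exact: all 2^M
feature subsets are enumerated and the coalition value is the
path-dependent tree expectation (splits on conditioned features follow the
observation; others average children by training cover). Efficiency
(base + Σφ = predicted probability) and the dummy axiom (never-split
feature → exactly 0) hold to machine precision and are tested. Ranking
analyses use ≥200 trees because forest sampling noise, not the attribution
method, dominates the ordering of closely matched features in small
ensembles. A permutation-sampling approximation is provided for models
beyond the enumeration limit (14 features).

## Problem sizes and numerical defaults

Tests and the acceptance script use: 15–30 simulated subjects per class for
index-level comparisons, 10 seeds for the balancing-trend benchmark at
N = 200 with 500-epoch generative models, 5 seeds for ctGAN KS consistency
and Shapley rankings, 100-instance oracle sweeps for RQA/KS/AUC, and a
30000-step Benettin integration for the Lorenz benchmark. These sizes make
the stochastic checks stable without being exhaustive; all are package
defaults, configurable at the call sites.

## Known limitations

* Signals and feature tables are generated independently; there is no
  subject-level coupling between raw-signal indexes and table rows.
* The GAN quality bar is distributional plausibility at small n, not
  high-fidelity synthesis; at 500 epochs a minority of features can drift
  past the KS threshold in unlucky seeds.
* The exact Shapley implementation is exponential in the feature count and
  intended for post-selection tables (≤ 14 features).
* Single-pass IQR cleaning can leave (and re-create) borderline outliers;
  use the fixed-point mode when idempotence matters.
* Reported per-fold SDs at k = 4 are coarse; seed-averaged summaries are
  the stable quantities.
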