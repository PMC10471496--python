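# Methods

`optoprop` analyzes dual-region two-photon calcium-imaging experiments in
which groups of 5–150 opsin-expressing neurons in primary somatosensory
cortex (S1) are photostimulated while the mouse reports detection by
licking, and activity is recorded simultaneously in S1 and the downstream
secondary somatosensory cortex (S2). This note documents the models,
estimators, numerical choices, and the synthetic data the tests run on.

## Preprocessing

Raw traces are corrected for neuropil contamination, `F = F_soma − 0.7 ·
F_neuropil`, and converted to ΔF/F against the whole-session mean,
`ΔF/F = (F − F̄)/F̄`. Cells with non-positive session mean (possible after
neuropil subtraction; the guard threshold is `1e-6` times the 95th
percentile of all means) are dropped and reported, as are cells with
max ΔF/F > 10 (transients that large are unlikely to arise from spikes).
Trials are cut into tensors spanning 2 s before to 8 s after onset
(onset = photostimulation for go, sham-spiral onset for catch, reward
delivery for reward-only). Frames with the stimulation laser on, plus two
frames on either side, are blanked; window lengths round half-up and the
stimulation frame count is `ceil(duration × rate)`. Post-onset activity is
baselined by subtracting the mean over the unblanked 2-s pre-onset window.

Blanked frames never enter any statistic. Because the two-frame blanking
pad precedes trial onset on go trials, every pre-onset computation
(baselining, the 0.5-s pre-stimulus window, the 6.5-s pre-trial segments,
the timescale baseline) selects unblanked frames explicitly; the suite
verifies end-to-end that randomizing blanked samples changes no output.

## Behavior

Outcomes follow signal detection: a go-trial lick in [150 ms, 1 s) is a
hit; earlier licks are "too-soon" (likely random, excluded); catch-trial
licks are false positives. `d′ = z(hit rate) − z(FA rate)` with the
log-linear extreme-rate correction (0 → 1/(2n), 1 → 1 − 1/(2n)); the FA
rate pools all catch trials of a session. Sessions pass QC iff
d′(150 targets) ≥ 0.95 and pooled d′(40∪50) ≥ 0.5. The psychometric curve
is `d′(n) = dmax / (1 + exp(−k(n − x50)))` clamped at 0 (lower bound
adjusted to d′ = 0), fit by bounded nonlinear least squares with all
points weighted equally; `x50` is the half-maximum in targeted cells.

## Pre-stimulus population metrics and the SNR model

Per trial, cells are averaged over the last 0.5 s of unblanked pre-onset
frames; the mean and across-cell sample variance (ddof = 1) of that vector
are the population mean and variance. The variance is log-transformed —
the transform is selected by comparing normal vs log-normal maximum-
likelihood fits through KL divergence against the empirical histogram
(50 equal-width bins, Laplace smoothing) — and both metrics are z-scored
across trials within a session before any outcome split.

The SNR model is a pooled logistic regression of hit/miss on the number
of targeted cells (signal) and the z-scored log population variance
(noise), with per-coefficient two-sided tests and McFadden's pseudo-R²
(`1 − ll_model/ll_null`) for the full and both single-regressor models.
The 2-D hit-probability surface bins trials by z-variance (width 0.5) ×
target count; the 1-D SNR curve projects occupied bins orthogonally onto
the normalized anti-diagonal (low variance, high count = high SNR) and
averages bins sharing a projection coordinate.

## Effective recurrence from covariance width

The estimator views the population as a discrete-time linear recurrent
network sampled at the frame rate, `r[t+1] = W r[t] + input`, with i.i.d.
random coupling of spectral bound R < 1. Three steps per subsample
(15 trials × 6.5 s of pre-trial activity, 1,000 subsamples by default,
averaged):

1. **Shared-activity removal.** ML factor analysis estimates loadings of
   the low-dimensional shared component; the shared part is reconstructed
   by *orthogonal projection* onto the loading subspace and subtracted.
   Projection (rather than posterior-mean scores) is deliberate: the
   posterior mean is shrunk by the factor posterior covariance, which
   provably leaves `Cov(residual, scores) = ΛG ≠ 0` and hence shared
   leakage in the residuals. Default `n_factors = 3`: shared input enters
   through the dynamics, so its spatial footprint spans a Krylov subspace
   (B, WB, W²B, …), not a single direction; with one factor the leakage
   biases R upward by ≈ +0.12 at R_true = 0.5 (N = 500), with three the
   recovery error stays within ±0.03 across R ∈ {0.5, 0.8, 0.95}. Five
   factors are reported for the variance-explained profile.
2. **Bias-corrected width.** `abar` is the mean variance. The raw spread
   of off-diagonal covariances mixes the true width with estimation
   noise; covariances computed on two disjoint temporal halves carry
   independent noise, so the mean centered cross-product of their
   off-diagonal entries estimates the squared true width (floored at 0).
   On white noise (50 cells × 50,000 frames) the corrected ratio is
   < 0.001 versus a raw ratio two orders larger.
3. **Inversion.** For the linear map with i.i.d. Gaussian coupling of
   entry variance R²/N, summing the leading-order path pairings of the
   stationary covariance `C = Σ_k W^k (Wᵀ)^k` gives

       abar = σ²/(1−R²),   σ_CC² = σ⁴ R⁴ / (N (1−R⁴)(1−R²)²)

   so `δ² ≡ (σ_CC/abar)² = R⁴/(N(1−R⁴))` and

       R̂ = ( N δ² / (1 + N δ²) )^¼ .

   The relation is monotone: wider non-shared covariance distributions
   mean stronger effective recurrence, and R → 1 is the near-unstable,
   strongly amplifying regime. A simulation-calibrated inversion table
   (exact stationary covariances from the discrete Lyapunov equation
   `C = WCWᵀ + I` on an R grid) ships as an independent cross-check. At
   finite N the table ensemble — rescaled to an exact realized spectral
   radius — sits slightly below the asymptotic formula because the
   realized edge of a finite Ginibre spectrum exceeds the ensemble bound;
   the offset shrinks with N (≈ 0.02 in R through R = 0.8 at N = 800,
   ≈ 0.03–0.04 at R = 0.95) and is immaterial at the N = 50,000 used for
   real-data inversion. `N_assumed` defaults to 50,000 (the scale of the
   local cortical network); recovery benchmarks set it to the simulated N.

Full-loop recovery (simulate → factor removal → corrected width →
inversion) at N = 500 and 30,000 frames of rate data lands within ±0.03
of R_true (median over seeds) for R_true ∈ {0.5, 0.8, 0.95}.

## Network response timescale

τ_post is the exponential decay time of the mean targeted-cell response
after photostimulation: 250-ms-stimulation trials only (5–50 targets),
response averaged up to 5.5 s post onset, baselined to the 6.5-s
pre-trial mean, 10 trials per subsample × 1,000 subsamples, `A·exp(−t/τ)`
fit by nonlinear least squares on unblanked frames (τ bounded in
[1 ms, 60 s]; fits at the bound or with non-positive amplitude count as
failures; a session is flagged if more than half fail). For the same
linear model the slow collective mode decays by R per frame, so
`τ_post ≈ −dt/ln R ≈ dt/(1−R)`; `relate_timescale_recurrence` compares
the one-parameter law `τ = c/(1−R)` (closed-form least squares in c)
against a two-parameter linear regression by r².

## Decoding

One L2-penalized logistic regression per timeframe per fold (features:
one ΔF/F scalar per cell), four-fold stratified cross-validation with a
3:1 split, majority class subsampled once per pair for balance (chance =
0.5). The penalty strength λ = 0.001 (scikit-learn `C = 1/λ`) is a
config default reproducing a sweep over 1e-7…1e3. Timepoints at which any
selected trial is blanked are skipped. Cross-condition evaluation applies
the stored per-fold models to trials of a third label (never in
training) and reports the fraction classified as positive. Session-level
significance uses a two-sided Wilcoxon signed-rank against chance per
timepoint, Bonferroni-corrected over testable timepoints.

## Excitation–inhibition balance

A cell is excited/inhibited for a trial set if the two-sided Wilcoxon
signed-rank of its trial-wise mean baselined response (0–1.5 s, unblanked
frames) against zero is significant at α = 0.05, with the median's sign
choosing the label (window and test are configurable; fewer than 5 trials
yields a flagged neutral). Fraction-versus-strength lines use weighted
least squares with inverse-variance weights clipped to their [25th, 75th]
percentile range; equal weights reduce exactly to OLS. Excitation–
inhibition correlations between regions are compared with Steiger's Z for
dependent, non-overlapping correlations (Pearson–Filon covariance,
Fisher-z comparison); a pair-swap permutation oracle backs the
implementation in tests, with an agreement band of 0.04 that reflects the
oracle's own Monte-Carlo spread (~0.01 at 10,000 permutations) plus the
asymptotic-vs-exact gap.

## Synthetic sessions

The generator emulates the experiment's statistical structure:

- **Dynamics**: discrete-time at the 30-Hz frame rate (the analysis grid;
  the downstream theory is formulated on the same linear map). Coupling
  is i.i.d. Gaussian rescaled to spectral radius R_true (default 0.9, in
  the strongly recurrent regime observed in cortex), plus a rank-one
  uniform component constructed so the uniform vector is an exact real
  eigenvector at R_true, with the i.i.d. bulk shrunk to 0.9·R_true. The
  collective mode is what gives targeted perturbations a slow mean decay
  (with pure zero-mean coupling E[W^k] = 0 and the mean response carries
  no recurrence signature); for the covariance estimator it acts as one
  more shared direction, removed by factor analysis. Shared input is a
  low-dimensional AR(1) latent (default 2 dims, coefficient 0.9) with
  Gaussian private noise.
- **Photostimulation**: additive drive into targeted cells for
  ceil(duration × rate) frames — 250 ms for 5–50 targets, 760 ms for
  150 targets.
- **Calcium**: Poisson spikes with intensity `spike_gain · softplus(rate)`
  (softplus avoids hard zero-gradient regimes; the spiking model is a
  stand-in judged only by downstream property tests), convolved with a
  difference-of-exponentials GCaMP6s-like kernel (rise 0.18 s, decay
  1.4 s — named-sensor defaults, configurable); soma fluorescence adds a
  `neuropil_mix` share of the population-average signal (contamination)
  plus shot noise, and the neuropil channel measures that contamination.
- **Schedule**: a pre-session block of 10 reward-only trials at 10-s
  spacing, then go/catch trials at exact 1/3 strong-go : 1/3 variable-go
  : 1/3 catch proportions with no more than three consecutive trials of
  the same type (a constrained sequential draw from fixed pools with a
  completability check — naive rejection biases proportions and
  deadlocks), onsets separated by the 1-s response period + 5-s ITI +
  4–6-s uniform lick withhold. Variable counts come from
  {5,10,20,30,40,50}.
- **Outcomes**: `P(hit) = logistic(β₀ + β_n·n + β_v·v)` with v the
  z-scored pre-stimulus log population variance; catch trials are false
  positives at a 0.1 base rate; responders lick uniformly in 150–1000 ms.
  Defaults β₀ = −2.0, β_n = 0.15, β_v = −0.5 are calibrated (see
  `calibrate_outcome_model`) so the analytic psychometric half-point of a
  500-trial session is ≈ 22 targeted cells. The analytic reference applies
  the identical d′ pipeline — including the extreme-rate correction at the
  design's expected per-condition trial counts — to the exact expected
  rates; an uncorrected asymptotic half-point would differ by ≈ 10 cells
  purely through the d′ ceiling.

What the generator does **not** emulate: spatial optics (PSF, off-target
excitation), conductance-based or nonlinear neurons, plasticity, slow
drift, motion artifacts, or realistic lick dynamics. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions — linear dynamics, Poisson spiking, stationary noise — not
robustness to every property of real recordings. In particular, applying
the recurrence estimator to ΔF/F inherits the indicator's temporal
smearing, which is acknowledged and not corrected; recovery benchmarks
run on rate data.

## Validation experiments and problem sizes

`optoprop.experiments` holds the self-contained experiments the test
suite and `scripts/acceptance.py` run; sizes were chosen for minutes-scale
runs on one CPU:

- recurrence recovery: N = 500 cells, 30,000 frames, R ∈ {0.5, 0.8, 0.95},
  10 seeds (float32 dynamics; FA loadings fit on an 8,000-frame stride);
- bias-correction null: 50 cells × 50,000 frames;
- timescale law: N = 200, six-point R grid, 80 trials of 50-target
  stimulation at amplitude 40 (a strong probe is legitimate in a linear
  model and keeps the post-blanking tail measurable at small R),
  100 subsamples of 15 trials;
- psychometric recovery: 10 sessions × 500 trials (a ~90-min session at
  one trial per ~11 s);
- SNR recovery: 8 sessions × 400 trials (> 2,000 scored go trials);
- decoding checks: 100 label permutations at one timepoint, and a
  48-trial injected-signal session with reward-only evaluation.

## Known limitations

- The closed-form inversion is leading-order in 1/N; at N of a few
  hundred it underestimates R by ~0.01–0.03 (visible in the recovery
  experiments), within the stated recovery tolerance. The Lyapunov-
  calibrated table quantifies the residual finite-size offset.
- The split-half width correction assumes the two halves are independent;
  with strong temporal autocorrelation (R → 1) the shared boundary
  contributes a small positive coupling, negligible at the segment
  lengths used.
- Steiger's test is asymptotic; at small session counts the permutation
  comparison is the more trustworthy arbiter.
- `optoprop recurrence` (CLI) estimates from the tensor container's 2-s
  pre-onset windows because the container does not retain the 6.5-s
  pre-trial history; the library API (`estimate_recurrence_from_activity`)
  on session-level traces is the reference path.
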