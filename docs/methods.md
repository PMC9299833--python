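# Methods

Models, assumptions, parameter defaults and numerical choices behind
`synhomeo`. All defaults live in the dataclasses of `synhomeo.synthgen` and
the keyword defaults of the analysis functions; this note records why they
are what they are.

## 1. Miniature-event traces and detection

### Generative model

A recording of duration `T` sampled at `dt` contains `K ~ Poisson(rate * T)`
events at uniform onset times. Each event is a peak-normalized
biexponential kernel

    w(t) = (1 - exp(-t / tau_r)) * exp(-t / tau_d),  w normalized to max 1,

scaled by a lognormal amplitude with arithmetic mean `amp_mean` and
coefficient of variation `amp_cv` (lognormal because mini amplitudes are
positive and right-skewed). Events sum linearly onto white Gaussian noise of
standard deviation `noise_sd`; polarity -1 renders them as inward currents.

Assumptions: linear summation (no receptor saturation), stationary rate,
white noise (no 50/60 Hz hum, no baseline drift), perfectly stereotyped
kinetics. These idealizations make ground-truth scoring exact but
overstate how easy real recordings are; see Limitations.

### Defaults and rationale

- `rate = 2 Hz`, `duration = 60 s`: ~120 events, enough for stable
  per-trace sensitivity estimates while keeping overlap between events rare
  (~2% of events start within one decay time of another).
- `rise_tau = 0.5 ms`, `decay_tau = 5 ms`, `dt = 0.1 ms`: typical fast
  glutamatergic mEPSC kinetics at 10 kHz sampling.
- `noise_sd = 0.2` with `amp_mean = 1`: amplitude signal-to-noise 5, a
  moderate operating point at which threshold-4 detection is challenged but
  not hopeless.
- `amp_cv = 0.10`. This is the one deliberately unphysiological default.
  The detection criterion (below) estimates amplitude/noise, so at SNR 5 and
  threshold 4 every event whose amplitude falls below roughly 0.8x the mean
  sits at or below the detection boundary; adding the sampling noise of the
  criterion itself (SD ~0.35-0.45 at these settings), a population CV above
  ~0.12 necessarily pushes >10% of events under the threshold and no
  detector using this statistic can reach 90% sensitivity. Physiological
  mini-amplitude CVs are 0.2-0.5; with those the same detector yields
  sensitivities of ~0.7-0.87 at threshold 4. The default therefore
  represents a "calibration regime" in which the detector's advertised
  operating point is achievable, and users simulating realistic populations
  should expect — and will observe — lower sensitivity. This limitation is
  intrinsic to fixed-threshold template matching, not to the implementation.

### Detector

`cb_detect` slides the template across the trace and, at every lag, fits
`scale * kernel + offset` by least squares. The detection statistic is the
Clements-Bekkers criterion: fitted scale divided by the standard error of
the fit residuals, `SE = sqrt(SSE / (N - 1))` with `N` the template length.
Peaks of the criterion above the threshold (default 4) separated by at least
`min_separation` (default rise time + 2 ms) become events.

- All sliding sums are computed with cumulative sums and one FFT
  overlap-add convolution (`scipy.signal.oaconvolve`), so detection over a
  600,000-sample trace takes well under a second and is numerically
  identical to the direct per-lag least squares (tested against an explicit
  `lstsq` oracle).
- Template length defaults to `rise_tau + 2 * decay_tau` (10.5 ms at the
  default kinetics). Longer templates (e.g. 5 decay constants) average over
  more noise but overlap the decaying tails of neighboring events, which
  both misses events riding on tails and inflates the residual SE; an
  empirical sweep showed sensitivity 0.896 at 10.5 ms vs 0.859 at 30.5 ms
  with false-discovery rates of ~0.002 in both cases. Short templates trade
  a slight loss of amplitude precision for localization robustness.
- Noiseless traces make the residual SE collapse toward 0 and the criterion
  toward infinity; the implementation guards the division and caps the
  statistic, and tests of exactness use a wide separation window because in
  that degenerate regime decaying shoulders also exceed any finite
  threshold.

`match_events` scores detections against ground truth by greedy one-to-one
nearest-time matching within a tolerance (default 5 ms), reporting
sensitivity, false-discovery rate and relative amplitude bias. Measured
performance at the defaults over 20 seeds: sensitivity 0.934 (min 0.903),
FDR 0.002, amplitude bias +2% (detection misses the dimmest events, so the
detected-amplitude mean is slightly high).

## 2. Trains, quantal content and the RRP

### Depletion-replenishment model

For each 60 Hz train of 60 stimuli (5 trains averaged):

    A_i = q * pr * N_i * (1 + eps_i),      eps_i ~ Normal(0, trial_noise_cv)
    N_{i+1} = clip(R_i + k_replenish * dt * (N0 - R_i), 0, N0),
    R_i = N_i * (1 - pr),  N_1 = N0,  dt = 1/freq.

With `k_replenish = 0` the amplitudes are exactly geometric,
`A_i = q*pr*N0*(1-pr)^(i-1)`.

### Estimators

`cumulative_profile` averages trains pointwise (raising an error on ragged
trains) and accumulates. `rrp_from_cumulative` fits an ordinary least
squares line to the last `last_k = 15` cumulative points against stimulus
time and reports the intercept at t = 0; dividing by the group-mean mini
amplitude gives the pool in quanta. `pr_and_ppr` returns
`p_r = A_1 / intercept` and `PPR = A_2 / A_1`.

- In the noise-free geometric regime the estimator recovers `q*N0` and `pr`
  to better than 1e-4 relative error (the residual error is the geometric
  tail `(1-pr)^45`, far below 1e-4 for pr >= 0.3).
- The intercept of an OLS line is invariant to fitting against stimulus
  index instead of time only when the abscissa is zero-based consistently;
  the implementation fits against time of the 0-based stimulus offset, which
  equals the index fit's intercept (tested).
- With `k_replenish > 0` the method is biased (it reports the recurrence's
  extrapolated intercept, not `N0`); the package reproduces that textbook
  bias exactly — verified to 1e-9 against a brute-force recurrence
  simulation — rather than correcting it, because the bias is a property of
  the published method being modeled. Strong replenishment shrinks the
  depletion transient and lowers the intercept below the true pool.
- Negative intercepts (facilitating or noisy inputs) are flagged with a
  warning and returned unclamped.
- Quantal content divides evoked amplitudes by the *group mean* mini
  amplitude, with minis and evoked responses drawn from different cells —
  mirroring the experimental design in which the two measurements come from
  different NMJs. Each NMJ's mean contributes equally regardless of its
  event count.

Defaults `n0 = 500`, `pr = 0.5`, `q = 1` give ~50% depression over the
train and intercepts resolvable with 5 trains at 10% trial noise (median
pool-recovery error ~1.5%).

## 3. Screens and statistics

### Screen generator

Each line contributes `3 + Poisson(1)` NMJs truncated at 12 (mean ~4,
range 3-12, matching the small per-genotype samples typical of screens).
Per-NMJ means are Gaussian around the line mean with between-NMJ CV 0.15 —
a deliberate simplification (real between-animal variability is larger and
right-skewed) chosen so that the planted-effect benchmark (a halved EPSC at
n = 4) is near the detection boundary rather than trivial. PhTX multiplies
quantal size by `phtx_q_scale = 0.6` (a 40% mini reduction, the standard
sub-blocking concentration's effect); PHP-competent lines multiply quantal
content by the reciprocal so the EPSC is conserved, PHP-deficient lines do
not. Wild-type reference groups (n = 16) with and without PhTX are
appended.

### Hit calling

`volcano_screen` fits one pooled one-way ANOVA over all lines plus the
reference and compares each line to the PhTX-treated wild type with the
Tukey-Kramer adjustment, computed directly from the studentized-range
distribution:

    q_i = |m_i - m_ref| / sqrt(MSE/2 * (1/n_i + 1/n_ref)),
    p_i = SF_studentized_range(q_i; k groups, df_error).

With k = 2 this reduces exactly to the pooled two-sample t-test (tested).
Flags at `p <= 0.01` are "smaller"/"larger" by the ratio to the reference.
Calibration: null screens flag ~0% of lines; a planted 0.5x line (n = 4 vs
n = 16 reference, CV 0.15) is flagged in >= 95% of seeds. `hit_rate_percent`
truncates (does not round) the percentage, matching how such fractions are
conventionally reported.

`twoway_php_test` fits `value ~ genotype * condition` with type-II sums of
squares (sensible under unbalance) via statsmodels and runs Tukey HSD over
the four cells. The interaction test's type-I rate is calibrated (tested at
n = 400 simulations). `compare_two` gates on Shapiro-Wilk normality (either
group rejecting -> Mann-Whitney), then Levene (reject -> Welch), else
Student's t; zero-variance groups fall back to Mann-Whitney with a warning.

### Power

`power_two_sample_t` uses the noncentral t distribution
(df = 2n - 2, noncentrality d*sqrt(n/2), two-sided alpha = 0.05);
`min_n_power` searches upward from n = 2. Validated against an independent
numeric integration of the conditional-normal representation of the
noncentral t. Reference values: d = 1.0 -> n = 17, d = 0.5 -> n = 64,
d = 10 -> n = 2 per group at 80% power.

## 4. Spatial proximity of puncta

### Generator

Boutons are jittered circles (radius 1.25 um, 16 vertices, +/-20% radial
jitter) — a crude but adequate stand-in for bouton outlines, since the NND
null only needs a bounded region of realistic size. Per-channel puncta
counts are Poisson(12) floored at 1. Reference points are uniform;
coupled target points (fraction `coupling_fraction`) sit at a uniformly
chosen reference point plus isotropic Normal(0, 50 nm) displacement,
redrawn until inside the polygon.

### Monte-Carlo NND test

For each bouton the observed mean reference-to-target nearest-neighbor
distance (cKDTree) is compared with the mean over `n_rand = 100` uniform
re-placements of both channels (same counts, same polygon; vectorized
rejection sampling and broadcast distance minima, ~0.3 s per 130-bouton
dataset). The global p-value is a two-sided **paired** Student's t over the
per-bouton (observed, randomized-mean) pairs.

The paired test is the package's default after explicit calibration: the
observed and randomized means share each bouton's geometry and point counts,
a strong positive correlation. An unpaired two-sample t ignores it and is
drastically conservative (0 rejections in 30 null datasets at alpha = 0.05);
the paired test's measured size over 2,000 independent null datasets is
0.051 at alpha 0.05 (0.011 at 0.01). Under coupling (fraction 0.8,
sigma = 50 nm) the paired test yields p < 1e-3 in 10/10 datasets. The
unpaired variant remains available (`paired=False`).

`n_rand = 100` keeps the Monte-Carlo noise of the per-bouton randomized
mean well below the between-bouton spread (and that noise only widens the
paired differences symmetrically; it does not bias the test).

### Costes block-scramble test

Pixelwise Pearson r between two channels over all PSF-sized blocks
(default 3 px = 60 nm at 20 nm pixels) lying fully inside the mask; the
null permutes channel-A blocks among their positions (`n_scramble = 200`)
and the p-value is the add-one exceedance fraction, so the smallest
attainable p is 1/(n_scramble + 1). Degenerate inputs (constant channel,
fewer than two blocks) raise errors rather than returning fake p-values.
Null calibration is tested empirically.

## 5. Morphometry

Rendering: each punctum is an isotropic Gaussian (sigma 60 nm ~ a gSTED-like
PSF) with unit peak on a 20 nm grid padded by 3 sigma.

Quantification chain (defaults follow the standard active-zone counting
recipe): maximum-intensity projection; rolling-ball background subtraction
with a 1 um radius ball (50 px at 20 nm — a fixed *physical* radius, so
pixel size matters); 3x3 median filter for the mask image only; binary mask
at >= 15% (or 35%) of the filtered image's maximum; 8-connected component
labeling; punctum density = count / HRP-membrane-mask area (um^2);
per-punctum mean intensity measured on the background-corrected but
*unfiltered* projection (median filtering flattens peak intensities, so it
is deliberately excluded from the measurement image). Fraction-of-max
thresholds are scale-invariant but sensitive to a single hot pixel — which
is exactly why the median filter precedes the mask. On rendered,
well-separated puncta the 15% count is exact and density x area equals the
count to machine precision.

## 6. Pipeline and reproducibility

- Every generator takes an explicit integer seed into
  `numpy.random.default_rng`; no global state.
- Pipeline stage seeds are `sha256(f"{seed}:{stage}") % 2**31` — stable,
  independent across stages, and insensitive to stage order, so adding a
  stage never shifts another stage's stream. The same derivation is used by
  `scripts/acceptance.py` for its named sub-computations.
- Two pipeline runs with the same config are byte-identical across all
  outputs (tested).
- Lognormal amplitudes with prescribed arithmetic mean m and CV c use
  `sigma^2 = ln(1 + c^2)`, `mu = ln m - sigma^2/2`.
- Uniform sampling in polygons is batch rejection sampling from the
  bounding box with vectorized point-in-polygon tests; acceptance ratio is
  area/bbox-area, so near-degenerate polygons are rejected up front.

## 7. Generator realism and limitations

- Mini traces: no baseline drift, line noise, seal instabilities or
  multivesicular bursts; amplitude CV 0.10 is below the physiological
  0.2-0.5 range for the reason given in section 1. Detection metrics
  reported here are upper bounds on real-data performance.
- Trains: deterministic depletion with multiplicative Gaussian trial noise;
  no facilitation term, no calcium-dependent replenishment, no postsynaptic
  receptor desaturation. The RRP estimator inherits the known biases of
  back-extrapolation (underestimation with fast replenishment).
- Screens: Gaussian between-NMJ variation with a single shared CV; no
  batch/day effects, no correlation between mEPSP and EPSC noise within a
  line.
- Boutons: convex-ish jittered circles rather than traced outlines; puncta
  are points, not extended objects; channel coupling is isotropic.
- Images: Gaussian PSF, additive Gaussian noise only (no Poisson photon
  statistics), no chromatic offset between channels.
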