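# Methods

This note documents the models, numerical choices and limitations of
`dmnaec`, in the order the pipeline runs them.

## Synthetic cohorts (`dmnaec.cohort`)

**What is emulated.** Two-group resting-state cohorts (default 26 HC,
27 SCD; 300 s at 1000 Hz) of 12-ROI DMN source time series whose
pairwise envelope couplings are programmable per band, with the SCD
group receiving extra delta- and gamma-band coupling on PCC–LTC and
PCC–PCu edges.

**Generative model.** Each ROI's signal is a sum over bands of
unit-variance narrowband Gaussian components (zero-phase FIR-filtered
white noise), scaled by a per-band amplitude, plus a broadband white
noise floor (SD 0.1). Filtering white Gaussian noise — rather than an
oscillator model — keeps the signals jointly Gaussian, for which the
envelope-correlation calibration below is exact in the large-sample
limit.

**Coupling construction.** For a coupled pair $(i, j, r)$ in band $b$,
both ROIs mix a shared narrowband component $s_{ij}$:
$x_i = \sqrt{1-\rho_i}\,n_i + \sum_k \sqrt{r_k}\, s_k$, where the sum
runs over ROI $i$'s pairs in that band (in sorted-pair order) and
$\rho_i = \sum_k r_k$ is its total shared variance. This keeps every
band component at unit variance and makes the latent signal
correlation of each pair exactly $r$. A configuration demanding
$\rho_i > 1$ for any ROI is rejected (the private weight would be
imaginary); this also caps the node strengths the mechanistic
generator can express at well below the published magnitudes of ~3–4,
which is why group-level calibration against printed values uses the
summary generator instead (below).

**Envelope-correlation calibration.** For jointly Gaussian narrowband
pairs with signal correlation $r$, the amplitude envelopes are
correlated Rayleigh variables with correlation
$(\pi/2)\big(\,_2F_1(-\tfrac12,-\tfrac12;1;r^2)-1\big)/(2-\pi/2)$,
which is $r^2$ to first order but runs ~5 % low at large $r$ (0.464 vs
0.49 at $r=0.7$). Tests check Monte-Carlo AEC means against a
10×-duration brute-force simulation (3·SE) and against this closed
form; the nominal $r^2$ is asserted only within 0.05.

**Defaults.** Baseline (both groups): a PCC-centred core
(PCC_L–PCC_R 0.15, PCC_L–PCu_L 0.12, PCC_R–PCu_R 0.12,
PCC_L–IPL_L 0.10, scaled 1.4× at alpha, 0.8× at the non-alpha/beta
bands) — nonzero HC connectivity with a resting alpha emphasis. SCD
extra: $r = 0.35$ on PCC_L–LTC_R, PCC_R–LTC_L and PCC_R–PCu_R at
delta, gamma1 and gamma2, mirroring the reported hyperconnected edges;
0.35 is the largest round value that respects the $\rho \le 1$ budget
on PCC_R alongside the baseline. Band amplitudes (delta 1.0, theta
0.7, alpha 1.2, beta 0.6, gamma1 0.35, gamma2 0.25) sketch an
alpha-dominant resting spectrum with a 1/f-like decline; they do not
affect AEC (which is amplitude-scale invariant), only the relative
band-power tables.

**Complaint counts.** SCD subjects report 1–12 complaints, drawn as
Poisson(intercept + slope·S + noise) clipped to [1, 12], where S is
the subject's expected gamma1 PCC strength under its configured
couplings (defaults 2.0, 3.0, 0.5). This yields a positive, noisy
association between gamma1 PCC strength and complaints — the
qualitative shape of the reported correlation — without asserting an
effect size the data cannot pin down.

**Seeding.** Per-subject generators spawn from the master seed with
the subject index as spawn key; identical configurations reproduce
cohorts bit-identically.

**Summary-level generator.** `simulate_strength_summaries` draws
independent Gaussians per (group, ROI, band) cell from the published
means ± SDs (e.g. delta left-PCC HC 3.1 ± 0.9 vs SCD 4.4 ± 1.6). It is
the basis for the ROC reproduction targets, where only the score
distributions matter.

**What a green test does not establish.** The generator has no 1/f
background beyond the white floor, no sensor-level physics, no
inter-subject variability in coupling strength (within-group subjects
differ only by noise realization), and stationary coupling. Recovery
results therefore speak to the pipeline's correctness, not to
clinical effect sizes.

## Preprocessing (`dmnaec.preprocess`)

Notch filtering is zero-phase (forward–backward) IIR at the powerline
base and all harmonics below Nyquist. All notches share one absolute
bandwidth; `q` (default 30) describes the complete two-pass operation,
so the single-pass notch is designed at 2q. This attenuates each line
far beyond 30 dB while removing <5 % of white-noise variance — a
constant per-notch Q would progressively widen the high harmonics.

Artifact removal is signal-space projection: epochs around supplied
event samples (≥10 required) are averaged, and the top-k left singular
vectors of the event-locked average form an orthonormal projector
(default k=1 per artifact type; the number of components removed per
artifact is not standardized in practice). Projection $x - UU^\top x$
is idempotent to machine precision. Visual segment rejection is
modeled as a boolean keep-mask (JSON intervals) honoured by the Welch
and AEC stages.

All filters in the package are zero-phase: envelope timing must not be
skewed across ROIs, and relative envelope timing is what AEC measures.

## Source estimation (`dmnaec.inverse`)

$W = R G^\top (G R G^\top + \lambda^2 C)^{-1}$ with depth weights
$R_{ii} = \lVert g_i \rVert^{-2\gamma}$ normalized to max 1,
$\gamma = 0.5$ (the common default; the exponent is rarely reported).
The regularization convention is $\lambda^2 = 1/\mathrm{SNR}$ (0.33 at
SNR 3); the alternative $1/\mathrm{SNR}^2$ convention is a config
switch because both are in circulation. Rank-deficient noise
covariances are diagonally loaded with $10^{-6}\,\mathrm{tr}(C)/n$
(logged); a system condition number above $10^{12}$ is an error. With
$\gamma = 0$ and identity noise, $W$ reduces to classic Tikhonov MNE
(verified against a direct oracle). ROI averaging is the plain
arithmetic mean of member sources; opposite-oriented members cancel —
deliberate, documented behaviour, with no sign-flip heuristic.

## Spectra (`dmnaec.spectral`)

Welch PSD with 5-s Hann windows at 50 % overlap (0.2 Hz resolution at
1 kHz). Masked recordings are split into contiguous clean segments;
per-segment Welch averages are pooled with window-count weights, and
at least two windows are required. Relative band power integrates the
PSD (trapezoid, closed band edges on the grid) and divides by total
power over 2–90 Hz — the span of the defined bands; the denominator
range is a package decision, since "total power" conventions vary, and
the inter-band gaps (4–5, 7–8, 12–15, 29–30 Hz) count toward the
denominator only, so the six bands sum to ≤1. Peak frequency is the
within-band argmax with ties broken toward the lower frequency.

## Connectivity (`dmnaec.connectivity`)

Envelopes come from the zero-phase FIR bandpass (transition width
0.25·min(f_lo, bandwidth), Hamming window) followed by the analytic
signal magnitude. One filter-transient length — max(1 s, 3/f_lo) — is
trimmed at each end before correlating, and AEC is computed over the
full remaining (masked) recording rather than per epoch: no epoching
convention is standard for resting AEC, and full-series correlation
uses all the data. No orthogonalization/leakage correction is applied:
plain AEC is the metric being modeled, and the synthetic ROIs have no
leakage. Zero-variance envelopes produce zeroed entries with a warning
rather than NaNs. The diagonal is fixed at 0 so node strength needs no
self-term logic.

## Group statistics (`dmnaec.stats`)

The two-level group comparison is run as one-way ANOVA (F = t² for two
groups, checked to 1e-10). FDR is Benjamini–Hochberg over all
ROI × band cells per measure (12 × n_bands for power and for
strength), cross-checked in tests against a brute-force step-up
implementation. Edge-level follow-ups use two-sample t tests at
α/m with m an explicit config value (default 11, the published
convention; its derivation is not recomputable from first principles,
so it is configuration, not inference). The demographics helpers run
pooled t tests (including from printed summaries) and chi-squared
without continuity correction (matching published two-level
contingency p-values; correction available). Spearman uses average
ranks and a one-tailed (positive) alternative.

## Discrimination (`dmnaec.roc`)

Empirical AUC is Mann–Whitney U/(n₀n₁) with midrank ties — identical
to the trapezoidal curve area — with SCD as the positive class. The
operating point maximizes Youden's J; ties resolve toward higher
specificity (the lowest-FPR maximizer). The criterion is recorded in
the output since published sensitivity/specificity pairs rarely name
theirs. `binormal_auc` provides the Gaussian closed form, and
`monte_carlo_summary_auc` the finite-sample mean over replicate
cohorts drawn from group summaries — for n₀=26, n₁=27 the
finite-sample mean sits within ~0.001 of the closed form.

## Numerical details

* FIR lengths force odd tap counts so 'same'-mode convolution is
  exactly zero-phase; overlap-add convolution keeps 300-s, 1-kHz,
  12-ROI subjects tractable (≈1 s per subject per band).
* Band purity of the generator (≥95 % in-band power) is assessed with
  10-s Welch windows; at 5-s windows the measurement itself smears
  ~3 % of a 2-Hz-wide band's power outside, so the check would gauge
  the estimator rather than the filter.
* All randomness flows through `numpy.random.Generator` seeded by
  explicit integers or spawned `SeedSequence`s; no global state.

## Known limitations

* The mechanistic generator cannot reach published node-strength
  magnitudes (sum-of-shared-variance cap); printed-value calibration
  is delegated to the summary-level generator.
* The inverse stage is exercised on toy leadfields only (no realistic
  forward model, ≤ tens of sources); it exists to make the pipeline
  complete from sensor space, not to validate source localization.
* AEC without orthogonalization is blind to zero-lag leakage; on real
  source-reconstructed data this inflates short-range edges. The
  synthetic world has no leakage, so this bias is absent from all
  calibration figures.
* Group recovery tests run at 250 Hz/60 s to fit a CPU-minute budget;
  envelope correlations are invariant to this rescaling, but absolute
  AEC estimation noise at 300 s/1 kHz is ~√5 smaller.
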