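# Methods

This note documents the models implemented in `smpc`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user should know about.

## Imaging model and spot counting

A field of view (FOV) covers 100 × 100 µm². The default simulation
samples it at 0.1 µm/px (1000 × 1000 px), which makes a
diffraction-limited spot (isotropic Gaussian PSF, sigma 1.3 px ≈ 130 nm)
well resolved and makes the 12,000-spot counting ceiling physically
meaningful: at that density spot footprints begin to overlap. Images are
background (default 100 a.u.) plus per-spot Gaussian peaks (amplitude
400 ± 40 a.u.) plus additive Gaussian pixel noise (sd 8 a.u.);
acquisitions are 5 frames of 100 ms that are averaged before analysis,
which reduces pixel noise by √5.

Counting proceeds in three steps:

1. **Background subtraction** — median filter (window 11 px, i.e. well
   above the PSF footprint) or rolling ball for spatially varying
   backgrounds; a `global` sigma-clipped scalar estimate for the
   high-density regime, where any local filter absorbs real signal
   (at 20,000 spots/FOV roughly half the pixels carry fluorescence, and
   a median window can no longer see past it). During subtraction the
   pixel-noise scale is estimated from the *lower* quantile side of the
   residuals (median minus 15.87th percentile, one Gaussian sigma).
   Fluorescent spots only add signal, so this estimate remains valid at
   any spot density; it is attached to the image and reused for
   thresholding.
2. **Detection** — local maxima above median + k·sd (k = 5 by default,
   matching the instrument's SNR ≥ 5 counting regime), with non-maximum
   suppression at 2 px. Each candidate is then confirmed on a sigma-1
   Gaussian-smoothed copy of the image: a real PSF-shaped spot keeps
   ~63% of its height under that smooth, while a single-pixel noise
   excursion collapses to ~16%, so the confirmation rejects the rare
   above-threshold pixel that a megapixel FOV produces by chance without
   costing true spots. Beyond the ceiling (default 12,000) the spot map
   is flagged saturated.
3. **Intensity extrapolation** — total fluorescence is integrated over
   the background-subtracted FOV; a least-squares line of count against
   intensity, fitted on sub-ceiling FOVs, converts intensities to counts
   beyond the ceiling (rounded half-up; counts are integers downstream).
   The line's intercept absorbs the small positive bias that clipping
   negative residuals introduces into the integral. On synthetic data
   the calibration is linear to r² > 0.999 and a 20,000-spot FOV is
   recovered to within ~1%.

The measured signal-to-noise ratio (mean detected peak amplitude over
the robust sd of spot-free pixels) scales inversely with camera noise,
as expected. It does **not** fall with spot density in this simulation:
synthetic spots have a fixed amplitude distribution and the robust noise
estimator ignores the sparse tail light that density adds, whereas on a
real instrument denser fields degrade the effective SNR. Passing the
density-sweep tests here therefore says nothing about density effects on
real hardware.

## Probe-binding assay and Kd

Fractional occupancy is bound probes over surface baits, clipped to
[0, 1] with a warning on over-counts. The dissociation constant is
fitted by nonlinear least squares on the single-site isotherm,
parameterised as log Kd to enforce positivity and initialised at the
concentration whose occupancy is nearest 0.5; noise-free titrations are
recovered to machine precision, and the fit is scale-equivariant in
concentration units.

Confidence intervals are bootstrap percentile intervals (default 1,000
resamples, seed required). The default resampling is **parametric**:
bound counts are redrawn from Binomial(baits, fitted occupancy), the
actual counting-noise process of the assay. The classic nonparametric
resampling of titration points is available (`ci_method="resample"`)
but undercovers noticeably (≈85% at nominal 95%) on the short 6-point
titration designs used in practice, because resampling 6 points often
discards the informative ones; the parametric interval holds ≈94%
coverage in simulation.

## BH3 profiling

JC-1 time series run 0–180 min at 5-min intervals. AUCs are trapezoidal
integrals over the observed window; depolarization is the AUC linearly
rescaled between the DMSO (0) and FCCP (1) controls, invariant to any
common affine gain/offset of the plate reader, and deliberately *not*
clipped — values slightly outside [0, 1] indicate control noise and are
flagged rather than hidden. The synthetic series are pointwise mixtures
of a slowly sagging DMSO curve and a fast-collapsing FCCP curve, so the
statistic recovers the generating fraction exactly; real kinetic shapes
(lag phases, biphasic collapse) are not modelled, which is irrelevant to
the AUC-based statistic but means the curves themselves are not
realistic templates. The BAD − HRK composite subtracts per-sample
depolarizations of the two peptides at 10 µM, isolating the
BCL2-dependent priming component.

## Ex vivo efficacy

Viability is fitted with the 4-parameter logistic
y = A2 + (A1 − A2)/(1 + (c/x0)^p); the fitted curve is integrated on the
linear concentration axis over the tested range (default 0–1000 nM,
adaptive quadrature at 1e-10 tolerance). "Maximal AUC" is defined as
100% viability over the same range, so the normalised score
1 − AUC/Maximal AUC lies in [0, 1] with 0 = fully insensitive — the
definition that makes all observed scores interpretable on one scale.
Degenerate curves (flat viability) and optimizer failures fall back to a
trapezoid on the raw data, flagged, never silent. The responsiveness
threshold 0.61 is boundary-inclusive.

One caveat: the sensitivity score is antitone in viability for
*pointwise-dominating* changes (raising viability everywhere can only
lower the score), but raising a single point can move the fitted curve's
other parameters enough to change the score by a few 1e-3 in either
direction. That is a property of any parametric fit, not a bug; the
raw-trapezoid fallback is exactly antitone.

## Cohort model

Features are log2 metrics with floors: counts below 100 spots are fixed
to 100, and the three intensity-type metrics (BCLxL-BAX, BCLxL-BAK,
BCL2-BAK complexes, which are too dim for reliable spot counting) below
10⁷ a.u. are fixed to 10⁷. Single-metric screening and panel fits are
ordinary least squares; the overall F statistic against the
intercept-only model, with its upper-tail p-value, is the acceptance
gate (p < 0.05). Rank-deficient panels fail loudly, naming the
collinear columns.

The Lasso ensemble draws, per candidate, a stratified 75/25 train/test
split and an L1 penalty log-uniform on [1e-4, 3e-2] (the span in which
the penalty moves from negligible to support-destroying at these
feature scales), fits on the training samples, and retains a candidate
only when (i) every test sample's responsiveness is classified
correctly at 0.61, (ii) the training Pearson R is ≥ 0.7, and (iii) an
OLS refit on the selected support passes the F-test gate. The
coefficient matrix across retained models shows which metrics the data
insist on: on synthetic cohorts with three true coefficients the true
panel is non-zero in ≈90% of retained models, while null metrics enter
at much lower frequency (small penalties keep them; the quantity of
interest is the contrast, not the absolute rate).

ROC AUC uses the rank formulation with ties counted one half, making it
numerically identical to the Mann–Whitney U over n1·n2 — an identity
the tests verify against scipy's independent implementation. The
Mann–Whitney p-value is exact for group sizes ≤ 12 without ties, and
tie-corrected normal otherwise.

## Synthetic cohort: what it does and does not emulate

`gen_cohort` draws each of the 22 metrics log2-normally (levels around
2¹¹ spots, complex counts around 2⁹·⁵, PBA counts around 2¹⁰·⁵,
intensity metrics around 2²⁴·⁵ a.u., all with log2-sd 1.0 — counts
spanning orders of magnitude, as single-molecule data do) and computes
the target as clip(intercept + Σ coef · feature, 0, 1) plus Gaussian
noise (sd 0.05). The default ground-truth coefficients are the ABT-199
driver/resistance panel at 0.12, 0.157 and −0.05 per log2 unit, with
the intercept set for a mean score of 0.55 so both responder classes
are well represented in a 32-sample cohort.

Because the noise-free target is computed on the same floored features
the fitting chain uses, a zero-noise cohort is exactly recoverable —
provided no sample hits the [0, 1] clip. Clipping affects ≈2% of
samples at the default spread; it is the one deliberate
misspecification (the score scale is genuinely bounded), and it costs
about 1–2 points of CI coverage in the recovery simulations (observed
93–97% per coefficient at nominal 95%). Metrics are drawn
independently; the correlation structure of real PPI profiles (levels
constrain complexes, occupied and unoccupied pools sum) is not
emulated, so passing tests here demonstrate the *estimation machinery*,
not robustness to real-world collinearity.

## Reproducibility

Every stochastic function takes an explicit seed and is a pure function
of (parameters, seed); the pipeline writes a config hash and versions
with every artifact, and a rerun with the same configuration is
bit-identical. The acceptance script derives per-stage sub-seeds from
its single `--seed` argument. Simulation sizes there (100 FOVs at
0.25 µm/px for the recovery rate, 50 titrations for CI coverage, 100
cohorts for coefficient coverage, 1,000 Lasso candidates) were chosen
to keep the full run around half a minute while leaving the Monte-Carlo
error on each reported rate below ~3 percentage points.
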