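# Methods

This note documents the models, estimators and numerical choices behind
`efrpipe`, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate about real recordings.

## Stimuli

SAM and RAM tones share carrier `f`, modulation frequency `fm`, modulation
depth `md` and start phase `φ`; only the envelope differs. The RAM
modulator is an ideal ±1 rectangular wave evaluated pointwise at sample
times (no band-limiting), matching a "square"-function construction; at
48 kHz and fm = 120 Hz the duty-cycle discretisation error is below one
sample per modulation period. Envelope extremes are `1 ± md` (SAM) and
`2 ± 2 md` (RAM), so at md = 0.95 the unscaled RAM has exactly twice the
SAM peak-to-peak amplitude and level matching scales it by 0.5. The
resulting RMS offset has the closed form

```
Δ = 10 log10( 0.25 · (τ (2+2md)² + (1−τ)(2−2md)²) / (2 + md²) ) ≈ −1.83 dB,
```

which the rendered waveforms reproduce to within a few thousandths of a dB
(residual due to carrier–envelope correlation at finite duration).
Peak-to-peak is evaluated on the full rendered waveform *before* the 2.5%
tapered-cosine presentation window: the taper affects only the outer 1.25%
of samples and leaves the extremes untouched for all standard parameters,
and matching physical stimulus amplitudes is the intent. dB SPL is
referenced to 20 μPa RMS; absolute calibration is a single linear scale
carried in `Stimulus.scale` (hardware chains are out of scope).

## EFR estimator

The estimator treats each epoch as signal + noise where only the
phase-locked envelope response is reproducible across epochs. Averaging
*complex* spectra across epochs (rather than magnitudes) lets
non-phase-locked noise cancel at rate 1/√n, and averaging across the two
stimulus polarities cancels carrier-locked components while preserving the
polarity-invariant envelope response.

Numerical conventions:

* **Amplitude scale.** One-sided spectra are multiplied by
  `2 / (N · mean(window))` (coherent-gain normalisation), so a sinusoid of
  amplitude A μV at an exact bin reports magnitude A μV. This makes the μV
  scale of the final amplitude well defined.
* **Bin alignment.** Harmonic bins are the nearest rFFT bin to `k·fm`; a
  warning is logged when any harmonic is off-bin by more than 10% of a bin.
  The synthetic defaults (fs = 16384 Hz, 8192-sample epochs → 2 Hz bins)
  put all five harmonics of fm = 120 Hz on exact bins, eliminating
  scalloping from ground-truth tests.
* **Noise floor.** Mean magnitude of the five bins on each side of the
  harmonic, excluding the harmonic bin. With a 2% tapered-cosine epoch
  window the window skirt leaks ~1% of a harmonic's energy into its
  immediate flanks, so PtN slightly underestimates a noiseless amplitude
  (≈1–2%); this bias is inherent to the flanking-bin definition and is the
  reason the oracle-equivalence tests carry a 2% tolerance.
* **Clipping.** Negative PtN values after subtraction are clipped to zero
  before reconstruction: a negative spectral amplitude is physically
  meaningless and would corrupt the waveform. This makes the null
  (no-signal) estimate a small positive quantity rather than zero-mean.
* **Point estimate and SD.** The amplitude is half the peak-to-peak of the
  *mean* of the B per-run waveforms; the SD is taken over the per-run half
  peak-to-peak values (each run using its own extremes).
* **Fast path.** `compute_efr` computes each epoch's windowed rFFT once and
  restricts bootstrap averaging to the harmonic and flank bins; this is
  algebraically identical to averaging full per-draw spectra and is
  asserted against the single-draw operation in the tests.

## DPOAE threshold

Growth points are resampled per draw from Gaussians with the measured
per-point SD, truncated at ±1.96 SD (the most literal reading of "draws
from within the confidence interval"). Monotonicity is restored by removing
points from the *ends* of the function only; an interior dip that endpoint
pruning cannot fix rejects the draw. The "adapted cubic" is implemented as
an ordinary least-squares cubic accepted only if non-decreasing over the
retained range (degree reduced when fewer than four points remain); the
originally cited parameterisation is not reproduced in the source material,
so this constrained cubic is a documented stand-in with the same described
behaviour.

Root finding: the threshold is the unique criterion crossing on the fitted
cubic's *monotone downward continuation* — the curve is extrapolated below
the lowest retained level only as far as its derivative stays non-negative,
and never more than 30 dB. A cubic tail that turns over before reaching
−25 dB SPL is a failed draw. (A naive "smallest real root in range" rule
was found to select spurious far-left cubic roots and to break the
expected monotonicity of the threshold under uniform level shifts.) TH_DP
is the median over valid draws, its SD the draw SD; zero measurement SD
yields a deterministic threshold with zero SD. Low-outlier thresholds can
be winsorised at the lower Tukey fence Q1 − 1.5·IQR (quartiles by
linear-interpolation percentiles).

## Adaptive speech-reception-threshold simulation

The listener is psychometric: P(word correct at level L) =
`guess + (1−guess) · logistic(4·slope·(L − SRT50))`, so slope is the
proportion-correct slope per dB at the midpoint. The exact step rule of the
matrix sentence test is not published in the source material; the package
uses a word-scoring proportional rule — after each 5-word sentence the
level moves by `step · (p̂ − 0.5)/0.5` toward threshold, with the step
(initial 5 dB) decaying by 0.8 at every direction reversal, and the SRT
taken as the mean presentation level of the last 10 of 20 sentences. All
rule parameters are configurable. With the default slope of 0.15/dB and a
start 10 dB above threshold, 200 seeded tracks recover SRT50 with ≈0.4 dB
mean absolute error.

## Synthetic data: what it does and does not show

The epoch generator produces exactly the structure the estimator assumes:
stationary harmonics at `k·fm` with per-epoch multiplicative gain jitter in
additive white + 1/f^α Gaussian noise (α = 1 by default, a minimal model of
the EEG noise floor). It contains no blink/EMG artifacts, no drifting
phase, no carrier-locked components and one channel only; passing tests
therefore validate the estimator's algebra and calibration, not its
robustness to real-EEG nuisance structure.

The cohort generator draws each group from a multivariate Gaussian scaled
to target means/SDs; Spearman correlation targets are realised through the
latent-Pearson map `r = 2 sin(π ρ/6)` (exact for Gaussian copulas). Group
means and SDs for the EFR, audiometric and age variables follow the
reported group statistics of the underlying study design (e.g. young
normal-hearing RAM EFR 0.239 ± 0.076 μV, older-group means whose pooled
average is 0.126 μV); SRT means/SDs per condition are **configuration, not
reported values** — plausible matrix-sentence levels chosen once (quiet
SRTs in dB SPL, noise SRTs in dB SNR) — because the study reports them only
graphically. The default within-group Spearman target couples the RAM EFR
to the high-pass speech-in-noise SRT at −0.73 and the two
hearing-sensitivity metrics at 0.84, with weaker plausible values filling
the remaining structure so the target matrix is positive definite.

## Statistics

The partially overlapping samples t-test is implemented in both the
pooled-variance and Welch-type variants; the pooled variant uses
df `(n12−1) + (na+nb+n12−1)/(na+nb+2n12)·(na+nb)` and reduces exactly to
Student's t with no pairs, while the Welch variant reduces exactly to the
paired t statistic with no independent observations. Monte-Carlo
calibration on a 3-paired/11-pre/4-post Gaussian null gives a type-I error
of ≈0.054 at nominal 0.05 over 10⁴ replicates. Commonality analysis uses
the all-subsets identity (supported for 2–3 predictors); components are
asserted to sum to the full-model R² at 1e-10. Ordinary regression fits and
their diagnostics (VIF, Durbin–Watson, Shapiro–Wilk) delegate to
statsmodels/scipy. The piecewise growth fit is continuous at the knee by
construction (`y = a + b_lo·min(x−k,0) + b_hi·max(x−k,0)`); free-knee mode
scans interior grid levels and keeps the minimum-RSS knee, requiring at
least two points per side.

## Problem sizes and determinism

Default problem sizes (1000 epochs × 8192 samples, B = 200 bootstrap runs,
500 DPOAE draws, 5000-per-group convergence checks) were chosen so each
estimator operates in its intended regime while a full verification run
completes in minutes on one core. Every stochastic operation takes a seed
(NumPy `default_rng`); the pipeline driver derives per-stage sub-seeds from
the global seed by hashing, so stages are independently reproducible and
every artifact records its seed, configuration hash and package version.

## Known limitations

* Single-channel epochs are the entry point; raw-recording parsing,
  re-referencing and artifact rejection are out of scope.
* The flanking-bin noise floor inherits a small negative bias from window
  leakage (see above); amplitudes are comparable across conditions
  analysed with the same window, but are not bias-free absolute μV.
* The "adapted cubic" and the adaptive-track step rule are documented
  stand-ins for procedures whose exact parameterisations are not public.
* Winsorisation of low DPOAE thresholds interprets an ambiguous published
  rule as the lower Tukey fence.
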