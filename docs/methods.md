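# Methods

This note documents the models, estimators and numerical choices behind
pupvox, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left room.

## Calibration convention

All audio lives on a full-scale digital axis with a declared mapping to
sound pressure level: `cal_db` (default 100) is the dB SPL of a signal
whose RMS amplitude is 1.0, so `rms = 10^((SPL − cal_db)/20)`. The default
leaves ≥ 20 dB of headroom above the loudest default call level (75 dB
SPL), guaranteeing synthetic sessions never clip. The round trip
SPL → RMS → SPL is exact to numerical precision; generated noise beds are
RMS-rescaled after filtering, so measured levels match the nominal
65 / 45 / 25 dB SPL to well under 0.1 dB.

## Synthetic sessions

**Design.** A session is nine blocks, three per condition (no playback,
low, high), ordered uniformly at random over the 174 orderings of the
multiset {N,N,N,L,L,L,H,H,H} that avoid two identical conditions in a row.
Rejection sampling from uniform permutations delivers exact uniformity
over that set (verified by a chi-square test against brute-force
enumeration). The field design used 5-min blocks; the desk-scale default
is 30 s with the duration as a config field, so the full design remains
expressible.

**Noise beds.** Low/high beds are white Gaussian noise through a 4th-order
Butterworth bandpass (250–500 Hz) applied forward-backward (zero phase),
then RMS-calibrated; the no-playback condition is broadband white noise at
the ambient level. The real playback stimuli were wind recordings; a
stationary surrogate was chosen deliberately, because stationarity makes
the spectral-subtraction mean-recovery property provable and testable. The
spectrum inside the band is flat by decision, not evidence.

**Calls.** A call is a sum of up to 20 harmonics of a time-varying f0:
per-call base drawn lognormally with the condition's population *median*
(exact by construction: the lognormal multiplier has median 1) and a
condition CV; slow sinusoidal drift (±3%, 2–4 Hz, random phase);
multiplicative per-cycle jitter (CV 0.004); harmonic amplitudes falling at
the source tilt in dB/octave; a tilt-shaped broadband aspiration floor
20 dB below the harmonic part; raised-cosine onset/offset ramps (40 ms);
total RMS calibrated exactly to the call level. Draws outside 200–800 Hz
are rejected and redrawn. Durations are untruncated lognormal with
`mu = ln(median)` and `sigma = sqrt(2 ln(mean/median))`, the joint fit to
the observed mean 0.785 s and median 0.729 s (the observed min/max are
empirical, not constraints). Harmonics are capped at 0.45 × sample rate
(default 16 kHz), so with the aspiration floor the source fills the whole
1/3-octave analysis range up to ~7.2 kHz — an abrupt spectral edge inside
the analysis band would make band energies there meaningless.

Defaults encode the study conditions: condition medians 403 / 374 / 324 Hz;
call level 75 dB SPL in every condition (no intrinsic amplitude response),
which pins the high-condition SNR at +10 dB; a common −6 dB/octave source
tilt; f0 CVs 0.08 / 0.08 / 0.05 (no playback / low / high). No CV values
are published; these were chosen once so that the within-condition 2-sigma
spread stays inside the observed 270–620 Hz f0 range while the
high-noise dispersion is visibly lower, and they are configurable.
Per-individual Lombard responses (intensity gain, tilt flattening) are
config options, not defaults.

**Assembly.** Calls are placed by a scheduler that fixes each call's
ground truth (duration, f0, level, tilt) before assembly and packs onsets
without overlap, then added sample-wise onto the noise bed. The session's
noise-only rendering reuses the identical noise realization — the
surrogate for separate noise-only reference recordings. Mixing is linear
and sample-exact; an empty schedule reproduces the bed bit-for-bit. Every
random draw descends from one session seed via `SeedSequence` children, so
any call can be re-synthesized in isolation.

**What the generator does not emulate.** Reverberation, moving sources,
non-stationary wind spectra, vocal-tract formants beyond the fixed tilt
envelope, overlapping choruses, and observer annotation error. Passing
recovery tests therefore shows the estimators are correct and calibrated
under the stated signal model — not that they are robust to every artifact
of field audio.

## Screening

The four exclusion criteria gate the amplitude/f0 analyses only: (1)
clipping, operationalized as ≥ 3 consecutive samples at ≥ 0.999 of full
scale (a run criterion ignores isolated extreme samples); (2) temporal
overlap with a different individual's call, on half-open intervals so a
shared boundary is not an overlap; (3) extraneous noise, carried as an
upstream flag because the original judgement was human (synthetic data set
it programmatically); (4) untrackable pitch, operationalized as a voiced
fraction < 0.5 of pitch frames — the original criterion ("properly
tracked") had no number, so this surrogate is documented and adjustable.
Rate and duration analyses always use the full call set.

## Pitch tracking

Classical normalized-autocorrelation design: 15 ms Hann-windowed,
mean-subtracted frames every 10 ms (window = 3 periods of the 200 Hz
floor); frame autocorrelation by FFT, divided by the window's own
autocorrelation; candidate lags in [1/800, 1/200] s from local maxima with
three-point parabolic interpolation; candidate strength penalized/rewarded
by an octave cost (0.01), an unvoiced candidate scored from the voicing
threshold (0.45) and local/global peak ratio against the silence threshold
(0.03); Viterbi path with octave-jump cost (0.35) and voiced/unvoiced
transition cost (0.14). Only step, floor and ceiling are fixed by the
experiment's extraction settings; the remaining constants follow the
classical defaults and are all exposed in `PitchSettings`.

Accuracy under masking is the load-bearing property: because the masker is
bandlimited to 250–500 Hz and calls carry ≥ 10 harmonics above it, the
autocorrelation at the true period survives masking. Measured on synthetic
calls at +10 dB SNR the per-call median-f0 bias is ≈ 0.2% with an SD of
≈ 0.6% — far inside the 5 Hz recovery tolerance. A spectral harmonic-comb
estimator (implemented only in the tests) provides an
autocorrelation-free cross-check on steady calls. Per-call statistics use
the median over voiced frames (robust to tracker outliers); the mean is
also reported. Whether condition summaries should pool frames or per-call
medians is ambiguous in the original description; the pipeline computes
per-call medians and takes the median over calls.

## Spectral features

**Average power spectra** use 512-sample Hamming windows with 256 hop; the
normalizer is chosen so summed bin power equals the mean window-weighted
frame power (one-sided bins doubled), making spectra commensurate with
time-domain intensities (Parseval check in the tests at 1e−6).

**Gain compensation.** Recording gain varies per session. The RMS power of
non-vocal portions (annotated calls masked) of the low and high blocks is
divided by the noise-only reference's power over the same masked segments;
the session gain is the geometric mean of the two ratios (the single
published "gain value per recording session" did not state the averaging;
the geometric mean is symmetric in dB). Dividing samples by `sqrt(gain)`
puts the session on the reference scale: a session recorded 6 dB hot has
gain ≈ 4 in power, and compensation restores the bed to 65/45 dB SPL. All
downstream features are invariant to the recording scale to 1e−6.

**Intensity and SNR.** Call intensity = RMS power of the gain-compensated
call interval minus RMS power of the matched noise-only interval. Weak
calls can come out negative; values are kept, and condition comparisons
stay in the linear power domain where the mean remains unbiased. SNR (dB)
is defined only for positive intensities. The published SNR procedure was
a footnote not available here; the linear intensity ratio in dB is the
documented surrogate, and it reproduces the designed +10 dB within 0.05 dB
on average.

**Spectral subtraction** is the signed bin-wise difference of call and
matched-noise average spectra. It is unbiased for the mean spectrum;
variance stays inflated by the noise (no variance correction is
attempted). Negative bins are preserved through band summation; positivity
is enforced only at the fit/ratio stage.

**Tilt.** One-third-octave bands are centered at 1000·2^(k/3) Hz with
edges ±1/6 octave, restricted to centers above 400 Hz (the masker corrupts
energies below) and below min(8 kHz, Nyquist·2^(−1/6)) — the upper limit
is a package decision, configurable. The slope is the OLS fit of
10·log10(band energy) on log2(center/1 kHz) over bands with positive
energy; fewer than two positive bands makes the slope undefined with a
recorded reason. R14 = 10·log10(E(0.4–1 kHz)/E(1–4 kHz)), in dB (the
original unit was unstated), undefined when either signed band energy is
non-positive. Sign conventions: Lombard-type "flattening" = slope moves
toward 0 (less negative) and R14 decreases.

Two caveats discovered during validation and worth knowing. First, with
harmonically sparse sources the 1/3-octave energies depend on where
harmonics land relative to band edges, so *absolute* condition-mean slopes
carry an f0-placement component whenever conditions differ in f0; the
tilt-difference recovery experiment therefore shares call draws between
conditions (common random numbers), isolating the planted tilt change —
recovered to 0.002 dB/octave at n = 300 versus a sampling SD that would be
~0.14 unpaired. Second, flat-spectrum closed forms for band energies and
R14 hold only up to FFT bin quantization (31.25 Hz bins at 16 kHz); tests
account for that.

## Statistics

**Model.** For call counts, durations, per-call median f0 and
coefficients of variation: a linear mixed model with crossed random
intercepts for session and seal, fixed effects condition and trial number
(the latter controlling for habituation within sessions). The REML/ML
profile over the two variance ratios is computed with the Woodbury
identity (cost O(n·q²), q = sessions + seals), optimized by Nelder–Mead on
the log scale with the variance profiled out analytically. The solver is
package-owned because permutation testing needs thousands of refits;
statsmodels' `MixedLM` with crossed variance components is the independent
oracle in the tests (agreement to ~1e−3 on variance components and fixed
effects). A variance component collapsing to the boundary is reported as
zero and logged, which is equivalent to refitting without it. The
pseudo-R² is the squared correlation between fitted values (including
BLUPs) and observations — one of several definitions in circulation, fixed
and documented here; published pseudo-R² values are not comparable targets.

**Permutation inference.** Calls within a block share a condition by
design, so blocks are the exchangeable units: condition labels are
permuted across the nine blocks within each session (for grouped tables
without blocks, e.g. CV cells, labels permute within session × seal).
Variance components are estimated once by REML under the condition-free
null model — making the estimated covariance identical for observed and
permuted data — the data are whitened with that covariance, and the
statistic is the F ratio for the condition term in the whitened
regression. This fixed-covariance score-type statistic replaces a full
REML refit per permutation (computationally prohibitive at calibration
scale) and is empirically calibrated: type-I error 0.03–0.07 at nominal
0.05 over 500 null simulations. p = (1 + #{perm ≥ obs})/(1 + n_perm)
(never zero; n_perm = 1000 by default). The statistic is invariant to
affine transformations of the response.

**Multiple comparisons.** Pairwise condition contrasts refit the model on
each two-condition subset at alpha = 0.05/3 ≈ 0.0167. Intensity and the
two tilt measures are strongly non-normal, so they use two-sided
Mann–Whitney U tests per seal and condition pair (exact null distribution
for min(n) ≤ 12 without ties, normal approximation with tie and continuity
corrections otherwise; scipy's implementation behind the module surface,
checked against exhaustive enumeration for all |x|+|y| ≤ 8) at
alpha = 0.05/(seals × 3) — 0.05/24 ≈ 0.00208 for eight seals.

**Dispersion.** CV = sample SD (n−1) / mean per session × seal × condition
group; groups with fewer than three calls are dropped and logged (the
original grouping evidently dropped some cells but stated no rule; three
is the smallest size with a meaningful sample SD). The CV table feeds the
same mixed model + permutation machinery with condition as the only fixed
effect.

## Pipeline and reproducibility

Stages (generate → features → stats → report) persist all intermediates as
WAV and tab-separated text; re-running any stage from persisted artifacts
is byte-identical, and a fixed global seed makes the whole run
reproducible (seeds consumed per session are logged). Desk-scale defaults
— 14 sessions × nine 30 s blocks × 2 seals, ~2 calls per seal per block,
1000 permutations — run end-to-end in well under a minute and reproduce
the qualitative result pattern (significant monotone f0 effect in all
three pairs; null call-count and duration effects; an f0-dispersion
effect only for high noise versus the other two conditions). A "valid
session" in the report requires at least two calls per pup. Degenerate
inputs (empty schedules, subsets smaller than the fixed-effect count) are
reported as insufficient data rather than failures.

## Known limitations

* The generator's stationary, flat-in-band noise and additive mixing make
  spectral subtraction better behaved than in reverberant field audio.
* Matched noise intervals share the realization of the session's bed, so
  noise cancellation is more exact than separate recordings would allow;
  the mean-recovery tests use independent noise for this reason.
* Absolute 1/3-octave slopes of sparse harmonic spectra are not comparable
  across conditions with different f0 (see above); only within-call and
  paired comparisons are.
* The permutation statistic fixes variance components at their null REML
  estimates; with very few sessions/seals this approximation (like any
  asymptotic treatment of the variance) is only as good as its empirical
  calibration, which the test suite checks at the default design size.
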