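# pupvox

Tools for analysing — and synthesizing — noise-playback experiments on
vocalizing animals, built around the design used to study vocal plasticity
in harbour seal (*Phoca vitulina*) pups: individuals are exposed to
bandpass-filtered noise (250–500 Hz, overlapping the fundamental-frequency
range of pup "mother attraction" calls) at two intensities plus a
no-playback baseline, and their spontaneous calls are measured for shifts
in fundamental frequency (f0), amplitude, and spectral tilt (Lombard-type
responses).

Because field recordings of this kind are rarely shareable, the package
pairs the analysis chain with a first-class synthetic-session generator, so
every estimator can be validated against known ground truth.

## What it does

* **synth** — calibrated sessions: nine randomized blocks (three per noise
  condition, never two identical conditions in a row), a 250–500 Hz
  Butterworth-bandpass Gaussian noise bed at 65 / 45 dB SPL over a
  ~25 dB SPL ambient background (SPL realized digitally as 100 dB SPL at
  full-scale RMS), and harmonic calls with lognormal durations
  (mean 0.785 s, median 0.729 s), per-condition median f0
  (403 / 374 / 324 Hz), f0 drift + jitter, a dB/octave source tilt and a
  breathy aspiration floor. A matched noise-only rendering of every session
  stands in for separate noise-only reference recordings.
* **audio** — WAV / annotation-table / TextGrid I/O and the four
  call-screening criteria (not clipped, no overlap with another individual,
  no extraneous noise, trackable pitch). Screening gates only the
  amplitude/f0 analyses; call-rate and duration analyses use every call.
* **pitch** — normalized-autocorrelation f0 tracking (window-autocorrelation
  correction, parabolic lag interpolation, Viterbi path with octave and
  jump costs; time step 0.01 s, floor 200 Hz, ceiling 800 Hz). Harmonics
  above the masking band keep the tracker accurate even when the f0 band
  itself is buried in noise.
* **spectral** — per-session preamp-gain compensation against the
  noise-only reference, spectral subtraction of averaged power spectra
  (512-sample Hamming frames, 256 hop), noise-compensated intensity kept in
  the linear power domain (negative values allowed; condition means stay
  unbiased), SNR, and two spectral-tilt measures: the OLS slope of
  one-third-octave log band energies above 400 Hz referenced to 1 kHz
  (dB/octave), and R14 = 10·log10(E(0.4–1 kHz) / E(1–4 kHz)).
* **stats** — linear mixed models with crossed random intercepts (session,
  seal) and condition + trial fixed effects; p-values by permutation of
  condition labels at the block level within session (p = (1 + #{perm ≥
  obs}) / (1 + n_perm)); Bonferroni-adjusted pairwise comparisons (0.05/3)
  and per-seal Mann–Whitney U tests for intensity and tilt (0.05/24 for
  eight seals); coefficient-of-variation analysis of f0 and duration
  dispersion per session × seal × condition.
* **pipeline / cli** — `pupvox generate|features|stats|report|all` runs the
  whole chain reproducibly from one seed and writes plain-text artifacts
  plus a report with ground-truth recovery scores and a qualitative result
  checklist.

## Worked example

```bash
pupvox all --seed 11 --out run/
```

synthesizes fourteen sessions (nine 30 s blocks each, two seals per
session), screens and measures ~500 calls, and prints a report ending in:

```
f0 median [no_playback]: estimated 397.1 Hz, true 397.2 Hz, error -0.1 Hz
f0 median [low]: estimated 369.5 Hz, true 368.0 Hz, error +1.5 Hz
f0 median [high]: estimated 321.6 Hz, true 320.8 Hz, error +0.8 Hz
mean SNR in high noise: 10.02 dB
...
f0_median_hz [all_conditions]: pseudoR2 = 0.550; p = 0.000999; N = 496 (alpha = 0.05)*
duration_s [all_conditions]: pseudoR2 = 0.004; p = 0.977; N = 496 (alpha = 0.05)
cv_f0 [all_conditions]: pseudoR2 = 0.186; p = 0.000999; N = 76 (alpha = 0.05)*
```

(The "true" medians differ slightly from the population values 403 / 374 /
324 Hz because each run samples finitely many calls and per-seal f0
offsets.)

Read: the pitch tracker recovers the per-condition median f0 within ~1 Hz
despite the masking noise; the noise-compensated SNR of 75 dB SPL calls
over the 65 dB SPL bed sits at the designed +10 dB; the permutation mixed
model flags the (planted) f0 shift and the reduced f0 dispersion under
high noise while durations stay null — the same qualitative pattern the
experimental design targets.

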