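"""Noise compensation and spectral features.

Per call the pipeline computes, after per-session gain compensation:

* noise-compensated intensity — RMS power of the call interval minus RMS
  power of the matched noise-only interval, kept in the *linear* power
  domain (subtraction can make it negative; the mean over calls is still an
  unbiased estimate of the mean clean-call power, so condition comparisons
  stay valid there);
* SNR in dB, defined only when the compensated intensity is positive;
* two spectral-tilt measures on the spectrally subtracted average power
  spectrum (512-sample Hamming frames, 256 hop): a regression slope of
  one-third-octave log-energies above 400 Hz referenced to 1 kHz
  (dB/octave), and R14, the dB ratio of the 0.4–1 kHz band energy to the
  1–4 kHz band energy.  Bands whose energy is non-positive after
  subtraction are excluded from the slope fit; fewer than two positive
  bands, or a non-positive band in the ratio, makes the measure undefined
  with a recorded reason.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .audio import CallClip, Waveform

__all__ = [
    "PowerSpectrum",
    "NoiseProfile",
    "TiltMeasures",
    "IntensityResult",
    "DiscardReason",
    "average_power_spectrum",
    "estimate_session_gain",
    "apply_gain_compensation",
    "spectral_subtract",
    "call_intensity",
    "third_octave_centers",
    "third_octave_energies",
    "octave_slope",
    "r14",
    "call_tilt_measures",
]

N_FFT_DEFAULT = 512
HOP_DEFAULT = 256


class DiscardReason(enum.Enum):
    NONE = "none"
    TOO_FEW_POSITIVE_BANDS = "too_few_positive_bands"
    NONPOSITIVE_BAND_ENERGY = "nonpositive_band_energy"


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided average power spectrum.

    Normalized so that the summed bin power equals the mean power of the
    window-weighted frames (Parseval-consistent: for stationary input the
    total equals the time-domain mean-square amplitude).  Spectra of raw
    audio are non-negative; spectra produced by spectral subtraction may
    carry negative bins.
    """

    freqs: np.ndarray
    power: np.ndarray
    n_fft: int
    hop: int
    sample_rate: float
    n_frames: int

    def __post_init__(self) -> None:
        if len(self.power) != self.n_fft // 2 + 1:
            raise ValueError("power length must be n_fft/2 + 1")
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power lengths differ")

    def band_energy(self, lo_hz: float, hi_hz: float) -> float:
        """Sum of (signed) bin powers with bin centers in (lo_hz, hi_hz]."""
        mask = (self.freqs > lo_hz) & (self.freqs <= hi_hz)
        return float(np.sum(self.power[mask]))


@dataclass(frozen=True)
class NoiseProfile:
    """Per-condition average noise spectrum and intensity, plus the
    session's estimated preamp gain (power-domain factor)."""

    spectra: Mapping[str, PowerSpectrum]
    intensity: Mapping[str, float]
    session_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.session_gain <= 0:
            raise ValueError("session_gain must be > 0")
        if any(v <= 0 for v in self.intensity.values()):
            raise ValueError("noise intensities must be > 0")


@dataclass(frozen=True)
class TiltMeasures:
    octave_slope_db_per_oct: float
    r14_db: float
    n_positive_bands: int
    discard_reason: DiscardReason = DiscardReason.NONE


@dataclass(frozen=True)
class IntensityResult:
    call_intensity: float  # linear power; may be negative after subtraction
    noise_intensity: float
    snr_db: float  # NaN when call_intensity <= 0

    @property
    def snr_defined(self) -> bool:
        return math.isfinite(self.snr_db)


def average_power_spectrum(
    w: Waveform, n_fft: int = N_FFT_DEFAULT, hop: int = HOP_DEFAULT
) -> PowerSpectrum:
    """Average one-sided power spectrum over Hamming-windowed frames.

    The normalizer is ``n_fft * sum(win**2)``, with interior one-sided bins
    doubled, so that the summed bin power equals the mean windowed-frame
    power ``mean_t(sum_n (win_n x_n)^2 / sum_n win_n^2)``.
    """
    x = w.samples
    if len(x) < n_fft:
        raise ValueError(f"need >= {n_fft} samples, got {len(x)}")
    win = np.hamming(n_fft)
    n_frames = (len(x) - n_fft) // hop + 1
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    scale = np.ones(n_fft // 2 + 1)
    scale[1:-1] = 2.0  # fold negative frequencies
    power = (spec * scale).mean(axis=0) / (n_fft * np.sum(win**2))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / w.sample_rate)
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        n_fft=n_fft,
        hop=hop,
        sample_rate=w.sample_rate,
        n_frames=n_frames,
    )


# ---------------------------------------------------------------------------
# Gain compensation


def estimate_session_gain(
    session: Waveform,
    annotations: Sequence,
    block_bounds: Sequence[tuple[float, float]],
    block_conditions: Sequence[str],
    noise_ref: Waveform,
    conditions: tuple[str, ...] = ("low", "high"),
) -> float:
    """Power-domain preamp gain of a session relative to its noise-only
    reference.

    For each noisy condition (low, high) the RMS power of the session's
    non-vocal portions (annotated call intervals masked out) is divided by
    the reference's power over the *same* masked segments; the session gain
    is the geometric mean of the two per-condition ratios.  Dividing the
    session samples by ``sqrt(gain)`` equalizes the powers (see
    :func:`apply_gain_compensation`).
    """
    fs = session.sample_rate
    mask = np.ones(len(session.samples), dtype=bool)
    for a in annotations:
        i0 = int(round(a.onset_s * fs))
        i1 = int(round(a.offset_s * fs))
        mask[i0:i1] = False
    ratios = []
    for cond in conditions:
        sel = np.zeros(len(session.samples), dtype=bool)
        for (b0, b1), c in zip(block_bounds, block_conditions):
            if c == cond:
                sel[int(round(b0 * fs)) : int(round(b1 * fs))] = True
        sel &= mask
        if not sel.any():
            raise ValueError(f"no non-vocal audio available in condition {cond!r}")
        p_sess = float(np.mean(np.square(session.samples[sel])))
        p_ref = float(np.mean(np.square(noise_ref.samples[sel])))
        ratios.append(p_sess / p_ref)
    return float(np.exp(np.mean(np.log(ratios))))  # geometric mean


def apply_gain_compensation(w: Waveform, session_gain: float) -> Waveform:
    """Scale samples by 1/sqrt(session_gain), matching the session's power
    to the noise-only reference scale."""
    return Waveform(w.samples / math.sqrt(session_gain), w.sample_rate)


# ---------------------------------------------------------------------------
# Spectral subtraction and intensity


def spectral_subtract(call: PowerSpectrum, noise: PowerSpectrum) -> PowerSpectrum:
    """Bin-wise signed difference of average power spectra.

    Negative bins are preserved — downstream consumers decide how to treat
    them.  Because call and noise are independent, the expectation of the
    difference equals the clean call's spectrum (the variance remains
    inflated by the noise)."""
    if call.n_fft != noise.n_fft or call.sample_rate != noise.sample_rate:
        raise ValueError("call and noise spectra have mismatched shape/rate")
    return PowerSpectrum(
        freqs=call.freqs,
        power=call.power - noise.power,
        n_fft=call.n_fft,
        hop=call.hop,
        sample_rate=call.sample_rate,
        n_frames=call.n_frames,
    )


def call_intensity(clip: CallClip, profile: NoiseProfile | None = None) -> IntensityResult:
    """Noise-compensated intensity of one (gain-compensated) call.

    intensity = RMS power of the call interval − RMS power of the matched
    noise-only interval.  The result may be negative for weak calls;
    condition comparisons therefore stay in the linear domain.  snr_db is
    10·log10(intensity / noise) when the intensity is positive, else NaN.
    """
    p_call = clip.waveform.rms_power()
    p_noise = clip.context_noise.rms_power()
    intensity = p_call - p_noise
    snr = (
        10.0 * math.log10(intensity / p_noise)
        if intensity > 0 and p_noise > 0
        else float("nan")
    )
    return IntensityResult(
        call_intensity=intensity, noise_intensity=p_noise, snr_db=snr
    )


# ---------------------------------------------------------------------------
# Spectral tilt


def third_octave_centers(
    fmin_hz: float = 400.0,
    fmax_hz: float = 8000.0,
    ref_hz: float = 1000.0,
) -> np.ndarray:
    """One-third-octave band centers ``ref * 2**(k/3)`` within
    (fmin_hz, fmax_hz]."""
    k_lo = math.ceil(3 * math.log2(fmin_hz / ref_hz) + 1e-9)
    k_hi = math.floor(3 * math.log2(fmax_hz / ref_hz) + 1e-9)
    centers = ref_hz * 2.0 ** (np.arange(k_lo, k_hi + 1) / 3.0)
    return centers[centers > fmin_hz]


def third_octave_energies(
    s: PowerSpectrum,
    fmin_hz: float = 400.0,
    fmax_hz: float | None = None,
    ref_hz: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed band energies on one-third-octave bands referenced to 1 kHz.

    Band edges are center ``* 2**(±1/6)``.  The default upper limit is
    8 kHz or Nyquist ``* 2**(-1/6)``, whichever is lower, so the top band
    stays inside the spectrum.  Returns (centers, energies)."""
    if fmax_hz is None:
        fmax_hz = min(8000.0, s.sample_rate / 2.0 * 2.0 ** (-1.0 / 6.0))
    centers = third_octave_centers(fmin_hz, fmax_hz, ref_hz)
    energies = np.array(
        [
            s.band_energy(c * 2.0 ** (-1.0 / 6.0), c * 2.0 ** (1.0 / 6.0))
            for c in centers
        ]
    )
    return centers, energies


def octave_slope(
    centers: np.ndarray, energies: np.ndarray, ref_hz: float = 1000.0
) -> tuple[float, int, DiscardReason]:
    """OLS slope of 10·log10(band energy) on log2(center / 1 kHz), fitted
    only on bands whose energy remained positive after subtraction.

    Returns (slope dB/octave, number of positive bands, discard reason);
    the slope is NaN when fewer than two bands are positive."""
    pos = energies > 0
    n_pos = int(np.sum(pos))
    if n_pos < 2:
        return float("nan"), n_pos, DiscardReason.TOO_FEW_POSITIVE_BANDS
    x = np.log2(centers[pos] / ref_hz)
    y = 10.0 * np.log10(energies[pos])
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, n_pos, DiscardReason.NONE


def r14(s: PowerSpectrum) -> tuple[float, DiscardReason]:
    """dB ratio of band energy in (0.4, 1] kHz to that in (1, 4] kHz.

    Energies below 400 Hz are excluded (the noise band corrupts them).
    Undefined (NaN) when either signed band energy is non-positive."""
    e1 = s.band_energy(400.0, 1000.0)
    e2 = s.band_energy(1000.0, 4000.0)
    if e1 <= 0 or e2 <= 0:
        return float("nan"), DiscardReason.NONPOSITIVE_BAND_ENERGY
    return 10.0 * math.log10(e1 / e2), DiscardReason.NONE


def call_tilt_measures(
    clip: CallClip,
    *,
    n_fft: int = N_FFT_DEFAULT,
    hop: int = HOP_DEFAULT,
    fmin_hz: float = 400.0,
    fmax_hz: float | None = None,
) -> TiltMeasures:
    """Both tilt measures for one call: average spectra of the call and its
    matched noise interval, spectral subtraction, then the one-third-octave
    slope and R14 on the subtracted spectrum."""
    cs = average_power_spectrum(clip.waveform, n_fft, hop)
    ns = average_power_spectrum(clip.context_noise, n_fft, hop)
    sub = spectral_subtract(cs, ns)
    centers, energies = third_octave_energies(sub, fmin_hz, fmax_hz)
    slope, n_pos, reason = octave_slope(centers, energies)
    ratio, r_reason = r14(sub)
    if reason is DiscardReason.NONE and r_reason is not DiscardReason.NONE:
        reason = r_reason
    return TiltMeasures(
        octave_slope_db_per_oct=slope,
        r14_db=ratio,
        n_positive_bands=n_pos,
        discard_reason=reason,
    )
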