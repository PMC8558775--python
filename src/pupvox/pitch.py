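"""Autocorrelation f0 tracking.

The tracker follows the classical normalized-autocorrelation design used by
standard phonetic software: per frame, the short-term autocorrelation of the
Hann-windowed, mean-subtracted segment is divided by the autocorrelation of
the window itself; candidate periods are local maxima in the lag range
implied by the pitch floor and ceiling, refined by parabolic interpolation;
a voiced/unvoiced decision and octave disambiguation come from a
Viterbi-style best path over candidates with octave and jump costs.

Because the call's harmonics extend well above a bandlimited masker, the
autocorrelation at the true period stays strong even when the f0 band itself
is masked — the property that makes f0 recoverable under 250–500 Hz noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .audio import Waveform

__all__ = ["PitchSettings", "PitchTrack", "track_pitch", "call_f0_summary"]


@dataclass(frozen=True)
class PitchSettings:
    """Tracker settings.  The analysis window spans three periods of the
    pitch floor; thresholds follow the classical defaults, with the frame
    step, floor and ceiling set to the experiment's extraction values."""

    time_step: float = 0.01
    floor: float = 200.0
    ceiling: float = 800.0
    voicing_threshold: float = 0.45
    silence_threshold: float = 0.03
    octave_cost: float = 0.01
    jump_cost: float = 0.35
    voiced_unvoiced_cost: float = 0.14
    max_candidates: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.floor < self.ceiling):
            raise ValueError("need 0 < floor < ceiling")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")

    @property
    def window_s(self) -> float:
        return 3.0 / self.floor


@dataclass(frozen=True)
class PitchTrack:
    """Frame-wise f0 (NaN marks unvoiced) and candidate strength."""

    frame_times: np.ndarray
    f0: np.ndarray
    strength: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if len(self.f0) else 0.0

    def export(self, path) -> None:
        """Delimiter-separated (time_s, f0_hz, strength); unvoiced f0 empty."""
        import pandas as pd

        pd.DataFrame(
            {
                "time_s": self.frame_times,
                "f0_hz": self.f0,
                "strength": self.strength,
            }
        ).to_csv(path, sep="\t", index=False, na_rep="")


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location and height via three-point parabola."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    return i + d, b - 0.25 * (a - c) * d


def track_pitch(w: Waveform, s: PitchSettings | None = None) -> PitchTrack:
    """Track f0 over `w`; frames shorter than one analysis window yield an
    empty track with a warning."""
    s = s or PitchSettings()
    fs = w.sample_rate
    if s.ceiling >= fs / 2:
        raise ValueError("ceiling must be below the Nyquist frequency")
    x = w.samples
    nwin = int(round(s.window_s * fs))
    hop = s.time_step * fs
    if len(x) < nwin:
        warnings.warn("input shorter than one analysis window; empty track")
        e = np.empty(0)
        return PitchTrack(e, e.copy(), e.copy())

    n_frames = int((len(x) - nwin) / hop) + 1
    starts = np.round(np.arange(n_frames) * hop).astype(int)
    frames = np.stack([x[i : i + nwin] for i in starts])
    frame_times = (starts + nwin / 2) / fs

    lag_min = max(int(np.floor(fs / s.ceiling)), 2)
    lag_max = int(np.ceil(fs / s.floor))
    nfft = 1 << int(np.ceil(np.log2(2 * nwin)))

    win = np.hanning(nwin)
    # normalized autocorrelation of the window itself, for the Boersma
    # correction r_x(tau) / r_w(tau)
    wspec = np.abs(np.fft.rfft(win, nfft)) ** 2
    acw = np.fft.irfft(wspec)[: lag_max + 2]
    acw /= acw[0]

    global_peak = float(np.max(np.abs(x))) or 1.0

    frames = frames - frames.mean(axis=1, keepdims=True)
    local_peaks = np.max(np.abs(frames), axis=1)
    spec = np.abs(np.fft.rfft(frames * win, nfft, axis=1)) ** 2
    ac = np.fft.irfft(spec, axis=1)[:, : lag_max + 2]

    # candidates per frame: (f0 or nan, local strength)
    cand_f0: list[np.ndarray] = []
    cand_str: list[np.ndarray] = []
    unvoiced_floor = s.silence_threshold / (1.0 + s.voicing_threshold)
    for fi in range(n_frames):
        a = ac[fi]
        if a[0] <= 0:
            r = np.zeros(lag_max + 2)
        else:
            r = a / a[0] / np.maximum(acw, 1e-12)
        seg = r[lag_min : lag_max + 1]
        inner = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
        idx = np.nonzero(inner)[0] + lag_min + 1
        f0s, strengths = [], []
        if len(idx):
            order = np.argsort(r[idx])[::-1][: s.max_candidates]
            for i in idx[order]:
                lag, height = _parabolic(r, int(i))
                if height <= 0:
                    continue
                f = fs / lag
                if not (s.floor <= f <= s.ceiling):
                    continue
                # favour high-frequency candidates (octave disambiguation)
                strengths.append(
                    min(height, 1.0) - s.octave_cost * np.log2(s.floor * lag / fs)
                )
                f0s.append(f)
        # unvoiced candidate strength, rewarding silence
        rel = local_peaks[fi] / global_peak
        uv = s.voicing_threshold + max(0.0, 2.0 - rel / unvoiced_floor)
        f0s.append(np.nan)
        strengths.append(uv)
        cand_f0.append(np.array(f0s))
        cand_str.append(np.array(strengths))

    f0_path, str_path = _viterbi(cand_f0, cand_str, s)
    return PitchTrack(frame_times, f0_path, str_path)


def _viterbi(
    cand_f0: list[np.ndarray], cand_str: list[np.ndarray], s: PitchSettings
) -> tuple[np.ndarray, np.ndarray]:
    """Best path maximizing sum of candidate strengths minus transition
    costs (octave-jump cost between voiced frames, a fixed cost for
    voicing-state changes)."""
    n = len(cand_f0)
    f0 = np.full(n, np.nan)
    strength = np.zeros(n)
    if n == 0:
        return f0, strength
    score = cand_str[0].copy()
    back: list[np.ndarray] = []
    for t in range(1, n):
        prev_f, cur_f = cand_f0[t - 1], cand_f0[t]
        pv, cv = ~np.isnan(prev_f), ~np.isnan(cur_f)
        cost = np.zeros((len(prev_f), len(cur_f)))
        both = np.outer(pv, cv)
        if both.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                jumps = np.abs(np.log2(np.outer(prev_f, 1.0 / cur_f)))
            cost[both] = s.jump_cost * jumps[both]
        mixed = np.outer(pv, ~cv) | np.outer(~pv, cv)
        cost[mixed] = s.voiced_unvoiced_cost
        total = score[:, None] - cost
        best_prev = np.argmax(total, axis=0)
        score = total[best_prev, np.arange(len(cur_f))] + cand_str[t]
        back.append(best_prev)
    i = int(np.argmax(score))
    path = [i]
    for bp in reversed(back):
        i = int(bp[i])
        path.append(i)
    path.reverse()
    for t, i in enumerate(path):
        f0[t] = cand_f0[t][i]
        strength[t] = cand_str[t][i]
    return f0, strength


def call_f0_summary(track: PitchTrack) -> dict:
    """Per-call f0 statistics over voiced frames only.

    Returns f0_median / f0_mean as NaN when no frame is voiced (the call is
    then flagged untrackable upstream)."""
    voiced = track.f0[track.voiced]
    if len(voiced) == 0:
        return {
            "f0_median_hz": float("nan"),
            "f0_mean_hz": float("nan"),
            "voiced_fraction": 0.0,
            "n_voiced": 0,
        }
    return {
        "f0_median_hz": float(np.median(voiced)),
        "f0_mean_hz": float(np.mean(voiced)),
        "voiced_fraction": track.voiced_fraction,
        "n_voiced": int(len(voiced)),
    }
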