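"""Synthetic playback sessions: calibrated noise beds with embedded calls.

The generator emulates the structure of a noise-playback experiment on
harbour seal pups: nine 5-min blocks per session (three per noise condition,
order randomized with no two identical conditions in a row), a 250–500 Hz
bandpass noise bed at 65 dB SPL (high) or 45 dB SPL (low) over an
approx. 25 dB SPL ambient background, and harmonic pup-like calls whose
per-condition population median f0 and f0 dispersion are configurable.
Durations follow an untruncated lognormal parameterized jointly from the
observed mean (0.785 s) and median (0.729 s).

Every random draw descends from a single session seed through
:class:`numpy.random.SeedSequence` children, so any call can be re-synthesized
in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .audio import CONDITIONS, CallAnnotation, Waveform
from .calibration import CalibrationConvention, spl_to_rms

logger = logging.getLogger(__name__)

__all__ = [
    "SessionDesign",
    "SynthCallParams",
    "CallTruth",
    "ScheduledCall",
    "duration_lognormal_params",
    "draw_durations",
    "make_session_design",
    "synth_noise",
    "synth_call",
    "schedule_calls",
    "assemble_session",
    "simulate_feature_table",
]

#: Playback noise band edges, Hz.
NOISE_BAND = (250.0, 500.0)

#: Default per-condition playback levels, dB SPL.
NOISE_SPL = {"no_playback": 25.0, "low": 45.0, "high": 65.0}

#: Observed duration statistics used to parameterize the lognormal model, s.
DURATION_MEAN_S = 0.785
DURATION_MEDIAN_S = 0.729

#: Observed per-condition median f0, Hz.
F0_MEDIANS = {"no_playback": 403.0, "low": 374.0, "high": 324.0}


def duration_lognormal_params(
    mean_s: float = DURATION_MEAN_S, median_s: float = DURATION_MEDIAN_S
) -> tuple[float, float]:
    """Lognormal (mu, sigma) fitted jointly to a mean and median.

    For X ~ lognormal(mu, sigma): median = exp(mu) and
    mean = exp(mu + sigma^2/2), hence sigma = sqrt(2 ln(mean/median)).
    """
    if not (0 < median_s <= mean_s):
        raise ValueError("need 0 < median <= mean for a lognormal fit")
    return math.log(median_s), math.sqrt(2.0 * math.log(mean_s / median_s))


_DUR_MU, _DUR_SIGMA = duration_lognormal_params()


@dataclass(frozen=True)
class SessionDesign:
    """Ordered playback blocks: (condition, duration_s) with exactly three
    blocks per condition and no two adjacent blocks sharing a condition."""

    blocks: tuple[tuple[str, float], ...]
    seed: int

    def __post_init__(self) -> None:
        conds = [c for c, _ in self.blocks]
        for c in CONDITIONS:
            if conds.count(c) != 3:
                raise ValueError(f"need exactly 3 blocks of {c!r}, got {conds.count(c)}")
        for a, b in zip(conds, conds[1:]):
            if a == b:
                raise ValueError(f"adjacent blocks share condition {a!r}")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("all block durations must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.blocks)

    def block_bounds(self) -> list[tuple[float, float]]:
        """Absolute (start, end) seconds of each block."""
        bounds, t = [], 0.0
        for _, d in self.blocks:
            bounds.append((t, t + d))
            t += d
        return bounds


@dataclass(frozen=True)
class SynthCallParams:
    """Parameters of the harmonic call generator.

    f0 medians / CVs and source tilt are per noise condition; the defaults
    encode the observed condition medians, equal call level in every
    condition (75 dB SPL, i.e. no intrinsic amplitude response to noise, so
    the high-condition SNR is +10 dB), a common −6 dB/octave source tilt,
    and an f0 dispersion that is lower under high noise than in the other
    two conditions.
    """

    f0_median_by_condition: Mapping[str, float] = field(
        default_factory=lambda: dict(F0_MEDIANS)
    )
    f0_cv_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"no_playback": 0.08, "low": 0.08, "high": 0.05}
    )
    source_tilt_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {c: -6.0 for c in CONDITIONS}
    )
    call_spl_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {c: 75.0 for c in CONDITIONS}
    )
    duration_mu: float = _DUR_MU
    duration_sigma: float = _DUR_SIGMA
    n_harmonics: int = 20
    aspiration_db: float = -20.0
    jitter_cv: float = 0.004
    drift_depth: float = 0.03
    drift_rate_hz: tuple[float, float] = (2.0, 4.0)
    onset_ramp: float = 0.04
    f0_floor: float = 200.0
    f0_ceiling: float = 800.0

    def __post_init__(self) -> None:
        for c, m in self.f0_median_by_condition.items():
            if not (200.0 <= m <= 800.0):
                raise ValueError(f"f0 median for {c!r} outside [200, 800] Hz: {m}")
        if any(v < 0 for v in self.f0_cv_by_condition.values()):
            raise ValueError("f0 CVs must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class CallTruth:
    """Ground truth for one synthesized call."""

    f0_base_hz: float
    duration_s: float
    spl_db: float
    tilt_db_per_octave: float
    f0_contour_times: np.ndarray
    f0_contour_hz: np.ndarray


@dataclass(frozen=True)
class ScheduledCall:
    """One call's slot in a session: identity, placement, and the ground
    truth fixed at scheduling time."""

    seal_id: str
    block_index: int
    onset_s: float  # absolute, seconds from session start
    condition: str
    truth_f0_base: float
    truth_duration: float
    spl_db: float
    tilt_db_per_octave: float
    seed: int


class ScheduleOverflowError(ValueError):
    """Calls do not fit inside their blocks; lists the offenders."""

    def __init__(self, offenders: Sequence[ScheduledCall]):
        self.offenders = list(offenders)
        desc = ", ".join(
            f"{c.seal_id}@block{c.block_index}:{c.onset_s:.2f}s" for c in offenders
        )
        super().__init__(f"{len(offenders)} call(s) overflow their block: {desc}")


# ---------------------------------------------------------------------------
# Design


def make_session_design(
    block_duration_s: float | Mapping[str, float], seed: int
) -> SessionDesign:
    """Randomize the nine-block order uniformly over orderings with no two
    identical conditions in a row (rejection sampling from uniform
    permutations of the block multiset, which is uniform over the valid set).
    """
    if isinstance(block_duration_s, Mapping):
        durations = dict(block_duration_s)
    else:
        durations = {c: float(block_duration_s) for c in CONDITIONS}
    if any(d <= 0 for d in durations.values()):
        raise ValueError("block durations must be > 0")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(3), 3)
    while True:
        order = rng.permutation(labels)
        if not np.any(order[1:] == order[:-1]):
            break
    blocks = tuple((CONDITIONS[i], durations[CONDITIONS[i]]) for i in order)
    return SessionDesign(blocks=blocks, seed=seed)


# ---------------------------------------------------------------------------
# Noise


def synth_noise(
    condition: str,
    duration_s: float,
    sample_rate: float,
    cal: CalibrationConvention,
    seed: int | np.random.Generator,
    *,
    band_hz: tuple[float, float] = NOISE_BAND,
    spl_by_condition: Mapping[str, float] = NOISE_SPL,
) -> Waveform:
    """Stationary noise bed for one block.

    low/high: white Gaussian noise through a 4th-order Butterworth bandpass
    (250–500 Hz), applied forward-backward for zero phase, then RMS-scaled
    exactly to the condition level.  no_playback: broadband (white) ambient
    surrogate at its level.
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be > 0, got {duration_s}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration_s * sample_rate))
    x = rng.standard_normal(n)
    if condition != "no_playback":
        sos = sps.butter(
            4, band_hz, btype="bandpass", fs=sample_rate, output="sos"
        )
        x = sps.sosfiltfilt(sos, x)
    target_rms = spl_to_rms(spl_by_condition[condition], cal)
    x *= target_rms / np.sqrt(np.mean(np.square(x)))
    return Waveform(x, sample_rate)


# ---------------------------------------------------------------------------
# Calls


def _draw_f0_base(
    median: float, cv: float, rng: np.random.Generator,
    floor: float, ceiling: float,
) -> float:
    """Per-call f0 drawn lognormally: median exactly `median`, coefficient
    of variation `cv`; draws outside [floor, ceiling] are rejected and
    redrawn (logged)."""
    sigma = math.sqrt(math.log1p(cv * cv))
    for attempt in range(1000):
        f0 = median * math.exp(sigma * rng.standard_normal())
        if floor <= f0 <= ceiling:
            if attempt:
                logger.debug("f0 draw accepted after %d rejections", attempt)
            return f0
        logger.debug("rejected f0 draw %.1f Hz outside [%g, %g]", f0, floor, ceiling)
    raise RuntimeError("f0 rejection sampling failed; check medians/CVs")


def draw_durations(
    n: int, params: SynthCallParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw n call durations (s) from the lognormal duration model."""
    return np.exp(
        params.duration_mu + params.duration_sigma * rng.standard_normal(n)
    )


def synth_call(
    params: SynthCallParams,
    condition: str,
    cal: CalibrationConvention,
    sample_rate: float,
    seed: int | np.random.Generator,
    *,
    duration_s: float | None = None,
    f0_base_hz: float | None = None,
    spl_db: float | None = None,
    tilt_db_per_octave: float | None = None,
) -> tuple[Waveform, CallTruth]:
    """Synthesize one harmonic call and its ground truth.

    The source is a sum of ``n_harmonics`` partials at multiples of a
    time-varying f0 (per-call lognormal base x slow sinusoidal drift x
    per-cycle multiplicative jitter); harmonic amplitudes decay at the
    source tilt in dB/octave; raised-cosine ramps shape onset and offset;
    RMS is calibrated exactly to the call level.  Explicit keyword overrides
    pin any of the drawn quantities (the scheduler uses this so ground truth
    is fixed before assembly).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if duration_s is None:
        duration_s = float(draw_durations(1, params, rng)[0])
    if f0_base_hz is None:
        f0_base_hz = _draw_f0_base(
            params.f0_median_by_condition[condition],
            params.f0_cv_by_condition[condition],
            rng,
            params.f0_floor,
            params.f0_ceiling,
        )
    if spl_db is None:
        spl_db = params.call_spl_by_condition[condition]
    if tilt_db_per_octave is None:
        tilt_db_per_octave = params.source_tilt_by_condition[condition]

    n = max(int(round(duration_s * sample_rate)), 8)
    t = np.arange(n) / sample_rate

    drift_rate = rng.uniform(*params.drift_rate_hz)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = 1.0 + params.drift_depth * np.sin(
        2.0 * np.pi * drift_rate * t + drift_phase
    )
    if params.jitter_cv > 0:
        cycle = max(int(round(sample_rate / f0_base_hz)), 1)
        n_cycles = n // cycle + 2
        j = np.repeat(
            1.0 + params.jitter_cv * rng.standard_normal(n_cycles), cycle
        )[:n]
    else:
        j = 1.0
    f_inst = f0_base_hz * drift * j

    phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
    nyq = 0.45 * sample_rate
    k_max = min(params.n_harmonics, int(nyq / float(np.max(f_inst))))
    k_max = max(k_max, 1)
    k = np.arange(1, k_max + 1)
    amps = 10.0 ** (tilt_db_per_octave * np.log2(k) / 20.0)
    x = np.sin(np.outer(k, phase)).T @ amps

    if params.aspiration_db > -80.0:
        # breathy (aspiration) component: broadband noise shaped to the same
        # source tilt, at a fixed level below the harmonic part — keeps the
        # spectrum dense between harmonics, as in real (noisy, reverberant)
        # calls, instead of window-leakage-only valleys
        spec = np.fft.rfft(rng.standard_normal(n))
        f_bins = np.fft.rfftfreq(n, 1.0 / sample_rate)
        shape = 10.0 ** (
            tilt_db_per_octave
            * np.log2(np.maximum(f_bins, f0_base_hz) / f0_base_hz)
            / 20.0
        )
        shape[f_bins > k_max * f0_base_hz * 1.05] = 0.0
        asp = np.fft.irfft(spec * shape, n)
        asp_rms = np.sqrt(np.mean(np.square(asp)))
        if asp_rms > 0:
            x_rms = np.sqrt(np.mean(np.square(x)))
            asp *= 10.0 ** (params.aspiration_db / 20.0) * x_rms / asp_rms
            x = x + asp

    ramp_n = min(int(round(params.onset_ramp * sample_rate)), n // 4)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]

    x *= spl_to_rms(spl_db, cal) / np.sqrt(np.mean(np.square(x)))

    step = 0.01
    ct = np.arange(0.0, duration_s, step)
    contour = np.interp(ct, t, f_inst)
    truth = CallTruth(
        f0_base_hz=f0_base_hz,
        duration_s=duration_s,
        spl_db=spl_db,
        tilt_db_per_octave=tilt_db_per_octave,
        f0_contour_times=ct,
        f0_contour_hz=contour,
    )
    return Waveform(x, sample_rate), truth


# ---------------------------------------------------------------------------
# Scheduling and assembly


def schedule_calls(
    design: SessionDesign,
    params: SynthCallParams,
    seal_ids: Sequence[str],
    calls_per_block: float,
    seed: int | np.random.SeedSequence,
    *,
    f0_scale_by_seal: Mapping[str, float] | None = None,
    spl_offset_by_seal_condition: Mapping[tuple[str, str], float] | None = None,
    tilt_offset_by_seal_condition: Mapping[tuple[str, str], float] | None = None,
    min_gap_s: float = 0.05,
) -> list[ScheduledCall]:
    """Draw each seal's calls for every block and place them without
    temporal overlap (across all seals, so the default sessions screen
    clean).  ``calls_per_block`` is the Poisson mean per seal per block;
    ``f0_scale_by_seal`` applies a multiplicative per-individual f0 offset;
    the per-(seal, condition) overrides express Lombard-type responses
    (intensity gain in dB, tilt flattening in dB/octave).
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    f0_scale_by_seal = f0_scale_by_seal or {}
    spl_offset_by_seal_condition = spl_offset_by_seal_condition or {}
    tilt_offset_by_seal_condition = tilt_offset_by_seal_condition or {}

    scheduled: list[ScheduledCall] = []
    bounds = design.block_bounds()
    for b, ((condition, block_dur), (b0, _b1)) in enumerate(
        zip(design.blocks, bounds)
    ):
        occupied: list[tuple[float, float]] = []
        for seal in seal_ids:
            n_calls = rng.poisson(calls_per_block)
            for _ in range(n_calls):
                call_seed = int(rng.integers(0, 2**31 - 1))
                crng = np.random.default_rng(call_seed)
                dur = float(draw_durations(1, params, crng)[0])
                f0 = _draw_f0_base(
                    params.f0_median_by_condition[condition]
                    * f0_scale_by_seal.get(seal, 1.0),
                    params.f0_cv_by_condition[condition],
                    crng,
                    params.f0_floor,
                    params.f0_ceiling,
                )
                if dur + 2 * min_gap_s >= block_dur:
                    continue  # cannot fit; skip rather than truncate
                placed = False
                for _try in range(50):
                    onset = b0 + rng.uniform(min_gap_s, block_dur - dur - min_gap_s)
                    iv = (onset - min_gap_s, onset + dur + min_gap_s)
                    if all(iv[1] <= o0 or iv[0] >= o1 for o0, o1 in occupied):
                        occupied.append(iv)
                        placed = True
                        break
                if not placed:
                    logger.debug("block %d full; dropping a call for %s", b, seal)
                    continue
                scheduled.append(
                    ScheduledCall(
                        seal_id=seal,
                        block_index=b,
                        onset_s=onset,
                        condition=condition,
                        truth_f0_base=f0,
                        truth_duration=dur,
                        spl_db=params.call_spl_by_condition[condition]
                        + spl_offset_by_seal_condition.get((seal, condition), 0.0),
                        tilt_db_per_octave=params.source_tilt_by_condition[condition]
                        + tilt_offset_by_seal_condition.get((seal, condition), 0.0),
                        seed=call_seed,
                    )
                )
    scheduled.sort(key=lambda c: c.onset_s)
    return scheduled


def assemble_session(
    design: SessionDesign,
    params: SynthCallParams,
    schedule: Sequence[ScheduledCall],
    cal: CalibrationConvention,
    seed: int,
    *,
    sample_rate: float = 16000.0,
    session_id: str = "S0",
) -> tuple[Waveform, list[CallAnnotation], Waveform]:
    """Render the session: noise bed per block (child seeds from the session
    seed), calls added sample-wise on top, and the matched noise-only
    rendering of the identical design (identical noise realization — the
    surrogate for separate noise-only recordings).

    Raises :class:`ScheduleOverflowError` if any call crosses its block
    boundary, listing the offending calls.
    """
    bounds = design.block_bounds()
    offenders = [
        c
        for c in schedule
        if not (
            bounds[c.block_index][0] <= c.onset_s
            and c.onset_s + c.truth_duration <= bounds[c.block_index][1]
        )
    ]
    if offenders:
        raise ScheduleOverflowError(offenders)

    ss = np.random.SeedSequence(seed)
    block_seeds = ss.spawn(len(design.blocks))
    noise_parts = [
        synth_noise(
            cond, dur, sample_rate, cal, np.random.default_rng(bs)
        ).samples
        for (cond, dur), bs in zip(design.blocks, block_seeds)
    ]
    noise = np.concatenate(noise_parts)
    session = noise.copy()

    annotations: list[CallAnnotation] = []
    trial_counter: dict[str, int] = {}
    for c in schedule:
        w, truth = synth_call(
            params,
            c.condition,
            cal,
            sample_rate,
            c.seed,
            duration_s=c.truth_duration,
            f0_base_hz=c.truth_f0_base,
            spl_db=c.spl_db,
            tilt_db_per_octave=c.tilt_db_per_octave,
        )
        i0 = int(round(c.onset_s * sample_rate))
        session[i0 : i0 + len(w.samples)] += w.samples
        trial = trial_counter.get(c.seal_id, 0)
        trial_counter[c.seal_id] = trial + 1
        annotations.append(
            CallAnnotation(
                session_id=session_id,
                seal_id=c.seal_id,
                condition=c.condition,
                trial_index=trial,
                block_index=c.block_index,
                onset_s=i0 / sample_rate,
                offset_s=(i0 + len(w.samples)) / sample_rate,
                extra={
                    "true_f0_hz": truth.f0_base_hz,
                    "true_duration_s": truth.duration_s,
                    "true_spl_db": truth.spl_db,
                    "true_tilt_db_per_oct": truth.tilt_db_per_octave,
                },
            )
        )
    peak = float(np.max(np.abs(session))) if len(session) else 0.0
    if peak > 1.0:
        raise ValueError(
            f"assembled session exceeds full scale (peak {peak:.3f}); "
            "lower call or noise levels"
        )
    return (
        Waveform(session, sample_rate),
        annotations,
        Waveform(noise, sample_rate),
    )


# ---------------------------------------------------------------------------
# Distribution-level surrogate (no audio)


def simulate_feature_table(
    n_sessions: int,
    seed: int,
    *,
    seals_per_session: int = 2,
    calls_per_block: float = 2.0,
    condition_effect: Mapping[str, float] | None = None,
    sd_session: float = 0.0,
    sd_seal: float = 0.0,
    sd_resid: float = 1.0,
    n_pairs: int | None = None,
):
    """Simulate a per-call response table with the experiment's grouping
    structure (sessions x seals x nine randomized blocks) but no audio.

    The response is `condition_effect[condition] + session intercept +
    seal intercept + residual`.  Used for statistical calibration studies
    (type-I error, power, variance-component recovery) where synthesizing
    audio would add nothing.
    """
    import pandas as pd

    condition_effect = condition_effect or {c: 0.0 for c in CONDITIONS}
    rng = np.random.default_rng(seed)
    if n_pairs is None:
        n_pairs = max(n_sessions // 7, 1)
    seal_names = [
        f"seal_{chr(ord('A') + i)}" for i in range(n_pairs * seals_per_session)
    ]
    seal_u = {s: sd_seal * rng.standard_normal() for s in seal_names}
    rows = []
    for s in range(n_sessions):
        pair = s * n_pairs // n_sessions
        seals = seal_names[
            pair * seals_per_session : (pair + 1) * seals_per_session
        ]
        design = make_session_design(1.0, int(rng.integers(0, 2**31 - 1)))
        sess_u = sd_session * rng.standard_normal()
        trial = {seal: 0 for seal in seals}
        for b, (cond, _d) in enumerate(design.blocks):
            for seal in seals:
                for _ in range(rng.poisson(calls_per_block)):
                    rows.append(
                        {
                            "session_id": f"S{s}",
                            "seal_id": seal,
                            "condition": cond,
                            "block_index": b,
                            "trial_index": trial[seal],
                            "y": condition_effect[cond]
                            + sess_u
                            + seal_u[seal]
                            + sd_resid * rng.standard_normal(),
                        }
                    )
                    trial[seal] += 1
    return pd.DataFrame(rows)
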