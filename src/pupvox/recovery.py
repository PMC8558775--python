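"""Parameter-recovery experiments.

Each experiment synthesizes data under known ground truth, runs the full
measurement chain, and reports how well the pipeline recovers the planted
quantity.  They are the package's calibration battery:

* SNR chain — default-level calls over high-condition noise through gain
  compensation and noise-compensated intensity; the mean estimated SNR
  should sit at the design value (call level − noise level = +10 dB).
* f0 recovery — per-condition medians recovered by screening + pitch
  tracking when the generator's population medians are the observed
  condition medians (324 / 374 / 403 Hz).
* Tilt-difference recovery — two conditions whose true source slopes
  differ by a known flattening; estimated as the difference of
  condition-mean one-third-octave slopes.  The two conditions share call
  draws (common random numbers), isolating the tilt difference from f0
  placement variability.
* Duration calibration — the sample mean of lognormal duration draws
  against the jointly fitted mean/median.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .audio import CallAnnotation, CallClip, Waveform, screen_calls
from .calibration import CalibrationConvention
from .pitch import PitchSettings, call_f0_summary, track_pitch
from .spectral import (
    apply_gain_compensation,
    call_intensity,
    call_tilt_measures,
    estimate_session_gain,
)
from . import synth as sy

__all__ = [
    "snr_experiment",
    "f0_recovery_experiment",
    "tilt_difference_experiment",
    "duration_mean_experiment",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def snr_experiment(
    seed: int,
    n_calls: int = 216,
    *,
    block_duration_s: float = 30.0,
    calls_per_block: float = 6.0,
    preamp_gain_sd_db: float = 2.0,
) -> dict:
    """Mean pipeline-estimated SNR of default-level calls in high noise.

    Assembles full sessions (so the gain-compensation step is exercised
    against a varying preamp gain), then averages ``snr_db`` over
    high-condition calls with positive compensated intensity until at
    least ``n_calls`` calls have been measured.
    """
    cal = CalibrationConvention()
    params = sy.SynthCallParams()
    fs = 16000.0
    snrs: list[float] = []
    session_seeds = iter(_child_seeds(seed, 64))
    while len(snrs) < n_calls:
        s = next(session_seeds)
        design = sy.make_session_design(block_duration_s, s)
        schedule = sy.schedule_calls(
            design, params, ["a", "b"], calls_per_block, s + 1
        )
        session, annots, noise = sy.assemble_session(
            design, params, schedule, cal, s + 2, sample_rate=fs
        )
        preamp_db = preamp_gain_sd_db * np.random.default_rng(s + 3).standard_normal()
        recorded = Waveform(session.samples * 10 ** (preamp_db / 20.0), fs)
        gain = estimate_session_gain(
            recorded,
            annots,
            design.block_bounds(),
            [c for c, _ in design.blocks],
            noise,
        )
        comp = apply_gain_compensation(recorded, gain)
        for a in annots:
            if a.condition != "high":
                continue
            clip = CallClip(
                annotation=a,
                waveform=comp.slice_seconds(a.onset_s, a.offset_s),
                context_noise=noise.slice_seconds(a.onset_s, a.offset_s),
            )
            res = call_intensity(clip)
            if res.call_intensity > 0:
                snrs.append(res.snr_db)
    arr = np.asarray(snrs[: max(n_calls, len(snrs))])
    return {
        "mean_snr_db": float(arr.mean()),
        "n_calls": int(len(arr)),
        "design_snr_db": params.call_spl_by_condition["high"] - sy.NOISE_SPL["high"],
    }


def f0_recovery_experiment(
    seed: int,
    n_per_condition: int = 200,
    *,
    settings: PitchSettings | None = None,
) -> dict:
    """Recovered per-condition median f0 after screening and pitch tracking.

    Calls are synthesized with the generator's default condition medians,
    mixed over the matching noise bed, screened (clipping, trackability),
    and tracked; the recovered statistic is the median over calls of the
    per-call median f0.
    """
    cal = CalibrationConvention()
    params = sy.SynthCallParams()
    settings = settings or PitchSettings()
    fs = 16000.0
    out: dict[str, dict] = {}
    cond_seeds = _child_seeds(seed, 3)
    for cond, cseed in zip(("no_playback", "low", "high"), cond_seeds):
        clips = []
        truths = []
        call_seeds = _child_seeds(cseed, 2 * n_per_condition)
        for i in range(n_per_condition):
            w, truth = sy.synth_call(params, cond, cal, fs, call_seeds[2 * i])
            noise = sy.synth_noise(
                cond, truth.duration_s + 0.05, fs, cal, call_seeds[2 * i + 1]
            ).samples[: len(w.samples)]
            ann = CallAnnotation(
                session_id="sim",
                seal_id="a",
                condition=cond,
                trial_index=i,
                onset_s=float(i),
                offset_s=float(i) + truth.duration_s,
            )
            clips.append(
                CallClip(
                    annotation=ann,
                    waveform=Waveform(w.samples + noise, fs),
                    context_noise=Waveform(noise, fs),
                )
            )
            truths.append(truth)
        tracks: dict[int, object] = {}

        def voiced_fraction(w, _cache=tracks):
            tr = track_pitch(w, settings)
            _cache[id(w)] = tr
            return tr.voiced_fraction

        screening = screen_calls(clips, voiced_fraction)
        medians = []
        for clip in screening.clean:
            tr = tracks.get(id(clip.waveform)) or track_pitch(
                clip.waveform, settings
            )
            medians.append(call_f0_summary(tr)["f0_median_hz"])
        out[cond] = {
            "recovered_median_hz": float(np.median(medians)),
            "true_median_hz": params.f0_median_by_condition[cond],
            "n_clean": len(medians),
            "n_total": n_per_condition,
        }
    return out


def tilt_difference_experiment(
    seed: int,
    n_per_condition: int = 300,
    flattening_db_per_octave: float = 0.31,
    conditions: tuple[str, str] = ("no_playback", "low"),
) -> dict:
    """Recovered between-condition spectral-slope difference.

    The two conditions share call draws (same f0, duration, drift, jitter
    per index) and differ only in the true source tilt — the baseline tilt
    in the first condition, flattened (less negative) by
    ``flattening_db_per_octave`` in the second — and in the noise bed they
    are mixed over.  The estimate is the difference of condition-mean
    one-third-octave slopes after gain compensation and spectral
    subtraction.
    """
    cal = CalibrationConvention()
    params = sy.SynthCallParams()
    fs = 16000.0
    base_tilt = params.source_tilt_by_condition[conditions[0]]
    tilts = (base_tilt, base_tilt + flattening_db_per_octave)
    call_seeds = _child_seeds(seed, 2 * n_per_condition)
    slopes: dict[str, list[float]] = {c: [] for c in conditions}
    for i in range(n_per_condition):
        for cond, tilt in zip(conditions, tilts):
            w, truth = sy.synth_call(
                params,
                conditions[0],
                cal,
                fs,
                call_seeds[2 * i],
                tilt_db_per_octave=tilt,
            )
            noise = sy.synth_noise(
                cond, truth.duration_s + 0.05, fs, cal, call_seeds[2 * i + 1]
            ).samples[: len(w.samples)]
            ann = CallAnnotation(
                session_id="sim",
                seal_id="a",
                condition=cond,
                trial_index=i,
                onset_s=0.0,
                offset_s=truth.duration_s,
            )
            clip = CallClip(
                annotation=ann,
                waveform=Waveform(w.samples + noise, fs),
                context_noise=Waveform(noise, fs),
            )
            tm = call_tilt_measures(clip)
            slopes[cond].append(tm.octave_slope_db_per_oct)
    means = {
        c: float(np.nanmean(np.asarray(v))) for c, v in slopes.items()
    }
    return {
        "estimated_difference_db_per_oct": means[conditions[1]]
        - means[conditions[0]],
        "true_difference_db_per_oct": flattening_db_per_octave,
        "condition_mean_slopes": means,
        "n_per_condition": n_per_condition,
    }


def duration_mean_experiment(seed: int, n: int = 2000) -> dict:
    """Sample mean of lognormal duration draws under the jointly fitted
    mean/median parameterization."""
    params = sy.SynthCallParams()
    rng = np.random.default_rng(seed)
    draws = sy.draw_durations(n, params, rng)
    return {
        "sample_mean_s": float(draws.mean()),
        "target_mean_s": sy.DURATION_MEAN_S,
        "sample_median_s": float(np.median(draws)),
        "n": n,
    }
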