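"""End-to-end orchestration: generate -> screen -> features -> stats -> report.

Each stage persists its outputs as plain text (tables) and WAV (audio), so
any stage can be re-run from the previous stage's artifacts with identical
results.  All randomness descends from one global seed through
`numpy.random.SeedSequence`; the log records every session seed consumed.

Desk-scale defaults: 14 sessions of nine 30 s blocks (the field design used
5-min blocks; block duration is a config field so the full design remains
expressible), two seals per session, seven sessions per pair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import audio as au
from . import spectral as sp
from . import stats as st
from . import synth as sy
from .calibration import CalibrationConvention
from .pitch import PitchSettings, call_f0_summary, track_pitch

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end", "generate", "features", "run_stats", "report"]


@dataclass
class RunConfig:
    """Full configuration of a synthetic run.

    ``lombard_seals`` maps a seal id to (intensity gain in dB, tilt
    flattening in dB/octave) applied in both playback conditions — the
    mechanism for emulating an individual Lombard responder.
    """

    seed: int = 0
    sample_rate: float = 16000.0
    cal_db: float = 100.0
    n_sessions: int = 14
    seals_per_session: int = 2
    n_pairs: int = 2
    block_duration_s: float = 30.0
    calls_per_block: float = 2.0
    preamp_gain_sd_db: float = 2.0
    seal_f0_scale_sd: float = 0.02
    lombard_seals: dict = field(default_factory=dict)
    call_params: dict = field(default_factory=dict)
    pitch: dict = field(default_factory=dict)
    n_perm: int = 1000
    min_calls_for_stats: int = 20

    @property
    def cal(self) -> CalibrationConvention:
        return CalibrationConvention(self.cal_db)

    @property
    def synth_params(self) -> sy.SynthCallParams:
        return sy.SynthCallParams(**self.call_params)

    @property
    def pitch_settings(self) -> PitchSettings:
        return PitchSettings(**self.pitch)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _seal_ids(config: RunConfig) -> list[list[str]]:
    """Per-session seal lists: pairs stay together across their sessions."""
    all_seals = [
        f"seal_{chr(ord('A') + i)}"
        for i in range(config.n_pairs * config.seals_per_session)
    ]
    per_session = []
    for s in range(config.n_sessions):
        pair = min(s * config.n_pairs // config.n_sessions, config.n_pairs - 1)
        per_session.append(
            all_seals[
                pair * config.seals_per_session : (pair + 1)
                * config.seals_per_session
            ]
        )
    return per_session


# ---------------------------------------------------------------------------
# Stage 1: generate


def generate(config: RunConfig, out_dir: Path) -> None:
    """Synthesize all sessions: audio, matched noise-only audio, block
    designs and ground-truth annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cal = config.cal
    params = config.synth_params
    ss = np.random.SeedSequence(config.seed)
    seal_lists = _seal_ids(config)

    # per-seal f0 scale (stable individual identity across sessions)
    all_seals = sorted({s for seals in seal_lists for s in seals})
    id_rng = np.random.default_rng(ss.spawn(1)[0])
    f0_scale = {
        s: float(np.exp(config.seal_f0_scale_sd * id_rng.standard_normal()))
        for s in all_seals
    }
    spl_off, tilt_off = {}, {}
    for seal, (gain_db, flatten) in config.lombard_seals.items():
        for cond, frac in (("low", 0.5), ("high", 1.0)):
            spl_off[(seal, cond)] = gain_db * frac
            tilt_off[(seal, cond)] = flatten  # flattening in both conditions

    annotations: list[au.CallAnnotation] = []
    design_rows = []
    seed_log = {"global_seed": config.seed, "sessions": {}}
    for i in range(config.n_sessions):
        sid = f"S{i:02d}"
        child = ss.spawn(1)[0]
        session_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        seed_log["sessions"][sid] = session_seed
        design = sy.make_session_design(config.block_duration_s, session_seed)
        schedule = sy.schedule_calls(
            design,
            params,
            seal_lists[i],
            config.calls_per_block,
            session_seed + 1,
            f0_scale_by_seal=f0_scale,
            spl_offset_by_seal_condition=spl_off,
            tilt_offset_by_seal_condition=tilt_off,
        )
        session, annots, noise = sy.assemble_session(
            design, params, schedule, cal, session_seed + 2,
            sample_rate=config.sample_rate, session_id=sid,
        )
        # preamp gain varies per session; the noise-only reference is on the
        # nominal scale, so the features stage must compensate
        gain_rng = np.random.default_rng(session_seed + 3)
        preamp_db = config.preamp_gain_sd_db * gain_rng.standard_normal()
        recorded = au.Waveform(
            session.samples * 10 ** (preamp_db / 20.0), session.sample_rate
        )
        au.write_wav(out_dir / f"{sid}.wav", recorded)
        au.write_wav(out_dir / f"{sid}_noise.wav", noise)
        annotations.extend(annots)
        for b, ((cond, _d), (b0, b1)) in enumerate(
            zip(design.blocks, design.block_bounds())
        ):
            design_rows.append(
                {
                    "session_id": sid,
                    "block_index": b,
                    "condition": cond,
                    "start_s": b0,
                    "end_s": b1,
                }
            )
    au.write_annotations(out_dir / "annotations.tsv", annotations)
    pd.DataFrame(design_rows).to_csv(out_dir / "designs.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "seeds.json", "w") as fh:
        json.dump(seed_log, fh, indent=2)
    logger.info("generated %d sessions, %d calls", config.n_sessions, len(annotations))


# ---------------------------------------------------------------------------
# Stage 2: features


def features(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Screen calls and extract per-call features from persisted audio.

    Per session: estimate and apply the preamp gain against the noise-only
    reference, cut gain-compensated call clips with matched noise
    intervals, apply the four screening criteria, then compute f0 summary,
    noise-compensated intensity / SNR and both tilt measures for clean
    calls.  Duration is recorded for every call (rate/duration analyses use
    the full call set)."""
    out_dir = Path(out_dir)
    annots = au.read_annotations(out_dir / "annotations.tsv")
    designs = pd.read_csv(out_dir / "designs.tsv", sep="\t")
    settings = config.pitch_settings
    rows = []
    for sid, sess_annots in _group_by_session(annots).items():
        session = au.read_wav(out_dir / f"{sid}.wav")
        noise = au.read_wav(out_dir / f"{sid}_noise.wav")
        d = designs[designs["session_id"] == sid].sort_values("block_index")
        bounds = list(zip(d["start_s"], d["end_s"]))
        conds = list(d["condition"])
        gain = sp.estimate_session_gain(session, sess_annots, bounds, conds, noise)
        comp = sp.apply_gain_compensation(session, gain)
        clips = [
            au.CallClip(
                annotation=a,
                waveform=comp.slice_seconds(a.onset_s, a.offset_s),
                context_noise=noise.slice_seconds(a.onset_s, a.offset_s),
            )
            for a in sess_annots
        ]
        tracks = {}

        def voiced_fraction(w, _cache=tracks):
            tr = track_pitch(w, settings)
            _cache[id(w)] = tr
            return tr.voiced_fraction

        screening = au.screen_calls(clips, voiced_fraction)
        for clip in screening.all_clips:
            a = clip.annotation
            row = {
                "session_id": a.session_id,
                "seal_id": a.seal_id,
                "condition": a.condition,
                "block_index": a.block_index,
                "trial_index": a.trial_index,
                "onset_s": a.onset_s,
                "duration_s": a.duration_s,
                "clean": a.is_clean,
                "session_gain": gain,
            }
            row.update({k: v for k, v in a.extra.items()})
            if a.is_clean:
                tr = tracks.get(id(clip.waveform)) or track_pitch(
                    clip.waveform, settings
                )
                row.update(call_f0_summary(tr))
                intensity = sp.call_intensity(clip)
                row["intensity_linear"] = intensity.call_intensity
                row["snr_db"] = intensity.snr_db
                tilt = sp.call_tilt_measures(clip)
                row["octave_slope_db_per_oct"] = tilt.octave_slope_db_per_oct
                row["r14_db"] = tilt.r14_db
                row["n_positive_bands"] = tilt.n_positive_bands
                row["discard_reason"] = tilt.discard_reason.value
            rows.append(row)
        logger.info(
            "session %s: %d calls, %d clean, gain %.3f",
            sid, len(clips), len(screening.clean), gain,
        )
    if rows:
        table = pd.DataFrame(rows)
    else:
        table = pd.DataFrame(
            columns=[
                "session_id", "seal_id", "condition", "block_index",
                "trial_index", "onset_s", "duration_s", "clean",
            ]
        )
    table.to_csv(out_dir / "features.tsv", sep="\t", index=False)
    return table


def _group_by_session(annots):
    out: dict[str, list] = {}
    for a in annots:
        out.setdefault(a.session_id, []).append(a)
    return out


# ---------------------------------------------------------------------------
# Stage 3: stats


def run_stats(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Run the inference battery on the persisted feature table.

    Degenerate inputs (too few calls) produce an 'insufficient data' row
    instead of a failure."""
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / "features.tsv", sep="\t")
    results: list[dict] = []

    def guarded(fn, *args, fallback=None, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as exc:
            logger.warning("skipping %s: %s", getattr(fn, "__name__", fn), exc)
            return fallback

    def add(res: st.StatResult | None, note: str = "") -> None:
        if res is None:
            return
        results.append(
            {
                "comparison": res.comparison,
                "response": res.response,
                "statistic": res.statistic,
                "p_perm": res.p_perm,
                "pseudo_r2": res.pseudo_r2,
                "n": res.n,
                "alpha_adjusted": res.alpha_adjusted,
                "significant": res.significant,
                "note": note,
            }
        )

    if len(table) < config.min_calls_for_stats:
        pd.DataFrame(
            [{"comparison": "none", "response": "all", "note": "insufficient data"}]
        ).to_csv(out_dir / "results.tsv", sep="\t", index=False)
        logger.warning("too few calls (%d) for statistics", len(table))
        return pd.read_csv(out_dir / "results.tsv", sep="\t")

    clean = table[table["clean"]].copy()
    seed = config.seed + 1

    # number of calls per session x seal x condition cell
    counts = (
        table.groupby(["session_id", "seal_id", "condition"])
        .size()
        .rename("n_calls")
        .reset_index()
    )
    spec_counts = st.ModelSpec(
        response="n_calls", fixed=("condition",), n_perm=config.n_perm, seed=seed
    )
    add(guarded(st.condition_main_test, counts, spec_counts))

    spec_dur = st.ModelSpec(response="duration_s", n_perm=config.n_perm, seed=seed + 10)
    add(guarded(st.condition_main_test, table, spec_dur))

    if len(clean) >= config.min_calls_for_stats:
        spec_f0 = st.ModelSpec(
            response="f0_median_hz", n_perm=config.n_perm, seed=seed + 20
        )
        add(guarded(st.condition_main_test, clean, spec_f0))
        for res in guarded(st.pairwise_condition_tests, clean, spec_f0) or []:
            add(res)

        for res in guarded(st.per_seal_intensity_tests, clean) or []:
            add(res, note="mann_whitney")

    # coefficient of variation (duration over all calls, f0 over clean)
    cv_dur_table, cv_dur = guarded(
        st.coefficient_of_variation,
        table,
        "duration_s",
        st.ModelSpec(response="cv", fixed=("condition",), n_perm=config.n_perm, seed=seed + 30),
        fallback=(pd.DataFrame(), None),
    )
    if cv_dur is not None:
        add(
            st.StatResult(
                comparison=cv_dur.comparison, response="cv_duration",
                statistic=cv_dur.statistic, p_perm=cv_dur.p_perm,
                pseudo_r2=cv_dur.pseudo_r2, n=cv_dur.n,
                alpha_adjusted=cv_dur.alpha_adjusted,
            )
        )
    cv_f0_table, cv_f0 = guarded(
        st.coefficient_of_variation,
        clean,
        "f0_median_hz",
        st.ModelSpec(response="cv", fixed=("condition",), n_perm=config.n_perm, seed=seed + 40),
        fallback=(pd.DataFrame(), None),
    )
    if cv_f0 is not None:
        add(
            st.StatResult(
                comparison=cv_f0.comparison, response="cv_f0",
                statistic=cv_f0.statistic, p_perm=cv_f0.p_perm,
                pseudo_r2=cv_f0.pseudo_r2, n=cv_f0.n,
                alpha_adjusted=cv_f0.alpha_adjusted,
            )
        )
        if len(cv_f0_table) >= 8:
            cv_spec = st.ModelSpec(
                response="cv", fixed=("condition",), n_perm=config.n_perm, seed=seed + 50
            )
            for res in guarded(st.pairwise_condition_tests, cv_f0_table, cv_spec) or []:
                add(
                    st.StatResult(
                        comparison=res.comparison, response="cv_f0",
                        statistic=res.statistic, p_perm=res.p_perm,
                        pseudo_r2=res.pseudo_r2, n=res.n,
                        alpha_adjusted=res.alpha_adjusted,
                    )
                )
    cv_f0_table.to_csv(out_dir / "cv_f0.tsv", sep="\t", index=False)
    cv_dur_table.to_csv(out_dir / "cv_duration.tsv", sep="\t", index=False)
    res_df = pd.DataFrame(results)
    res_df.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    return res_df


# ---------------------------------------------------------------------------
# Stage 4: report


def report(config: RunConfig, out_dir: Path) -> str:
    """Human-readable report: valid-session count, recovery scores of the
    estimators against ground truth, result sentences, and the qualitative
    checklist."""
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / "features.tsv", sep="\t")
    try:
        results = pd.read_csv(out_dir / "results.tsv", sep="\t")
    except FileNotFoundError:
        results = pd.DataFrame()

    lines = ["# Synthetic playback run report", ""]
    n_sessions = table["session_id"].nunique() if len(table) else 0
    valid = 0
    for sid, grp in table.groupby("session_id"):
        per_seal = grp.groupby("seal_id").size()
        if len(per_seal) and (per_seal >= 2).all():
            valid += 1
    lines.append(f"sessions: {n_sessions}  valid sessions (>=2 calls per pup): {valid}")
    lines.append(f"calls: {len(table)}  clean: {int(table['clean'].sum()) if len(table) else 0}")
    lines.append("")

    if len(table) and "f0_median_hz" in table.columns:
        lines.append("## Recovery scores (estimate vs ground truth)")
        clean = table[table["clean"]]
        for cond in au.CONDITIONS:
            sub = clean[clean["condition"] == cond]
            if not len(sub):
                continue
            est = float(sub["f0_median_hz"].median())
            true = float(sub["true_f0_hz"].median())
            lines.append(
                f"f0 median [{cond}]: estimated {est:.1f} Hz, true {true:.1f} Hz, "
                f"error {est - true:+.1f} Hz"
            )
        if "snr_db" in clean.columns:
            high = clean[clean["condition"] == "high"]["snr_db"].dropna()
            if len(high):
                lines.append(f"mean SNR in high noise: {high.mean():.2f} dB")
        if "octave_slope_db_per_oct" in clean.columns:
            for cond in au.CONDITIONS:
                sub = clean[clean["condition"] == cond]
                sl = sub["octave_slope_db_per_oct"].dropna()
                if len(sl):
                    lines.append(
                        f"octave slope [{cond}]: mean {sl.mean():.2f} dB/oct "
                        f"(true source tilt {sub['true_tilt_db_per_oct'].mean():.2f})"
                    )
        lines.append("")

    if len(results) and "p_perm" in results.columns:
        lines.append("## Results")
        for _, r in results.iterrows():
            if pd.isna(r.get("p_perm")):
                continue
            star = "*" if bool(r.get("significant")) else ""
            r2 = (
                f"pseudoR2 = {r['pseudo_r2']:.3f}; "
                if pd.notna(r.get("pseudo_r2"))
                else ""
            )
            lines.append(
                f"{r['response']} [{r['comparison']}]: {r2}p = {r['p_perm']:.4g}; "
                f"N = {int(r['n'])} (alpha = {r['alpha_adjusted']:.4g}){star}"
            )
        lines.append("")
        lines.append("## Qualitative checklist")
        chk = _qualitative_checklist(results)
        for name, ok in chk.items():
            lines.append(f"[{'x' if ok else ' '}] {name}")
    else:
        lines.append("statistics: insufficient data")

    text = "\n".join(lines) + "\n"
    (out_dir / "report.txt").write_text(text)
    return text


def _qualitative_checklist(results: pd.DataFrame) -> dict:
    def sig(response, comparison):
        m = results[
            (results["response"] == response)
            & (results["comparison"] == comparison)
        ]
        return bool(m["significant"].iloc[0]) if len(m) else False

    return {
        "f0 main effect significant": sig("f0_median_hz", "all_conditions"),
        "all three f0 pairs significant": all(
            sig("f0_median_hz", c)
            for c in ["no_playback_vs_low", "no_playback_vs_high", "low_vs_high"]
        ),
        "no n_calls effect": not sig("n_calls", "all_conditions"),
        "no duration effect": not sig("duration_s", "all_conditions"),
        "no duration-CV effect": not sig("cv_duration", "all_conditions"),
        "f0-CV effect present": sig("cv_f0", "all_conditions"),
        "f0-CV high vs others only": (
            sig("cv_f0", "no_playback_vs_high")
            and sig("cv_f0", "low_vs_high")
            and not sig("cv_f0", "no_playback_vs_low")
        ),
    }


def run_end_to_end(config: RunConfig, out_dir: Path) -> dict:
    """Run all stages; returns paths of the main artifacts."""
    out_dir = Path(out_dir)
    generate(config, out_dir)
    features(config, out_dir)
    run_stats(config, out_dir)
    report(config, out_dir)
    return {
        "audio": out_dir,
        "annotations": out_dir / "annotations.tsv",
        "features": out_dir / "features.tsv",
        "results": out_dir / "results.tsv",
        "report": out_dir / "report.txt",
        "seeds": out_dir / "seeds.json",
    }
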