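"""Waveform container, WAV and annotation I/O, and call screening.

Screening applies the experiment's four call-exclusion criteria to decide
which calls enter the amplitude / f0 analyses:

1. not clipped (amplitude-run detection),
2. no temporal overlap with calls of another individual,
3. no extraneous background noise (an upstream judgement carried as a flag),
4. trackable by the pitch extractor (voiced fraction of frames >= 0.5).

Rate and duration analyses always use *all* calls; the clean subset only
gates amplitude and f0.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

CONDITIONS = ("no_playback", "low", "high")

__all__ = [
    "CONDITIONS",
    "Waveform",
    "CallAnnotation",
    "CallClip",
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "read_textgrid_annotations",
    "detect_clipping",
    "detect_overlap",
    "screen_calls",
    "ScreeningResult",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio on the full-scale digital amplitude axis."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires mono (1-D) samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def slice_seconds(self, onset_s: float, offset_s: float) -> "Waveform":
        """Half-open slice [onset_s, offset_s) in seconds from start."""
        i0 = int(round(onset_s * self.sample_rate))
        i1 = int(round(offset_s * self.sample_rate))
        return Waveform(self.samples[i0:i1], self.sample_rate)

    def rms_power(self) -> float:
        """Mean-square amplitude (power on the digital axis)."""
        return float(np.mean(np.square(self.samples)))


@dataclass(frozen=True)
class CallAnnotation:
    """One annotated call interval with identity labels and screening flags.

    Intervals are half-open ``[onset_s, offset_s)``, seconds from session
    start.  A call is *clean* iff all four exclusion flags are False.
    """

    session_id: str
    seal_id: str
    condition: str
    trial_index: int
    onset_s: float
    offset_s: float
    block_index: int = -1
    clipped: bool = False
    overlapped: bool = False
    extraneous_noise: bool = False
    untrackable: bool = False
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def is_clean(self) -> bool:
        return not (
            self.clipped
            or self.overlapped
            or self.extraneous_noise
            or self.untrackable
        )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class CallClip:
    """A call's audio interval paired with the matched noise-only interval."""

    annotation: CallAnnotation
    waveform: Waveform
    context_noise: Waveform

    def __post_init__(self) -> None:
        if len(self.waveform.samples) != len(self.context_noise.samples):
            raise ValueError("waveform and context_noise must have equal length")
        if self.waveform.sample_rate != self.context_noise.sample_rate:
            raise ValueError("waveform and context_noise sample rates differ")


# ---------------------------------------------------------------------------
# WAV I/O


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a mono WAV file onto the full-scale float axis.

    16-bit PCM is scaled by 1/32768 (amplitudes in [-1, 1)); float32/float64
    are taken verbatim.  Other encodings raise with the encoding named.
    """
    import warnings

    try:
        with warnings.catch_warnings():
            # a truncated file must be a parse error, not silent truncation
            warnings.simplefilter("error", wavfile.WavFileWarning)
            rate, data = wavfile.read(os.fspath(path))
    except (ValueError, wavfile.WavFileWarning) as exc:
        raise ValueError(f"cannot parse WAV file {path!r}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(
            f"unsupported WAV encoding {data.dtype!r} in {path!r}; "
            "use 16-bit PCM or float32"
        )
    return Waveform(samples, float(rate))


def write_wav(
    path: str | os.PathLike, w: Waveform, *, encoding: str = "float32"
) -> None:
    """Write a Waveform; float32 round-trips losslessly (up to float32)."""
    if encoding == "float32":
        wavfile.write(os.fspath(path), int(w.sample_rate), w.samples.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(w.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(
            os.fspath(path),
            int(w.sample_rate),
            np.round(clipped * 32768.0).astype(np.int16),
        )
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


# ---------------------------------------------------------------------------
# Annotation tables

_ANNOT_COLUMNS = [
    "session_id",
    "seal_id",
    "condition",
    "trial_index",
    "block_index",
    "onset_s",
    "offset_s",
    "clipped",
    "overlapped",
    "extraneous_noise",
    "untrackable",
]


def write_annotations(
    path: str | os.PathLike, annotations: Sequence[CallAnnotation]
) -> None:
    """Write a tab-separated annotation table (ground-truth columns kept
    under a ``true_`` prefix from each annotation's ``extra`` dict)."""
    rows = []
    for a in annotations:
        row = {c: getattr(a, c) for c in _ANNOT_COLUMNS}
        row.update({k: v for k, v in a.extra.items() if k.startswith("true_")})
        rows.append(row)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=_ANNOT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> list[CallAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        extra = {
            k: r[k] for k in df.columns if k.startswith("true_") and pd.notna(r[k])
        }
        out.append(
            CallAnnotation(
                session_id=str(r["session_id"]),
                seal_id=str(r["seal_id"]),
                condition=str(r["condition"]),
                trial_index=int(r["trial_index"]),
                block_index=int(r.get("block_index", -1)),
                onset_s=float(r["onset_s"]),
                offset_s=float(r["offset_s"]),
                clipped=bool(r["clipped"]),
                overlapped=bool(r["overlapped"]),
                extraneous_noise=bool(r["extraneous_noise"]),
                untrackable=bool(r["untrackable"]),
                extra=extra,
            )
        )
    return out


def read_textgrid_annotations(
    path: str | os.PathLike,
    session_id: str,
    condition_of: Callable[[float], str],
) -> list[CallAnnotation]:
    """Import call intervals from a Praat TextGrid (long text format).

    Each interval tier is one individual (tier name = seal_id); non-empty
    interval labels mark calls.  ``condition_of`` maps an interval's onset
    time to its noise condition (the session design provides this for real
    recordings).  Screening flags start out all-False.
    """
    with io.open(os.fspath(path), "r", encoding="utf-8") as fh:
        text = fh.read()
    tiers = re.split(r"item \[\d+\]:", text)[1:]
    annotations: list[CallAnnotation] = []
    for tier in tiers:
        m = re.search(r'name\s*=\s*"([^"]*)"', tier)
        cls = re.search(r'class\s*=\s*"([^"]*)"', tier)
        if not m or not cls or cls.group(1) != "IntervalTier":
            continue
        seal_id = m.group(1)
        trial = 0
        for iv in re.finditer(
            r"intervals \[\d+\]:\s*"
            r"xmin\s*=\s*([\d.eE+-]+)\s*"
            r"xmax\s*=\s*([\d.eE+-]+)\s*"
            r'text\s*=\s*"([^"]*)"',
            tier,
        ):
            xmin, xmax, label = float(iv.group(1)), float(iv.group(2)), iv.group(3)
            if not label.strip():
                continue
            annotations.append(
                CallAnnotation(
                    session_id=session_id,
                    seal_id=seal_id,
                    condition=condition_of(xmin),
                    trial_index=trial,
                    onset_s=xmin,
                    offset_s=xmax,
                )
            )
            trial += 1
    return annotations


# ---------------------------------------------------------------------------
# Screening


def detect_clipping(
    w: Waveform, threshold: float = 0.999, min_run: int = 3
) -> bool:
    """True iff >= `min_run` consecutive samples sit at or above `threshold`
    in magnitude (digital limiting leaves flat-topped runs; an isolated
    extreme sample does not count)."""
    at_rail = np.abs(w.samples) >= threshold
    if min_run <= 1:
        return bool(at_rail.any())
    run = 0
    for flag in at_rail:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def detect_overlap(a: CallAnnotation, others: Iterable[CallAnnotation]) -> bool:
    """True iff `a`'s half-open interval intersects any interval of a
    *different* individual in the same session."""
    for b in others:
        if b.session_id != a.session_id or b.seal_id == a.seal_id:
            continue
        if a.onset_s < b.offset_s and b.onset_s < a.offset_s:
            return True
    return False


@dataclass
class ScreeningResult:
    clean: list[CallClip]
    all_clips: list[CallClip]
    audit: pd.DataFrame
    exclusion_counts: dict


def screen_calls(
    clips: Sequence[CallClip],
    voiced_fraction_of: Callable[[Waveform], float] | None = None,
    *,
    clip_threshold: float = 0.999,
    clip_min_run: int = 3,
    min_voiced_fraction: float = 0.5,
) -> ScreeningResult:
    """Apply the four exclusion criteria and return the clean subset.

    Criteria 1 (clipping), 2 (overlap) and 4 (trackability, via
    ``voiced_fraction_of``, typically the pitch tracker's voiced-frame
    fraction) are evaluated here; criterion 3 (extraneous noise) is honoured
    from the annotation's ``extraneous_noise`` flag, which encodes an
    upstream judgement.  A call may fail several criteria; the audit table
    records every failure.  The clean subset gates only the amplitude / f0
    analyses — rate and duration analyses use all calls.
    """
    annots = [c.annotation for c in clips]
    out_clips: list[CallClip] = []
    rows = []
    counts = {
        "clipped": 0,
        "overlapped": 0,
        "extraneous_noise": 0,
        "untrackable": 0,
    }
    for clip in clips:
        a = clip.annotation
        clipped = a.clipped or detect_clipping(
            clip.waveform, clip_threshold, clip_min_run
        )
        overlapped = a.overlapped or detect_overlap(a, annots)
        extraneous = a.extraneous_noise
        if a.untrackable:
            untrackable = True
            vf = np.nan
        elif voiced_fraction_of is not None:
            vf = float(voiced_fraction_of(clip.waveform))
            untrackable = vf < min_voiced_fraction
        else:
            vf, untrackable = np.nan, False
        updated = replace(
            a,
            clipped=clipped,
            overlapped=overlapped,
            extraneous_noise=extraneous,
            untrackable=untrackable,
        )
        out_clips.append(replace(clip, annotation=updated))
        for crit, flag in (
            ("clipped", clipped),
            ("overlapped", overlapped),
            ("extraneous_noise", extraneous),
            ("untrackable", untrackable),
        ):
            counts[crit] += int(flag)
        rows.append(
            {
                "session_id": a.session_id,
                "seal_id": a.seal_id,
                "condition": a.condition,
                "trial_index": a.trial_index,
                "onset_s": a.onset_s,
                "clipped": clipped,
                "overlapped": overlapped,
                "extraneous_noise": extraneous,
                "untrackable": untrackable,
                "voiced_fraction": vf,
                "clean": updated.is_clean,
            }
        )
    audit = pd.DataFrame(rows)
    clean = [c for c in out_clips if c.annotation.is_clean]
    return ScreeningResult(
        clean=clean, all_clips=out_clips, audit=audit, exclusion_counts=counts
    )
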