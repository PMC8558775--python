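"""Digital SPL calibration.

All audio in this package lives on a full-scale digital amplitude axis
(|sample| <= 1).  Acoustic levels in dB SPL are mapped onto that axis by a
single declared convention: the sound pressure level assigned to a signal
whose RMS amplitude is exactly 1.0.  The default, 100 dB SPL at digital
full-scale RMS, leaves >= 20 dB of headroom above the loudest default call
level (75 dB SPL) so that synthesized sessions never clip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationConvention",
    "CalibrationOverflowError",
    "spl_to_rms",
    "rms_to_spl",
    "measure_spl",
]


class CalibrationOverflowError(ValueError):
    """Requested SPL exceeds the level assigned to digital full scale."""


@dataclass(frozen=True)
class CalibrationConvention:
    """Declares which dB SPL corresponds to digital RMS 1.0.

    Parameters
    ----------
    cal_db
        Sound pressure level, in dB SPL, of a signal with RMS amplitude 1.0
        on the digital axis.  Must be finite.
    """

    cal_db: float = 100.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.cal_db):
            raise ValueError(f"cal_db must be finite, got {self.cal_db!r}")


def spl_to_rms(level_db: float, cal: CalibrationConvention) -> float:
    """Linear RMS amplitude of a tone at `level_db` dB SPL.

    Raises
    ------
    CalibrationOverflowError
        If `level_db` exceeds ``cal.cal_db``: such a signal could not be
        represented without exceeding digital full scale.
    """
    if level_db > cal.cal_db:
        raise CalibrationOverflowError(
            f"level {level_db} dB SPL exceeds full-scale calibration "
            f"{cal.cal_db} dB SPL"
        )
    return 10.0 ** ((level_db - cal.cal_db) / 20.0)


def rms_to_spl(rms: float, cal: CalibrationConvention) -> float:
    """Inverse of :func:`spl_to_rms`; requires ``rms > 0``."""
    if rms <= 0:
        raise ValueError(f"rms must be positive, got {rms!r}")
    return cal.cal_db + 20.0 * math.log10(rms)


def measure_spl(samples: np.ndarray, cal: CalibrationConvention) -> float:
    """Measured SPL of a sample block: RMS mapped through the convention."""
    rms = float(np.sqrt(np.mean(np.square(np.asarray(samples, dtype=float)))))
    return rms_to_spl(rms, cal)
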