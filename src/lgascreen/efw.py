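"""Estimated fetal weight (EFW) from third-trimester ultrasound biometry.

EFW is computed with Hadlock "Formula C", the three-parameter regression on
biparietal diameter (BPD), abdominal circumference (AC) and femur length (FL):

    log10 EFW = 1.335 - 0.0034*AC*FL + 0.0316*BPD + 0.0457*AC + 0.1623*FL

with all measurements in centimeters and EFW in grams.  The formula is a pure
function of the three measurements; gestational age is carried alongside only
because the chart percentile lookup needs it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiometryRecord",
    "BiometryError",
    "HADLOCK_C_COEF",
    "hadlock_c_log10_efw",
    "estimate_fetal_weight_hadlock_c",
    "GA_SCAN_MIN_WEEKS",
    "GA_SCAN_MAX_WEEKS",
]

# Intercept and coefficients of Hadlock Formula C (cm in, grams out).
HADLOCK_C_COEF = {
    "intercept": 1.335,
    "ac_fl": -0.0034,
    "bpd": 0.0316,
    "ac": 0.0457,
    "fl": 0.1623,
}

# Study-conformant scan window: 28+0 to 36+6 weeks.
GA_SCAN_MIN_WEEKS = 28.0
GA_SCAN_MAX_WEEKS = 36.0 + 6.0 / 7.0

# Plausibility windows (cm); values outside trigger a warning, not an error.
_PLAUSIBLE = {"bpd_cm": (4.0, 12.0), "ac_cm": (15.0, 45.0), "fl_cm": (3.0, 9.0)}


class BiometryError(ValueError):
    """Invalid biometry input; the message names the offending field."""


def _check_measurement(name: str, value: float, strict: bool) -> None:
    if not math.isfinite(value):
        raise BiometryError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise BiometryError(f"{name} must be >= 0 (centimeters), got {value!r}")
    if strict and name == "ac_cm" and value > 60:
        raise BiometryError(
            f"ac_cm={value!r} looks like millimeters; Hadlock C expects centimeters"
        )
    lo, hi = _PLAUSIBLE[name]
    if value and not lo <= value <= hi:
        warnings.warn(
            f"{name}={value} cm outside plausible range [{lo}, {hi}]",
            stacklevel=3,
        )


@dataclass(frozen=True)
class BiometryRecord:
    """One ultrasound's biometry: GA at scan plus BPD/AC/FL in centimeters."""

    ga_weeks: float
    bpd_cm: float
    ac_cm: float
    fl_cm: float

    def validate(self, strict: bool = False) -> "BiometryRecord":
        for name in ("bpd_cm", "ac_cm", "fl_cm"):
            _check_measurement(name, getattr(self, name), strict)
        if not math.isfinite(self.ga_weeks) or self.ga_weeks < 0:
            raise BiometryError(f"ga_weeks must be finite and >= 0, got {self.ga_weeks!r}")
        return self

    @property
    def in_study_window(self) -> bool:
        return GA_SCAN_MIN_WEEKS <= self.ga_weeks <= GA_SCAN_MAX_WEEKS + 1e-9


def hadlock_c_log10_efw(bpd_cm, ac_cm, fl_cm):
    """log10 of the Hadlock-C EFW (grams); accepts scalars or arrays."""
    bpd = np.asarray(bpd_cm, dtype=float)
    ac = np.asarray(ac_cm, dtype=float)
    fl = np.asarray(fl_cm, dtype=float)
    c = HADLOCK_C_COEF
    return (
        c["intercept"]
        + c["ac_fl"] * ac * fl
        + c["bpd"] * bpd
        + c["ac"] * ac
        + c["fl"] * fl
    )


def estimate_fetal_weight_hadlock_c(
    biometry: BiometryRecord, *, strict: bool = False
) -> float:
    """Hadlock Formula C estimated fetal weight in grams.

    Parameters
    ----------
    biometry
        Measurements in centimeters; validated (non-negative, finite) before
        evaluation.  Implausible values warn; ``strict=True`` additionally
        rejects AC values that look like millimeters (> 60 cm).
    """
    biometry.validate(strict=strict)
    return float(
        10.0 ** hadlock_c_log10_efw(biometry.bpd_cm, biometry.ac_cm, biometry.fl_cm)
    )
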