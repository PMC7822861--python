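"""Fluorescence anisotropy formulas and the bound-fraction calibration.

Steady-state anisotropy r reports the rotational mobility of a fluorophore:
a small labeled nucleotide tumbling freely has low r, and r rises when the
nucleotide is immobilized on a large protein such as G-actin.  With the two
extreme values calibrated — r_MIN for the fully free label and r_MAX for the
fully bound label — intermediate r values map linearly onto the bound
fraction of the labeled species, and from there onto concentrations.

The linear scale is exact only when the label's quantum yield and lifetime
are independent of binding state (its total fluorescence does not change on
binding); that assumption is recorded in output metadata rather than tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CalibrationError, ValidationError
from .kinetics import TimeCourse

__all__ = [
    "PolarizedIntensities",
    "AnisotropyCalibration",
    "grating_factor",
    "anisotropy_from_intensities",
    "bound_fraction",
    "r_from_bound_fraction",
    "concentrations_from_timecourse",
    "CONSTANT_INTENSITY_NOTE",
]

#: Assumption carried into every converted dataset's metadata.
CONSTANT_INTENSITY_NOTE = (
    "linear r-to-bound-fraction scale assumes label total fluorescence is "
    "occupancy-independent"
)


@dataclass(frozen=True)
class PolarizedIntensities:
    """Intensities at the four polarizer/analyzer positions (arbitrary units).

    The first letter is the excitation polarizer position, the second the
    emission analyzer position (V vertical, H horizontal).
    """

    I_VV: float
    I_VH: float
    I_HV: float
    I_HH: float

    def __post_init__(self) -> None:
        for name in ("I_VV", "I_VH", "I_HV", "I_HH"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"intensity {name}={v!r} must be finite and >= 0")


@dataclass(frozen=True)
class AnisotropyCalibration:
    """r_MIN / r_MAX pair mapping anisotropy to bound fraction.

    r_MIN is the anisotropy of the fully free labeled nucleotide; r_MAX of
    the fully protein-bound one.  ``provenance`` optionally records how r_MAX
    was measured (``F-actin-pelleting`` or ``Dowex``).
    """

    r_min: float
    r_max: float
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_min < self.r_max <= 0.4):
            raise CalibrationError(
                f"require 0 <= r_min < r_max <= 0.4 (one-photon limit); "
                f"got r_min={self.r_min}, r_max={self.r_max}"
            )

    @property
    def dynamic_range(self) -> float:
        return self.r_max - self.r_min


def grating_factor(I: PolarizedIntensities) -> float:
    """Instrument grating factor G = I_HV / I_HH."""
    if I.I_HH == 0:
        raise ValidationError(
            "invalid calibration measurement: I_HH = 0, grating factor undefined"
        )
    return I.I_HV / I.I_HH


def anisotropy_from_intensities(I: PolarizedIntensities, G: float) -> float:
    """Anisotropy r = (I_VV − G·I_VH) / (I_VV + 2·G·I_VH).

    For nonnegative intensities with a positive denominator, r lies in
    (−0.5, 1].
    """
    denom = I.I_VV + 2.0 * G * I.I_VH
    if denom <= 0:
        raise ValidationError(
            "invalid measurement: total-intensity denominator I_VV + 2·G·I_VH <= 0"
        )
    return (I.I_VV - G * I.I_VH) / denom


def bound_fraction(r, cal: AnisotropyCalibration):
    """Linear bound fraction (r − r_MIN)/(r_MAX − r_MIN), clipped to [0, 1].

    Accepts a scalar or array.  Values outside the calibration window (noise
    pushing r below r_MIN or above r_MAX) are clipped and a warning reports
    how many samples were affected, surfacing possible calibration drift
    while preserving downstream mass constraints.
    """
    if cal.dynamic_range == 0:  # unreachable given the type invariant
        raise CalibrationError("degenerate calibration: r_max equals r_min")
    r_arr = np.asarray(r, dtype=float)
    frac = (r_arr - cal.r_min) / cal.dynamic_range
    n_out = int(np.count_nonzero((frac < 0) | (frac > 1)))
    if n_out:
        warnings.warn(
            f"{n_out} anisotropy value(s) outside [r_min, r_max] clipped to [0, 1]",
            stacklevel=2,
        )
        frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if np.isscalar(r) else frac


def r_from_bound_fraction(fraction, cal: AnisotropyCalibration):
    """Inverse map: r = r_MIN + fraction·(r_MAX − r_MIN), fraction in [0, 1]."""
    frac = np.asarray(fraction, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValidationError("bound fraction must lie in [0, 1]")
    r = cal.r_min + frac * cal.dynamic_range
    return float(r) if np.isscalar(fraction) else r


def concentrations_from_timecourse(
    tc: TimeCourse, cal: AnisotropyCalibration, S_total: float
) -> TimeCourse:
    """Convert an anisotropy time course to bound-analog concentration (µM).

    Per-sample bound = bound_fraction(r) · S_total; the free concentration is
    S_total − bound and is recoverable from the metadata.
    """
    if tc.kind != "anisotropy":
        raise ValidationError(
            f"expected an anisotropy TimeCourse, got kind={tc.kind!r}"
        )
    if not S_total > 0:
        raise ValidationError(f"S_total={S_total!r} must be > 0")
    bound = bound_fraction(tc.values, cal) * S_total
    meta = dict(tc.meta)
    meta.update(
        {
            "S_total_uM": S_total,
            "r_MIN": cal.r_min,
            "r_MAX": cal.r_max,
            "assumption": CONSTANT_INTENSITY_NOTE,
        }
    )
    return TimeCourse(
        tc.times, bound, kind="bound_concentration", condition=tc.condition, meta=meta
    )
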