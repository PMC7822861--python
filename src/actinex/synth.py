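"""Seeded synthetic datasets with the statistical structure of each assay.

Generates association bundles (fixed G-actin, a ladder of labeled-analog
concentrations, 10-s sampling), ATP-chase dissociation traces, equilibrium
titrations of a labeled actin-binding protein, and synthetic polarized
intensities, so every fitting stage in the package is testable without any
measured data.  Noise is additive Gaussian on the anisotropy reading; the
default sd of 0.002 is twice the ±0.001 precision typical of plateau means
on a bench spectrofluorimeter and is configurable.

Default experiment geometry: 2 µM G-actin, labeled analog at 25–200 nM,
1800 s duration sampled every 10 s; chase with 100 µM unlabeled ATP after
1800 s of association.  Under the fully-ATP-loaded convention the total ATP
is three times the actin (1:1 bound plus a two-fold free excess).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .anisotropy import (
    AnisotropyCalibration,
    PolarizedIntensities,
    r_from_bound_fraction,
)
from .errors import ValidationError
from .fitting import TitrationDataset, TitrationParams, titration_model_eval
from .kinetics import (
    ExchangeExperiment,
    RateConstants,
    ScenarioModifiers,
    TimeCourse,
    simulate_exchange,
)

__all__ = [
    "NoiseModel",
    "NOISELESS",
    "ScenarioPreset",
    "SCENARIO_PRESETS",
    "ATTO488_CAL",
    "CY5_CAL",
    "generate_association_bundle",
    "generate_chase",
    "generate_titration",
    "generate_polarized_intensities",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the anisotropy reading.

    ``sd`` is in anisotropy units; a seed is mandatory whenever sd > 0 so
    every generated dataset is reproducible bit-for-bit.
    """

    sd: float = 0.002
    seed: Optional[int] = None
    kind: str = "gaussian_additive_on_r"

    def __post_init__(self) -> None:
        if self.kind != "gaussian_additive_on_r":
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValidationError(f"noise sd={self.sd!r} must be >= 0")
        if self.sd > 0 and self.seed is None:
            raise ValidationError("a seed is required whenever noise sd > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Noiseless shorthand used throughout the tests.
NOISELESS = NoiseModel(sd=0.0, seed=None)


@dataclass(frozen=True)
class ScenarioPreset:
    """Named buffer/cation/ABP condition with its net exchange fold-change."""

    name: str
    exchange_multiplier: float
    description: str

    def modifiers(self) -> ScenarioModifiers:
        return ScenarioModifiers(
            exchange_multiplier=self.exchange_multiplier, label=self.name
        )


SCENARIO_PRESETS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in (
        ScenarioPreset("Mg_baseline", 1.0, "Mg2+-bound G-actin, no KCl"),
        ScenarioPreset("Ca", 0.2, "Ca2+-bound G-actin: exchange 5x slower"),
        ScenarioPreset("Mg_KCl", 2.0, "Mg2+ plus 50 mM KCl: exchange 2x faster"),
        ScenarioPreset(
            "profilin_saturating", 3.5, "saturating profilin: exchange 3-4x faster"
        ),
        ScenarioPreset(
            "cofilin_inhibited", 0.3, "ADF/cofilin-bound monomers: exchange inhibited"
        ),
    )
}

#: Default calibration for the green-dye-labeled ATP analog (short-lifetime
#: dye, plausible free/bound plateaus).
ATTO488_CAL = AnisotropyCalibration(r_min=0.05, r_max=0.22, provenance="synthetic")

#: Calibration printed for the red-dye-labeled ATP analog (free/bound).
CY5_CAL = AnisotropyCalibration(
    r_min=0.242, r_max=0.295, provenance="F-actin-pelleting"
)


def _observe(
    tc: TimeCourse,
    S_total: float,
    cal: AnisotropyCalibration,
    noise: NoiseModel,
    rng: Optional[np.random.Generator],
) -> TimeCourse:
    """Map a state trajectory to a (possibly noisy) anisotropy trace."""
    frac = tc.observable("AS") / S_total if S_total > 0 else np.zeros_like(tc.times)
    frac = np.clip(frac, 0.0, 1.0)
    r = r_from_bound_fraction(frac, cal)
    if noise.sd > 0:
        r = r + rng.normal(0.0, noise.sd, size=r.shape)
    meta = dict(tc.meta)
    meta.update(
        {
            "S_total_uM": S_total,
            "r_MIN": cal.r_min,
            "r_MAX": cal.r_max,
            "noise_sd": noise.sd,
            "noise_seed": noise.seed if noise.seed is not None else "",
        }
    )
    return TimeCourse(
        tc.times, np.asarray(r), kind="anisotropy", condition=tc.condition, meta=meta
    )


def generate_association_bundle(
    rates: RateConstants,
    A_total: float = 2.0,
    S_totals: Sequence[float] = (0.025, 0.05, 0.1, 0.2),
    noise: NoiseModel = NOISELESS,
    cal: AnisotropyCalibration = ATTO488_CAL,
    duration: float = 1800.0,
    dt: float = 10.0,
    scenario: Optional[ScenarioModifiers] = None,
    T_total: Optional[float] = None,
) -> list[TimeCourse]:
    """Association traces at one G-actin concentration and a ladder of
    labeled-analog concentrations.

    Each trace is simulate → bound fraction → anisotropy via ``cal`` → noise.
    ``T_total`` defaults to 3×``A_total`` (fully loaded plus two-fold free
    excess).  Metadata records everything needed to refit.
    """
    scenario = scenario or ScenarioModifiers()
    T_tot = 3.0 * A_total if T_total is None else T_total
    rng = noise.rng() if noise.sd > 0 else None
    traces = []
    for S_tot in S_totals:
        exp = ExchangeExperiment(
            A_total=A_total,
            T_total=T_tot,
            S_total=S_tot,
            duration=duration,
            dt=dt,
            scenario=scenario,
        )
        traces.append(_observe(simulate_exchange(exp, rates), S_tot, cal, noise, rng))
    return traces


def generate_chase(
    rates: RateConstants,
    A_total: float = 2.0,
    S_total: float = 0.2,
    chase_T_add: float = 100.0,
    chase_time: float = 1800.0,
    noise: NoiseModel = NOISELESS,
    cal: AnisotropyCalibration = ATTO488_CAL,
    duration: float = 5400.0,
    dt: float = 10.0,
    scenario: Optional[ScenarioModifiers] = None,
    T_total: Optional[float] = None,
) -> TimeCourse:
    """Association followed by an instantaneous excess-ATP chase.

    The trace first relaxes toward the exchange steady state, then free
    unlabeled ATP steps up by ``chase_T_add`` at ``chase_time``, making
    labeled-analog dissociation effectively irreversible; the terminal decay
    rate approaches the analog's off-rate.
    """
    if not chase_time < duration:
        raise ValidationError("chase_time must be < duration")
    scenario = scenario or ScenarioModifiers()
    T_tot = 3.0 * A_total if T_total is None else T_total
    exp = ExchangeExperiment(
        A_total=A_total,
        T_total=T_tot,
        S_total=S_total,
        duration=duration,
        dt=dt,
        chase=(chase_time, chase_T_add),
        scenario=scenario,
    )
    rng = noise.rng() if noise.sd > 0 else None
    return _observe(simulate_exchange(exp, rates), S_total, cal, noise, rng)


def generate_titration(
    params: TitrationParams,
    ABP_total: float,
    G_grid: Sequence[float],
    noise: NoiseModel = NOISELESS,
) -> TitrationDataset:
    """Equilibrium titration of a labeled ABP against G-actin from the
    quadratic isotherm, plus optional Gaussian noise on r."""
    G = np.asarray(list(G_grid), dtype=float)
    r = np.asarray(titration_model_eval(params, G, ABP_total), dtype=float)
    if noise.sd > 0:
        r = r + noise.rng().normal(0.0, noise.sd, size=r.shape)
    return TitrationDataset(
        ABP_total=ABP_total,
        G_totals=G,
        r_observed=r,
        meta={
            "Kd_uM": params.Kd,
            "r_min": params.r_min,
            "r_max": params.r_max,
            "abp_total_uM": ABP_total,
            "noise_sd": noise.sd,
            "noise_seed": noise.seed if noise.seed is not None else "",
        },
    )


def generate_polarized_intensities(
    r_target: float, total_intensity: float = 4.0, G: float = 1.0
) -> PolarizedIntensities:
    """Synthesize four polarized intensities realizing a target anisotropy.

    Inverts the anisotropy formula with the convention that
    ``total = I_VV + 2·G·I_VH``; the horizontal-excitation pair is chosen so
    the measured grating factor reproduces ``G``.  One valid solution among
    many — intensities are only defined up to an overall scale.
    """
    if not (-0.5 < r_target <= 1.0):
        raise ValidationError(f"r_target={r_target!r} outside (-0.5, 1]")
    if not total_intensity > 0:
        raise ValidationError("total_intensity must be > 0")
    if not G > 0:
        raise ValidationError("grating factor G must be > 0")
    I_VV = total_intensity * (1.0 + 2.0 * r_target) / 3.0
    I_VH = total_intensity * (1.0 - r_target) / (3.0 * G)
    I_HH = total_intensity / 4.0
    I_HV = G * I_HH
    return PolarizedIntensities(I_VV=I_VV, I_VH=I_VH, I_HV=I_HV, I_HH=I_HH)
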