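"""Competitive nucleotide exchange on G-actin by deterministic mass action.

The reaction scheme is two reversible bimolecular bindings competing for the
same site on monomeric (G-) actin::

    A + T  <=>  AT        (unlabeled ATP)
    A + S  <=>  AS        (fluorescent ATP analog, "ATP*")

with five species: free nucleotide-free actin ``A``, the two complexes ``AT``
and ``AS``, and the two free nucleotides ``T`` and ``S``.  Units are fixed
package-wide: concentrations in µM, time in seconds, association rates in
µM⁻¹ s⁻¹ and dissociation rates in s⁻¹.

Simulation integrates the reduced system (AT, AS) and reconstructs the other
three species from the conservation laws, so total actin and both nucleotide
totals are conserved to machine precision at every sample.  An independent
analytic equilibrium solver (:func:`competitive_equilibrium`) provides the
long-time limit without touching the ODE path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import EquilibriumError, IntegrationError, ValidationError

__all__ = [
    "RateConstants",
    "MixtureState",
    "ScenarioModifiers",
    "ExchangeExperiment",
    "TimeCourse",
    "REFERENCE_RATES",
    "mass_action_rhs",
    "simulate_exchange",
    "competitive_equilibrium",
    "apply_scenario",
    "STATE_COLUMNS",
]

STATE_COLUMNS = ("A", "AT", "AS", "T", "S")

#: Relative / absolute integration tolerances (µM).  Validated by the
#: tolerance-halving contract in the test suite.
_RTOL = 1e-10
_ATOL = 1e-13


@dataclass(frozen=True)
class RateConstants:
    """The four mass-action rate constants of the competitive scheme.

    Attributes
    ----------
    k_on_T : float
        Association rate of unlabeled ATP (µM⁻¹ s⁻¹).
    k_on_S : float
        Association rate of the labeled analog (µM⁻¹ s⁻¹).
    k_off_T : float
        Dissociation rate of unlabeled ATP (s⁻¹).
    k_off_S : float
        Dissociation rate of the labeled analog (s⁻¹).
    """

    k_on_T: float
    k_on_S: float
    k_off_T: float
    k_off_S: float

    def __post_init__(self) -> None:
        for name in ("k_on_T", "k_on_S", "k_off_T", "k_off_S"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"rate constant {name}={v!r} must be strictly positive and finite"
                )

    @property
    def Kd_T(self) -> float:
        """Dissociation constant of unlabeled ATP (µM)."""
        return self.k_off_T / self.k_on_T

    @property
    def Kd_S(self) -> float:
        """Dissociation constant of the labeled analog (µM)."""
        return self.k_off_S / self.k_on_S


#: Reference rate set for ATP vs dye-labeled ATP exchange on Mg²⁺-G-actin,
#: in (k_on_T, k_on_S, k_off_T, k_off_S) order.
REFERENCE_RATES = RateConstants(k_on_T=10.0, k_on_S=12.0, k_off_T=2.8e-3, k_off_S=1e-3)


@dataclass(frozen=True)
class MixtureState:
    """Concentrations (µM) of the five species at one instant."""

    A: float
    AT: float
    AS: float
    T: float
    S: float

    def __post_init__(self) -> None:
        for name in ("A", "AT", "AS", "T", "S"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"concentration {name}={v!r} must be finite and >= 0"
                )

    @property
    def A_total(self) -> float:
        return self.A + self.AT + self.AS

    @property
    def T_total(self) -> float:
        return self.T + self.AT

    @property
    def S_total(self) -> float:
        return self.S + self.AS

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.AT, self.AS, self.T, self.S])


@dataclass(frozen=True)
class ScenarioModifiers:
    """Net fold-change of exchange speed for a buffer/cation/ABP condition.

    The multiplier acts on both dissociation rates only: exchange from
    fully-loaded actin is dissociation-limited, so a reported n-fold change
    of exchange speed is modeled as an n-fold change of both off-rates while
    the association rates stay at their baseline values.
    """

    exchange_multiplier: float = 1.0
    label: str = "Mg_baseline"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.exchange_multiplier) and self.exchange_multiplier > 0):
            raise ValidationError(
                f"exchange_multiplier={self.exchange_multiplier!r} must be > 0"
            )


@dataclass(frozen=True)
class ExchangeExperiment:
    """Geometry of one exchange experiment.

    Under the default fully-ATP-loaded convention the initial state is
    AT(0) = A_total, A(0) = 0, AS(0) = 0, T(0) = T_total − A_total,
    S(0) = S_total; actin is purified ATP-bound and dilution controls the
    *free* ATP, so a two-fold free excess means ``T_total = 3 * A_total``.

    Parameters
    ----------
    chase : optional (time_s, added_T_uM)
        Instantaneous addition of free unlabeled ATP at the given time
        (a chase makes labeled-analog dissociation effectively irreversible).
    """

    A_total: float
    T_total: float
    S_total: float
    duration: float
    dt: float
    initial_state: Optional[MixtureState] = None
    chase: Optional[tuple[float, float]] = None
    scenario: ScenarioModifiers = field(default_factory=ScenarioModifiers)

    def __post_init__(self) -> None:
        for name in ("A_total", "T_total", "S_total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name}={v!r} must be finite and >= 0")
        if not self.duration > 0:
            raise ValidationError(f"duration={self.duration!r} must be > 0")
        if not self.dt > 0:
            raise ValidationError(f"sampling interval dt={self.dt!r} must be > 0")
        if self.chase is not None:
            t_c, added = self.chase
            if not (0 < t_c < self.duration):
                raise ValidationError(
                    f"chase time {t_c!r} must lie strictly inside (0, {self.duration})"
                )
            if added < 0:
                raise ValidationError(f"chase ATP addition {added!r} must be >= 0")
        if self.initial_state is None and self.T_total < self.A_total:
            raise ValidationError(
                "fully-ATP-loaded convention requires T_total >= A_total "
                f"(got T_total={self.T_total}, A_total={self.A_total})"
            )
        if self.initial_state is not None:
            s0 = self.initial_state
            for got, want, name in (
                (s0.A_total, self.A_total, "A_total"),
                (s0.T_total, self.T_total, "T_total"),
                (s0.S_total, self.S_total, "S_total"),
            ):
                if abs(got - want) > 1e-9 * max(want, 1.0):
                    raise ValidationError(
                        f"initial_state {name}={got} inconsistent with declared {want}"
                    )

    def initial(self) -> MixtureState:
        """Initial mixture per the loading convention."""
        if self.initial_state is not None:
            return self.initial_state
        return MixtureState(
            A=0.0,
            AT=self.A_total,
            AS=0.0,
            T=self.T_total - self.A_total,
            S=self.S_total,
        )


@dataclass
class TimeCourse:
    """Sampled trajectory of one experiment.

    ``kind`` is one of ``state`` (values shaped (n, 5) in
    :data:`STATE_COLUMNS` order), ``anisotropy`` or ``bound_concentration``
    (values shaped (n,)).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    condition: Optional[ExchangeExperiment] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("times must be a non-empty 1-D sequence")
        if self.times[0] != 0.0:
            raise ValidationError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.kind not in ("state", "anisotropy", "bound_concentration"):
            raise ValidationError(f"unknown TimeCourse kind {self.kind!r}")
        if self.kind == "state":
            if self.values.ndim != 2 or self.values.shape != (self.times.size, 5):
                raise ValidationError(
                    "state TimeCourse requires values shaped (n_times, 5)"
                )
        else:
            if self.values.shape != self.times.shape:
                raise ValidationError("values must have one entry per time point")

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "state":
            df = pd.DataFrame(self.values, columns=list(STATE_COLUMNS))
        else:
            df = pd.DataFrame({self.kind: self.values})
        df.insert(0, "time_s", self.times)
        return df

    def observable(self, name: str) -> np.ndarray:
        """Column of a state trajectory by species name."""
        if self.kind != "state":
            raise ValidationError("observable() requires a state TimeCourse")
        return self.values[:, STATE_COLUMNS.index(name)]


def mass_action_rhs(state: MixtureState, rates: RateConstants) -> dict[str, float]:
    """Per-species time derivatives (µM/s) of the competitive scheme.

    dAT/dt = k_on_T·A·T − k_off_T·AT, dAS/dt = k_on_S·A·S − k_off_S·AS,
    and the remaining three derivatives follow from conservation, so the
    actin-species derivatives sum to zero exactly.
    """
    dAT = rates.k_on_T * state.A * state.T - rates.k_off_T * state.AT
    dAS = rates.k_on_S * state.A * state.S - rates.k_off_S * state.AS
    return {"A": -(dAT + dAS), "AT": dAT, "AS": dAS, "T": -dAT, "S": -dAS}


def _reduced_rhs(t, y, k_on_T, k_on_S, k_off_T, k_off_S, A_tot, T_tot, S_tot):
    AT, AS = y
    A = A_tot - AT - AS
    T = T_tot - AT
    S = S_tot - AS
    return (
        k_on_T * A * T - k_off_T * AT,
        k_on_S * A * S - k_off_S * AS,
    )


def _integrate_segment(y0, t_span, t_eval, rates, A_tot, T_tot, S_tot, label):
    sol = solve_ivp(
        _reduced_rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval if len(t_eval) else None,
        rtol=_RTOL,
        atol=_ATOL,
        args=(
            rates.k_on_T,
            rates.k_on_S,
            rates.k_off_T,
            rates.k_off_S,
            A_tot,
            T_tot,
            S_tot,
        ),
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for condition {label!r}: {sol.message}"
        )
    return sol


def simulate_exchange(
    experiment: ExchangeExperiment, rates: RateConstants
) -> TimeCourse:
    """Simulate one exchange experiment; returns a ``state`` TimeCourse.

    The scenario multiplier is applied to the rates before integration.  A
    chase, if present, is an instantaneous step increase of free unlabeled
    ATP; the sample at the exact chase time reports the pre-addition state.
    """
    eff = apply_scenario(rates, experiment.scenario)
    s0 = experiment.initial()
    times = np.arange(0.0, experiment.duration + experiment.dt * 0.5, experiment.dt)
    label = experiment.scenario.label

    A_tot, T_tot, S_tot = (
        experiment.A_total,
        experiment.T_total,
        experiment.S_total,
    )
    y0 = (s0.AT, s0.AS)

    if experiment.chase is None:
        sol = _integrate_segment(
            y0, (0.0, times[-1]), times, eff, A_tot, T_tot, S_tot, label
        )
        AT, AS = sol.y
        T_tot_arr = np.full_like(times, T_tot)
    else:
        t_c, added = experiment.chase
        pre_mask = times <= t_c
        sol1 = _integrate_segment(
            y0, (0.0, t_c), times[pre_mask], eff, A_tot, T_tot, S_tot, label
        )
        y_at_chase = sol1.sol(t_c)
        T_tot2 = T_tot + added
        post_times = times[~pre_mask]
        if post_times.size:
            sol2 = _integrate_segment(
                tuple(y_at_chase),
                (t_c, times[-1]),
                post_times,
                eff,
                A_tot,
                T_tot2,
                S_tot,
                label,
            )
            AT = np.concatenate([sol1.y[0], sol2.y[0]])
            AS = np.concatenate([sol1.y[1], sol2.y[1]])
        else:
            AT, AS = sol1.y
        T_tot_arr = np.where(times <= t_c, T_tot, T_tot2)

    AT = np.clip(AT, 0.0, None)
    AS = np.clip(AS, 0.0, None)
    A = A_tot - AT - AS
    T = T_tot_arr - AT
    S = S_tot - AS
    values = np.column_stack([A, AT, AS, T, S])
    meta = {
        "A_total_uM": A_tot,
        "T_total_uM": T_tot,
        "S_total_uM": S_tot,
        "scenario": label,
        "exchange_multiplier": experiment.scenario.exchange_multiplier,
        "k_on_T": rates.k_on_T,
        "k_on_S": rates.k_on_S,
        "k_off_T": rates.k_off_T,
        "k_off_S": rates.k_off_S,
    }
    if experiment.chase is not None:
        meta["chase_time_s"] = experiment.chase[0]
        meta["chase_T_add_uM"] = experiment.chase[1]
    return TimeCourse(times, values, kind="state", condition=experiment, meta=meta)


def competitive_equilibrium(
    A_total: float, T_total: float, S_total: float, rates: RateConstants
) -> MixtureState:
    """Analytic long-time limit of the competitive scheme.

    Solved by bracketed root-finding on free actin ``a`` using the binding
    polynomial: ``a (1 + T_tot/(a+Kd_T) + S_tot/(a+Kd_S)) = A_tot`` after the
    substitutions ``AT = a·T_tot/(a+Kd_T)``, ``AS = a·S_tot/(a+Kd_S)``.
    Independent of the ODE integration path, so it serves as an oracle for
    :func:`simulate_exchange`.
    """
    for name, v in (("A_total", A_total), ("T_total", T_total), ("S_total", S_total)):
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{name}={v!r} must be finite and >= 0")
    if A_total == 0.0:
        return MixtureState(A=0.0, AT=0.0, AS=0.0, T=T_total, S=S_total)
    Kd_T, Kd_S = rates.Kd_T, rates.Kd_S

    def residual(a: float) -> float:
        return (
            a
            + T_total * a / (a + Kd_T)
            + S_total * a / (a + Kd_S)
            - A_total
        )

    lo, hi = 0.0, A_total
    if residual(hi) < 0:  # cannot happen: bound species are <= totals
        raise EquilibriumError("no physical root bracketing free actin")
    a = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    # Newton polish to push the derivative residual to machine precision.
    for _ in range(3):
        f = residual(a)
        df = (
            1.0
            + T_total * Kd_T / (a + Kd_T) ** 2
            + S_total * Kd_S / (a + Kd_S) ** 2
        )
        step = f / df
        if a - step < 0:
            break
        a -= step
    AT = a * T_total / (a + Kd_T)
    AS = a * S_total / (a + Kd_S)
    return MixtureState(
        A=max(a, 0.0),
        AT=AT,
        AS=AS,
        T=T_total - AT,
        S=S_total - AS,
    )


def apply_scenario(rates: RateConstants, mod: ScenarioModifiers) -> RateConstants:
    """Scale both dissociation rates by the scenario multiplier.

    Association rates are deliberately unchanged: with actin fully loaded,
    the exchange flux is limited by nucleotide release, so net fold-changes
    of exchange speed map onto the off-rates.
    """
    m = mod.exchange_multiplier
    if m == 1.0:
        return rates
    return replace(rates, k_off_T=rates.k_off_T * m, k_off_S=rates.k_off_S * m)
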