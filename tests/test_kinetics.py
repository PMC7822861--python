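"""Mass-action scheme, simulation, equilibrium oracle, and scenarios."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import actinex.kinetics as kin
from actinex import (
    ExchangeExperiment,
    MixtureState,
    RateConstants,
    ScenarioModifiers,
    apply_scenario,
    competitive_equilibrium,
    mass_action_rhs,
    simulate_exchange,
)
from actinex.errors import ValidationError


class TestRateConstants:
    def test_derived_kds(self, rates):
        assert rates.Kd_T == pytest.approx(2.8e-4)
        assert rates.Kd_S == pytest.approx(1e-3 / 12.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValidationError):
            RateConstants(k_on_T=bad, k_on_S=12, k_off_T=2.8e-3, k_off_S=1e-3)


class TestMassActionRhs:
    def test_hand_evaluated_fluxes(self):
        state = MixtureState(A=1, AT=0, AS=0, T=1, S=1)
        rates = RateConstants(10, 12, 2.8e-3, 1e-3)
        d = mass_action_rhs(state, rates)
        assert d["AT"] == pytest.approx(10.0)
        assert d["AS"] == pytest.approx(12.0)
        assert d["A"] == pytest.approx(-22.0)
        assert d["T"] == pytest.approx(-10.0)
        assert d["S"] == pytest.approx(-12.0)

    def test_actin_species_derivatives_sum_to_machine_zero(self, rates):
        state = MixtureState(A=0.3, AT=1.2, AS=0.5, T=3.1, S=0.07)
        d = mass_action_rhs(state, rates)
        scale = abs(d["AT"]) + abs(d["AS"])
        assert abs(d["A"] + d["AT"] + d["AS"]) <= 4e-16 * scale

    def test_zero_at_analytic_equilibrium(self, rates):
        eq = competitive_equilibrium(2.0, 6.0, 0.2, rates)
        d = mass_action_rhs(eq, rates)
        assert max(abs(v) for v in d.values()) < 1e-12

    def test_absent_species_stays_absent(self, rates):
        state = MixtureState(A=1.0, AT=0.5, AS=0.0, T=2.0, S=0.0)
        d = mass_action_rhs(state, rates)
        assert d["AS"] == 0.0 and d["S"] == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            MixtureState(A=-0.1, AT=0, AS=0, T=1, S=1)


class TestCompetitiveEquilibrium:
    def test_single_ligand_matches_quadratic(self, rates):
        """With no labeled analog the problem reduces to the one-ligand
        quadratic, solved explicitly here as the oracle."""
        A_tot, T_tot, Kd = 2.0, 6.0, rates.Kd_T
        # AT^2 - (A_tot + T_tot + Kd) AT + A_tot T_tot = 0, physical root
        b = A_tot + T_tot + Kd
        AT_oracle = (b - np.sqrt(b * b - 4 * A_tot * T_tot)) / 2.0
        eq = competitive_equilibrium(A_tot, T_tot, 0.0, rates)
        assert eq.AT == pytest.approx(AT_oracle, rel=1e-12)
        assert eq.AS == 0.0
        assert eq.AT == pytest.approx(2.0, abs=5e-4)  # fully bound to Kd scale

    def test_two_ligand_fraction_against_fsolve(self, rates):
        """Independent 2-D root of the coupled conservation equations."""

        def eqs(x):
            AT, AS = x
            A = 5.0 - AT - AS
            return (
                rates.k_on_T * A * (15.0 - AT) - rates.k_off_T * AT,
                rates.k_on_S * A * (5.0 - AS) - rates.k_off_S * AS,
            )

        AT0, AS0 = fsolve(eqs, [2.5, 2.5], xtol=1e-13)
        eq = competitive_equilibrium(5.0, 15.0, 5.0, rates)
        assert eq.AT == pytest.approx(AT0, rel=1e-9)
        assert eq.AS == pytest.approx(AS0, rel=1e-9)
        assert eq.AS / 5.0 == pytest.approx(0.44, abs=0.01)

    def test_symmetric_ligands(self):
        rates = RateConstants(10, 10, 1e-3, 1e-3)
        eq = competitive_equilibrium(2.0, 3.0, 3.0, rates)
        assert eq.AT == pytest.approx(eq.AS, rel=1e-12)

    def test_all_zero_totals(self, rates):
        eq = competitive_equilibrium(0.0, 0.0, 0.0, rates)
        assert eq.as_array().tolist() == [0.0] * 5

    def test_negative_total_rejected(self, rates):
        with pytest.raises(ValidationError):
            competitive_equilibrium(-1.0, 0.0, 0.0, rates)


class TestSimulateExchange:
    def test_no_label_stays_unlabeled(self, rates):
        exp = ExchangeExperiment(
            A_total=2, T_total=6, S_total=0, duration=1000, dt=50
        )
        tc = simulate_exchange(exp, rates)
        assert np.all(tc.observable("AS") == 0.0)

    def test_long_time_limit_matches_equilibrium_oracle(self, rates):
        exp = ExchangeExperiment(
            A_total=2, T_total=6, S_total=0.2, duration=2e4, dt=500
        )
        tc = simulate_exchange(exp, rates)
        eq = competitive_equilibrium(2, 6, 0.2, rates).as_array()
        assert np.max(np.abs(tc.values[-1] - eq)) < 1e-4

    def test_conservation_on_random_conditions(self):
        """Total actin and both nucleotide totals conserved at every sample
        to relative 1e-9 over 100 random parameter/total draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            r = RateConstants(*np.exp(rng.uniform(np.log(0.5), np.log(20), 2)),
                              *np.exp(rng.uniform(np.log(1e-4), np.log(1e-2), 2)))
            A = rng.uniform(0.5, 5.0)
            T = A * rng.uniform(1.0, 3.0)
            S = rng.uniform(0.01, 1.0)
            exp = ExchangeExperiment(
                A_total=A, T_total=T, S_total=S, duration=2000, dt=100
            )
            tc = simulate_exchange(exp, r)
            a_sum = tc.values[:, :3].sum(axis=1)
            t_sum = tc.values[:, 3] + tc.values[:, 1]
            s_sum = tc.values[:, 4] + tc.values[:, 2]
            assert np.max(np.abs(a_sum - A)) <= 1e-9 * A
            assert np.max(np.abs(t_sum - T)) <= 1e-9 * T
            assert np.max(np.abs(s_sum - S)) <= 1e-9 * max(S, 1e-12)

    def test_ode_limit_matches_oracle_on_random_draws(self):
        """ODE state at t = 50/min(k_off) vs the analytic equilibrium,
        relative 1e-4 per species, 100 seeded random draws."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            r = RateConstants(*np.exp(rng.uniform(np.log(0.5), np.log(20), 2)),
                              *np.exp(rng.uniform(np.log(1e-4), np.log(1e-2), 2)))
            A = rng.uniform(0.5, 5.0)
            T = A * rng.uniform(1.0, 3.0)
            S = rng.uniform(0.01, 1.0)
            t_end = 50.0 / min(r.k_off_T, r.k_off_S)
            exp = ExchangeExperiment(
                A_total=A, T_total=T, S_total=S, duration=t_end, dt=t_end / 4
            )
            tc = simulate_exchange(exp, r)
            eq = competitive_equilibrium(A, T, S, r).as_array()
            rel = np.abs(tc.values[-1] - eq) / (np.abs(eq) + 1e-12)
            assert np.max(rel) < 1e-4

    def test_chase_steps_free_atp_and_strips_label(self, rates):
        exp = ExchangeExperiment(
            A_total=2, T_total=6, S_total=0.2, duration=5400, dt=10,
            chase=(1800.0, 100.0),
        )
        tc = simulate_exchange(exp, rates)
        i = np.searchsorted(tc.times, 1800.0)
        # sample at the chase time reports the pre-addition state
        assert tc.observable("T")[i] < 10.0
        assert tc.observable("T")[i + 1] > 90.0
        # labeled complex decays after the chase
        AS = tc.observable("AS")
        assert AS[-1] < 0.2 * AS[i]

    def test_tolerance_halving_changes_nothing_material(self, rates, monkeypatch):
        exp = ExchangeExperiment(
            A_total=2, T_total=6, S_total=0.2, duration=1800, dt=100
        )
        base = simulate_exchange(exp, rates).values
        monkeypatch.setattr(kin, "_RTOL", kin._RTOL / 2)
        monkeypatch.setattr(kin, "_ATOL", kin._ATOL / 2)
        tight = simulate_exchange(exp, rates).values
        assert np.max(np.abs(base - tight)) < 1e-6

    def test_monotone_label_binding_in_excess_atp_regime(self, rates):
        """For T_total >= 2 A_total >= 10 S_total, AS(t) is non-decreasing
        at the sampled resolution."""
        exp = ExchangeExperiment(
            A_total=2, T_total=6, S_total=0.2, duration=1800, dt=10
        )
        AS = simulate_exchange(exp, rates).observable("AS")
        assert np.all(np.diff(AS) >= -1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            ExchangeExperiment(A_total=2, T_total=6, S_total=0.2, duration=-1, dt=10)
        with pytest.raises(ValidationError):
            ExchangeExperiment(A_total=2, T_total=6, S_total=0.2, duration=100,
                               dt=10, chase=(200.0, 100.0))
        with pytest.raises(ValidationError):
            # fully-loaded convention needs T_total >= A_total
            ExchangeExperiment(A_total=2, T_total=1, S_total=0.2, duration=100, dt=10)


class TestScenarios:
    def test_identity_multiplier(self, rates):
        assert apply_scenario(rates, ScenarioModifiers(1.0)) is rates

    def test_calcium_and_salt_arithmetic(self, rates):
        ca = apply_scenario(rates, ScenarioModifiers(0.2, "Ca"))
        assert ca.k_off_T == pytest.approx(5.6e-4)
        assert ca.k_off_S == pytest.approx(2e-4)
        assert ca.k_on_T == rates.k_on_T and ca.k_on_S == rates.k_on_S
        kcl = apply_scenario(rates, ScenarioModifiers(2.0, "KCl"))
        assert kcl.k_off_T == pytest.approx(5.6e-3)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioModifiers(exchange_multiplier=0.0)

    def test_initial_exchange_rate_scales_linearly_with_multiplier(self, rates):
        """From fully loaded actin, ATP release is rate-limiting, so the
        early label-binding flux is proportional to the multiplier."""
        early = {}
        for m in (0.5, 1.0, 2.0):
            exp = ExchangeExperiment(
                A_total=2, T_total=6, S_total=0.2, duration=5, dt=5,
                scenario=ScenarioModifiers(m),
            )
            early[m] = simulate_exchange(exp, rates).observable("AS")[-1]
        assert early[2.0] / early[1.0] == pytest.approx(2.0, rel=0.02)
        assert early[0.5] / early[1.0] == pytest.approx(0.5, rel=0.02)
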