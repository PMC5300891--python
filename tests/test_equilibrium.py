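"""Steady-state solvers, apparent Kd and the concentration/closing sweeps."""

import numpy as np
import pytest

from loopbind import (
    MixtureConditions,
    SpeciesState,
    apparent_kd,
    closing_rate_sweep,
    detailed_balance_state,
    fraction_bound,
    protein_sweep,
    run_to_equilibrium,
    steady_state_solve,
)
from loopbind.exceptions import ParameterError

from conftest import random_consistent_params, settings_for


class TestSteadyStateSolve:
    def test_reference_mixture_is_mostly_closed_complex(self, ref_params,
                                                        ref_conditions):
        state = steady_state_solve(ref_params, ref_conditions)
        assert fraction_bound(state, ref_conditions.R_tot) == pytest.approx(
            0.907, abs=0.005)
        assert state.CC > 0.9 * state.bound_rna

    def test_no_closing_reproduces_open_complex_levels(self, ref_params,
                                                       ref_conditions):
        # with ring closure off, 200 nM protein and 0.4 nM RNA leave only
        # tens of pM in complexes: C3 38 pM, C4 63 pM, 2:1 complex 8.2 pM
        state = steady_state_solve(ref_params.replace(kC3=0.0, kC4=0.0),
                                   ref_conditions)
        assert state.C3 == pytest.approx(38e-12, rel=0.05)
        assert state.C4 == pytest.approx(63e-12, rel=0.05)
        assert state.D == pytest.approx(8.2e-12, rel=0.05)
        assert state.CC == 0.0

    def test_no_rna_means_no_complexes(self, ref_params):
        state = steady_state_solve(ref_params,
                                   MixtureConditions(P_tot=1e-7, R_tot=0.0))
        assert state == SpeciesState(0, 1e-7, 0, 0, 0, 0)

    def test_conservation_is_exact(self, ref_params, ref_conditions):
        state = steady_state_solve(ref_params, ref_conditions)
        state.check_conservation(ref_conditions, rtol=1e-9)


class TestDetailedBalanceState:
    @pytest.mark.parametrize("P_nM, expected", [(5, 0.19), (50, 0.71)])
    def test_fraction_bound_at_low_protein(self, ref_params, P_nM, expected):
        state = detailed_balance_state(
            ref_params, MixtureConditions(P_tot=P_nM * 1e-9, R_tot=0.4e-9))
        assert fraction_bound(state, 0.4e-9) == pytest.approx(expected,
                                                              abs=0.01)

    def test_saturation_at_high_protein(self, ref_params):
        state = detailed_balance_state(
            ref_params, MixtureConditions(P_tot=1e-3, R_tot=0.4e-9))
        assert fraction_bound(state, 0.4e-9) > 0.999

    def test_refuses_inconsistent_cycle(self, ref_params):
        with pytest.raises(ParameterError, match="detailed balance"):
            detailed_balance_state(
                ref_params.replace(kC3=0.2),
                MixtureConditions(P_tot=1e-7, R_tot=0.4e-9))

    def test_agrees_with_linear_solver(self, ref_params, ref_conditions):
        a = steady_state_solve(ref_params, ref_conditions).as_array()
        b = detailed_balance_state(ref_params, ref_conditions).as_array()
        assert np.all(np.abs(a - b) <= 1e-3 * np.maximum(b, 1e-18))


class TestApparentKd:
    def test_reference_equilibrium_value(self, ref_params, ref_conditions):
        state = steady_state_solve(ref_params, ref_conditions)
        assert apparent_kd(state) == pytest.approx(20.6e-9, rel=0.02)

    def test_tenfold_reduced_closing_weakens_to_150_nM(self, ref_params,
                                                       ref_conditions):
        state = steady_state_solve(
            ref_params.replace(kC3=0.2, kC4=0.9333), ref_conditions)
        assert apparent_kd(state) == pytest.approx(150e-9, rel=0.05)
        assert fraction_bound(state, ref_conditions.R_tot) == pytest.approx(
            0.57, abs=0.03)

    def test_reduces_to_single_site_kd(self):
        # a pure 1:1 state: Kd_app is exactly koff/kon
        Kd = 0.046 / 3.0e4
        P, R = 1e-6, 1e-9
        state = SpeciesState(R=R, P=P, C3=P * R / Kd, C4=0, CC=0, D=0)
        assert apparent_kd(state) == pytest.approx(Kd, rel=1e-12)

    def test_undefined_with_nothing_bound(self):
        with pytest.raises(ParameterError):
            apparent_kd(SpeciesState(1e-9, 1e-7, 0, 0, 0, 0))


class TestProteinSweep:
    def test_reference_titration_points(self, ref_params):
        table = protein_sweep(ref_params, [5e-9, 50e-9, 100e-9, 200e-9],
                              R_tot=0.4e-9)
        np.testing.assert_allclose(table["fraction_bound"],
                                   [0.19, 0.71, 0.83, 0.91], atol=0.02)

    def test_zero_protein_row_is_unbound(self, ref_params):
        table = protein_sweep(ref_params, [0.0, 1e-9], R_tot=0.4e-9)
        assert table["fraction_bound"].iloc[0] == 0.0

    def test_fraction_bound_increases_with_protein(self, ref_params):
        P = np.logspace(-9, -6, 12)
        table = protein_sweep(ref_params, P, R_tot=0.4e-9)
        assert np.all(np.diff(table["fraction_bound"]) > 0)

    def test_fraction_bound_falls_with_apparent_kd(self, ref_params,
                                                   ref_conditions):
        # across a closing-rate sweep, weaker apparent Kd means less bound
        table = closing_rate_sweep(ref_params, [0.2, 0.5, 1.0, 2.0, 5.0],
                                   ref_conditions)
        order = np.argsort(table["Kd_app_M"].to_numpy())
        assert np.all(np.diff(table["fraction_bound"].to_numpy()[order]) <= 0)

    def test_non_monotone_series_rejected(self, ref_params):
        with pytest.raises(ParameterError, match="monotone"):
            protein_sweep(ref_params, [1e-9, 5e-9, 2e-9], R_tot=0.4e-9)


class TestClosingRateSweep:
    def test_tenfold_reduction_with_ratio_preserved(self, ref_params,
                                                    ref_conditions):
        table = closing_rate_sweep(ref_params, [0.2], ref_conditions)
        assert table["kC4_s"].iloc[0] == pytest.approx(0.9333)
        assert table["fraction_bound"].iloc[0] == pytest.approx(0.57,
                                                                abs=0.03)

    def test_response_to_closing_rate_is_asymmetric(self, ref_params,
                                                    ref_conditions):
        # binding is nearly saturated at the reference closing rate, so a
        # tenfold increase gains little while a tenfold decrease loses a
        # third of the bound RNA
        table = closing_rate_sweep(ref_params, [0.2, 2.0, 20.0],
                                   ref_conditions)
        slow, base, fast = table["fraction_bound"]
        assert base == pytest.approx(0.907, abs=0.005)
        gain = fast - base
        loss = base - slow
        assert 0 < gain < 0.1
        assert loss > 3 * gain

    def test_two_to_one_complex_stays_negligible(self, ref_params,
                                                 ref_conditions):
        # over the explored decade each way, the 2:1 complex never exceeds
        # a couple percent of the total RNA
        table = closing_rate_sweep(ref_params,
                                   [0.2, 2.0, 20.0], ref_conditions)
        assert np.all(table["D_M"] / ref_conditions.R_tot < 0.02)

    def test_fixed_kc4_variant_available(self, ref_params, ref_conditions):
        table = closing_rate_sweep(ref_params, [0.2], ref_conditions,
                                   preserve_ratio=False)
        assert table["kC4_s"].iloc[0] == ref_params.kC4


class TestCrossRouteConsistency:
    """The three routes to equilibrium must agree on every species."""

    def test_solver_matches_detailed_balance_on_random_grid(self,
                                                            ref_params):
        rng = np.random.default_rng(2024)
        conditions = MixtureConditions(P_tot=0.2e-6, R_tot=0.4e-9)
        for _ in range(20):
            params = random_consistent_params(rng, ref_params)
            a = steady_state_solve(params, conditions).as_array()
            b = detailed_balance_state(params, conditions).as_array()
            assert np.all(np.abs(a - b) <= 1e-3 * np.maximum(b, 1e-18))

    def test_rk4_matches_solver_on_random_grid(self, ref_params):
        rng = np.random.default_rng(11)
        conditions = MixtureConditions(P_tot=0.2e-6, R_tot=0.4e-9)
        for _ in range(10):
            params = random_consistent_params(rng, ref_params)
            settings = settings_for(params, conditions)
            kinetic = run_to_equilibrium(params, conditions,
                                         settings).state.as_array()
            direct = steady_state_solve(params, conditions).as_array()
            assert np.all(np.abs(kinetic - direct)
                          <= 1e-3 * np.maximum(direct, 1e-18))

    def test_rk4_matches_solver_for_inconsistent_cycle(self, ref_params):
        # a steady state with circulating flux is still a steady state
        params = ref_params.replace(kC3=0.2)  # breaks detailed balance
        conditions = MixtureConditions(P_tot=0.2e-6, R_tot=0.4e-9)
        settings = settings_for(params, conditions)
        kinetic = run_to_equilibrium(params, conditions,
                                     settings).state.as_array()
        direct = steady_state_solve(params, conditions).as_array()
        assert np.all(np.abs(kinetic - direct)
                      <= 1e-3 * np.maximum(direct, 1e-18))


def test_fraction_bound_insensitive_to_rna_level(ref_params, ref_conditions):
    # protein is in vast excess, so 50-fold changes in total RNA shift the
    # bound fraction by less than a percentage point
    base = fraction_bound(
        steady_state_solve(ref_params, ref_conditions), ref_conditions.R_tot)
    for factor in (1 / 50, 50):
        R = ref_conditions.R_tot * factor
        cond = MixtureConditions(P_tot=ref_conditions.P_tot, R_tot=R)
        frac = fraction_bound(steady_state_solve(ref_params, cond), R)
        assert abs(frac - base) < 0.01
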