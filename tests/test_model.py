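"""Rate law, closing-rate derivation and analytic consistency formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from loopbind import (
    KineticParameters,
    MixtureConditions,
    SpeciesState,
    cycle_consistency_ratio,
    derive_closing_rates,
    effective_dissociation_rate,
    mass_action_rhs,
)
from loopbind.exceptions import InvalidStateError, ParameterError

conc = st.floats(min_value=0.0, max_value=1e-3, allow_nan=False)
rate1 = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
rate2 = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


class TestMassActionRhs:
    def test_empty_system_is_static(self, ref_params):
        state = SpeciesState(0, 0, 0, 0, 0, 0)
        assert mass_action_rhs(state, ref_params) == (0, 0, 0, 0, 0, 0)

    def test_closed_complex_opens_through_both_contacts(self, ref_params):
        # CC alone decays at koff3+koff4, feeding C3 via KH4 release and
        # C4 via KH3 release
        state = SpeciesState(R=0, P=0, C3=0, C4=0, CC=1e-9, D=0)
        d = mass_action_rhs(state, ref_params)
        assert d.dCC == pytest.approx(-0.176e-9, rel=1e-12)
        assert d.dC3 == pytest.approx(0.13e-9, rel=1e-12)
        assert d.dC4 == pytest.approx(0.046e-9, rel=1e-12)
        assert d.dR == d.dP == d.dD == 0.0

    @given(R=conc, P=conc, C3=conc, C4=conc, CC=conc, D=conc,
           kon3=rate2, koff3=rate1, kon4=rate2, koff4=rate1,
           kC3=rate1, kC4=rate1)
    @hyp_settings(max_examples=200, derandomize=True)
    def test_mass_conservation_for_any_state(self, R, P, C3, C4, CC, D,
                                             kon3, koff3, kon4, koff4,
                                             kC3, kC4):
        params = KineticParameters(kon3, koff3, kon4, koff4, kC3, kC4)
        d = mass_action_rhs(SpeciesState(R, P, C3, C4, CC, D), params)
        rna_scale = max(abs(v) for v in d) + 1e-30
        assert abs(d.dR + d.dC3 + d.dC4 + d.dCC + d.dD) <= 1e-12 * rna_scale
        assert abs(d.dP + d.dC3 + d.dC4 + d.dCC + 2 * d.dD) \
            <= 1e-12 * rna_scale

    def test_matches_compiled_rate_law_bitwise(self, ref_params):
        # the integrator core carries its own copy of the rate law; the
        # two must never drift apart
        from loopbind import _core
        from loopbind.simulate import _rate_vector

        rng = np.random.default_rng(3)
        k = _rate_vector(ref_params)
        for _ in range(50):
            y = rng.uniform(0, 1e-6, 6)
            out = np.empty(6)
            _core.rhs(y, k, out)
            d = mass_action_rhs(SpeciesState.from_array(y), ref_params)
            assert np.array_equal(out, np.array(d))

    def test_rejects_unphysical_states(self, ref_params):
        with pytest.raises(InvalidStateError):
            SpeciesState(R=-1e-9, P=0, C3=0, C4=0, CC=0, D=0)
        with pytest.raises(InvalidStateError):
            SpeciesState(R=math.nan, P=0, C3=0, C4=0, CC=0, D=0)


class TestDeriveClosingRates:
    def test_reproduces_reference_closing_rates(self):
        # single-domain kinetics + 20 nM overall Kd give the derived pair
        kC3, kC4 = derive_closing_rates(3.0e4, 0.046, 1.4e5, 0.13, 2.0e-8)
        assert kC3 == pytest.approx(2.1357142857, rel=1e-9)
        assert kC4 == pytest.approx(9.9666666667, rel=1e-9)
        # rounds to one significant figure of 2 (and ~10 for kC4)
        assert round(kC3) == 2

    def test_output_closes_the_cycle_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            kon3, kon4 = 10.0 ** rng.uniform(3, 7, 2)
            koff3, koff4 = 10.0 ** rng.uniform(-3, 0, 2)
            kd = 10.0 ** rng.uniform(-9, -6)
            kC3, kC4 = derive_closing_rates(kon3, koff3, kon4, koff4, kd)
            params = KineticParameters(kon3, koff3, kon4, koff4, kC3, kC4)
            assert cycle_consistency_ratio(params) == pytest.approx(1.0,
                                                                    rel=1e-12)

    def test_symmetric_domains_give_kc_equal_koff(self):
        kon, koff = 1e5, 0.1
        kC3, kC4 = derive_closing_rates(kon, koff, kon, koff, koff / kon)
        assert kC3 == pytest.approx(koff) and kC4 == pytest.approx(koff)

    def test_doubling_kd_halves_both_rates(self):
        a = derive_closing_rates(3.0e4, 0.046, 1.4e5, 0.13, 2.0e-8)
        b = derive_closing_rates(3.0e4, 0.046, 1.4e5, 0.13, 4.0e-8)
        assert b[0] == pytest.approx(a[0] / 2) and b[1] == pytest.approx(a[1] / 2)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ParameterError):
            derive_closing_rates(0.0, 0.046, 1.4e5, 0.13, 2e-8)
        with pytest.raises(ParameterError):
            derive_closing_rates(3e4, 0.046, 1.4e5, 0.13, -1e-8)


class TestCycleConsistency:
    def test_reference_set_is_consistent(self, ref_params):
        assert cycle_consistency_ratio(ref_params) == pytest.approx(
            0.9999642857, rel=1e-9)
        assert ref_params.is_thermodynamically_consistent()

    def test_tenfold_kc3_reduction_alone_breaks_the_cycle(self, ref_params):
        broken = ref_params.replace(kC3=0.2)
        assert cycle_consistency_ratio(broken) == pytest.approx(9.999642857,
                                                                rel=1e-8)
        assert not broken.is_thermodynamically_consistent()

    def test_undefined_for_zero_rates(self, ref_params):
        with pytest.raises(ParameterError):
            cycle_consistency_ratio(ref_params.replace(kC3=0.0))


class TestEffectiveDissociationRate:
    def test_reference_value(self, ref_params):
        assert effective_dissociation_rate(ref_params) == pytest.approx(
            0.0034451, rel=1e-4)

    def test_no_reclosure_limit_is_sum_of_offs(self, ref_params):
        p = ref_params.replace(kC3=0.0, kC4=0.0)
        assert effective_dissociation_rate(p) == pytest.approx(
            ref_params.koff3 + ref_params.koff4, rel=1e-12)

    def test_infinite_avidity_limit_vanishes(self, ref_params):
        p = ref_params.replace(kC3=1e12, kC4=1e12)
        assert effective_dissociation_rate(p) < 1e-12


class TestParameterTypes:
    def test_single_site_kds(self, ref_params):
        assert ref_params.Kd3 == pytest.approx(1.5333e-6, rel=1e-4)
        assert ref_params.Kd4 == pytest.approx(9.2857e-7, rel=1e-4)

    def test_rejects_negative_rate(self):
        with pytest.raises(ParameterError):
            KineticParameters(-1.0, 0.046, 1.4e5, 0.13, 2.0, 9.333)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ParameterError):
            MixtureConditions(P_tot=-1e-9, R_tot=0.0)

    def test_unit_tagged_roundtrip(self, ref_params):
        again = KineticParameters.from_dict(ref_params.to_dict())
        assert again == ref_params

    def test_unit_conversion_on_load(self):
        p = KineticParameters.from_dict({
            "kon3": {"value": 3.0e-5, "unit": "1/(nM*s)"},
            "koff3": {"value": 0.046, "unit": "1/s"},
            "kon4": 1.4e5, "koff4": 0.13, "kC3": 2.0, "kC4": 9.333,
        })
        assert p.kon3 == pytest.approx(3.0e4)

    def test_swap_is_an_involution(self, ref_params):
        assert ref_params.swapped().swapped() == ref_params
        assert ref_params.swapped().kon3 == ref_params.kon4
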