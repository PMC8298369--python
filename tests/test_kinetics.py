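"""Rate laws: radical partition factors, Fenton-like rate, rate vectors."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photofenton import kinetics as kin

# a representative reacting state: 40 mg/L PCT, 378 mg/L H2O2, 10 mg/L iron
STATE = kin.ConcentrationState(
    c_pct=2.646e-4, c_h2o2=1.111e-2, c_fe2=1.791e-4, c_fe3=0.0
)

positive_conc = st.floats(1e-9, 1.0, allow_nan=False)


@pytest.fixture(scope="module")
def params():
    return kin.default_params()


class TestPartitionFactors:
    def test_delta_reference_state(self, params):
        # 1 + (7.00e7/3.58e9) * 42.0
        assert kin.delta(STATE, params) == pytest.approx(1.821, rel=1e-3)

    def test_rho_reference_state(self, params):
        # 1 + 51.14 * 0.02381
        assert kin.rho(STATE, params) == pytest.approx(2.218, rel=1e-3)

    def test_delta_limits(self, params):
        no_h2o2 = kin.ConcentrationState(1e-4, 0.0, 0.0, 0.0)
        assert kin.delta(no_h2o2, params) == 1.0
        tiny_k4 = params.replace(k4=1e-30)
        assert kin.delta(STATE, tiny_k4) == pytest.approx(1.0)

    def test_rho_limit_no_pct(self, params):
        no_pct = kin.ConcentrationState(0.0, 1e-2, 0.0, 0.0)
        assert kin.rho(no_pct, params) == 1.0

    def test_degenerate_inputs_raise(self, params):
        with pytest.raises(ZeroDivisionError):
            kin.delta(kin.ConcentrationState(0.0, 1e-2, 0.0, 0.0), params)
        with pytest.raises(ZeroDivisionError):
            kin.rho(kin.ConcentrationState(1e-4, 0.0, 0.0, 0.0), params)

    @given(cp=positive_conc, ch=positive_conc)
    @settings(deadline=None, max_examples=100)
    def test_partition_fractions_sum_to_one(self, params, cp, ch):
        state = kin.ConcentrationState(cp, ch, 0.0, 0.0)
        assert 1 / kin.delta(state, params) + 1 / kin.rho(state, params) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_robust_partition_degenerate_limits(self, params):
        k4, k5 = params.k4, params.k5
        assert kin.radical_partition(0.0, 0.0, k4, k5) == (0.0, 0.0)
        assert kin.radical_partition(1e-4, 0.0, k4, k5) == (1.0, 0.0)
        assert kin.radical_partition(0.0, 1e-2, k4, k5) == (0.0, 1.0)


class TestGammaRate:
    def test_direct_product(self, params):
        s = kin.ConcentrationState(0.0, 1.111e-2, 0.0, 1.791e-4)
        assert kin.gamma_rate(s, params) == pytest.approx(6.29e-6, rel=1e-3)

    @pytest.mark.parametrize("cf3, ch", [(0.0, 1e-2), (1e-4, 0.0)])
    def test_vanishes_without_either_reagent(self, params, cf3, ch):
        s = kin.ConcentrationState(0.0, ch, 0.0, cf3)
        assert kin.gamma_rate(s, params) == 0.0


class TestThermalRates:
    def test_reference_pct_rate(self, params):
        r = kin.thermal_rates(STATE, params)
        # F = k1 * 1.791e-4 * 1.111e-2 = 2.931e-4, delta = 1.821
        assert r.r_pct == pytest.approx(-1.609e-4, rel=1e-3)

    def test_no_iron_is_inert(self, params):
        s = kin.ConcentrationState(2.6e-4, 1.1e-2, 0.0, 0.0)
        r = kin.thermal_rates(s, params)
        assert (r.r_pct, r.r_h2o2, r.r_fe2, r.r_fe3) == (0.0, 0.0, 0.0, 0.0)

    @given(cp=positive_conc, ch=positive_conc, cf2=positive_conc, cf3=positive_conc)
    @settings(deadline=None, max_examples=100)
    def test_iron_conservation_and_signs(self, params, cp, ch, cf2, cf3):
        s = kin.ConcentrationState(cp, ch, cf2, cf3)
        r = kin.thermal_rates(s, params)
        assert r.r_fe2 + r.r_fe3 == pytest.approx(0.0, abs=1e-25)
        assert r.r_pct <= 0 and r.r_h2o2 <= 0


class TestTotalRates:
    def test_dark_limit_matches_thermal(self, params):
        assert kin.total_rates(STATE, params, 0.0, 0.1) == kin.thermal_rates(
            STATE, params
        )

    def test_photochemical_split_and_iron_swap(self, params):
        lvrpa, v_ratio = 1e-6, 0.1
        dark = kin.thermal_rates(STATE, params)
        lit = kin.total_rates(STATE, params, lvrpa, v_ratio)
        photo = v_ratio * params.phi_bar * lvrpa
        # PCT + H2O2 photochemical losses sum to the full absorbed-photon rate
        extra_loss = (lit.r_pct - dark.r_pct) + (lit.r_h2o2 - dark.r_h2o2)
        assert extra_loss == pytest.approx(-photo, rel=1e-12)
        assert lit.r_fe2 - dark.r_fe2 == pytest.approx(+photo, rel=1e-12)
        assert lit.r_fe3 - dark.r_fe3 == pytest.approx(-photo, rel=1e-12)

    def test_negative_lvrpa_rejected(self, params):
        with pytest.raises(ValueError):
            kin.total_rates(STATE, params, -1e-9, 0.1)

    @given(cp=positive_conc, ch=positive_conc, cf2=positive_conc, cf3=positive_conc)
    @settings(deadline=None, max_examples=50)
    def test_rates_depend_on_k4_k5_only_through_ratio(
        self, params, cp, ch, cf2, cf3
    ):
        s = kin.ConcentrationState(cp, ch, cf2, cf3)
        scaled = params.replace(k4=params.k4 * 10, k5=params.k5 * 10)
        r1 = kin.total_rates(s, params, 1e-6, 0.1)
        r2 = kin.total_rates(s, scaled, 1e-6, 0.1)
        for attr in ("r_pct", "r_h2o2", "r_fe2", "r_fe3"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), rel=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        kin.KineticParams(k1=-1, k3=1, k4=1, k5=1, phi_bar=0.1)
    with pytest.raises(ValueError):
        kin.ConcentrationState(-1e-9, 0, 0, 0)
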