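"""Closed-form model evaluators: frozen values, limits and error handling."""

import math

import numpy as np
import pytest

from fluorex.constants import R_KCAL, T_DEFAULT
from fluorex.exchange_models import (
    CPMGDataset,
    CPMGPoint,
    LuzMeiboomParams,
    TwoStateFastParams,
    carver_richards_r2,
    delta_omega_from_ppm,
    derive_slow_exchange_thermo,
    luz_meiboom_r2,
    ppm_from_delta_omega,
    r2_effective,
    slow_exchange_intensity,
)

T_CT = 3.84e-3


class TestR2Effective:
    @pytest.mark.parametrize(
        "intensity, expected",
        [
            (1.0, 0.0),  # I = I0
            (math.exp(-1.0), 1.0 / T_CT),  # one decade of e
            (0.7, 92.8840999840449),  # frozen high-precision value
        ],
    )
    def test_values(self, intensity, expected):
        assert r2_effective(intensity, 1.0, T_CT) == pytest.approx(expected, rel=1e-12)

    def test_vectorised(self):
        out = r2_effective(np.array([1.0, 0.5]), 1.0, T_CT)
        assert out.shape == (2,)
        assert out[0] == 0.0

    def test_negative_rate_allowed_for_noise(self):
        assert r2_effective(1.1, 1.0, T_CT) < 0

    @pytest.mark.parametrize("i, i0, t", [(0.0, 1.0, T_CT), (-1.0, 1.0, T_CT),
                                          (0.5, 0.0, T_CT), (0.5, 1.0, 0.0)])
    def test_domain_errors(self, i, i0, t):
        with pytest.raises(ValueError):
            r2_effective(i, i0, t)


class TestLuzMeiboom:
    def test_no_exchange_returns_r2_0(self):
        p = LuzMeiboomParams(k_app=1234.0, c=0.0, r2_0=20.0)
        assert luz_meiboom_r2(500.0, p) == 20.0

    def test_large_nu_limit(self):
        p = LuzMeiboomParams(k_app=1000.0, c=2e5, r2_0=20.0)
        assert luz_meiboom_r2(1e9, p) == pytest.approx(20.0, abs=1e-6)

    def test_frozen_value(self):
        p = LuzMeiboomParams(k_app=1000.0, c=2e5, r2_0=20.0)
        assert luz_meiboom_r2(500.0, p) == pytest.approx(35.1531370959961, rel=1e-12)

    def test_monotone_non_increasing(self):
        p = LuzMeiboomParams(k_app=3000.0, c=5e5, r2_0=15.0)
        nus = np.linspace(130.0, 6000.0, 200)
        vals = luz_meiboom_r2(nus, p)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals >= p.r2_0 - 1e-12)

    def test_zero_rate_with_exchange_is_error(self):
        with pytest.raises(ValueError):
            luz_meiboom_r2(500.0, LuzMeiboomParams(k_app=0.0, c=1.0, r2_0=5.0))


class TestCarverRichards:
    def test_single_state_limit(self):
        p = TwoStateFastParams(k_i=5000.0, p_a=1.0, p_b=0.0, delta_delta=2.0,
                               r2_0=30.0)
        dw = delta_omega_from_ppm(2.0, 564.0)
        assert carver_richards_r2(500.0, p, dw) == pytest.approx(30.0, abs=1e-9)

    def test_degenerate_shifts(self):
        p = TwoStateFastParams(k_i=5000.0, p_a=0.7, p_b=0.3, delta_delta=0.0,
                               r2_0=30.0)
        assert carver_richards_r2(500.0, p, 0.0) == pytest.approx(30.0, abs=1e-9)

    def test_population_swap_invariance(self):
        dw = delta_omega_from_ppm(1.2, 564.0)
        a = TwoStateFastParams(4300.0, 0.81, 0.19, 1.2, 30.0)
        b = TwoStateFastParams(4300.0, 0.19, 0.81, 1.2, 30.0)
        nus = np.geomspace(130.0, 6000.0, 20)
        np.testing.assert_allclose(
            carver_richards_r2(nus, a, dw), carver_richards_r2(nus, b, dw),
            rtol=1e-10,
        )

    def test_high_nu_approaches_r2_0(self):
        dw = delta_omega_from_ppm(1.2, 564.0)
        p = TwoStateFastParams(4300.0, 0.81, 0.19, 1.2, 30.0)
        assert carver_richards_r2(1e8, p, dw) == pytest.approx(30.0, abs=1e-3)

    def test_fast_exchange_reduces_to_luz_meiboom(self):
        # k_i >> dw: populations and shift enter only through c = pA pB dw^2
        dd, f = 0.5, 564.0
        dw = delta_omega_from_ppm(dd, f)
        k = 50.0 * dw
        pa = 0.8
        cr = TwoStateFastParams(k, pa, 1 - pa, dd, 20.0)
        lm = LuzMeiboomParams(k_app=k, c=pa * (1 - pa) * dw**2, r2_0=20.0)
        nus = np.geomspace(130.2, 5989.6, 14)
        np.testing.assert_allclose(
            carver_richards_r2(nus, cr, dw), luz_meiboom_r2(nus, lm), rtol=0.01
        )


class TestSlowExchangeIntensity:
    def test_initial_condition(self):
        assert slow_exchange_intensity(0.0, 2.5, 1.2, 1.0) == pytest.approx(2.5)

    def test_steady_state_half(self):
        # k_mn = R1 -> plateau at i0/2
        assert slow_exchange_intensity(1e6, 1.0, 1.3, 1.3) == pytest.approx(0.5)

    def test_frozen_value(self):
        assert slow_exchange_intensity(0.5, 1.0, 1.2, 1.0) == pytest.approx(
            0.636111500198952, rel=1e-12
        )

    def test_strictly_decreasing_and_bounded(self):
        taus = np.linspace(0, 3, 100)
        vals = slow_exchange_intensity(taus, 1.0, 2.0, 1.5)
        assert np.all(np.diff(vals) < 0)
        plateau = 1.0 * 1.5 / 3.5
        assert np.all(vals >= plateau - 1e-12)

    def test_degenerate_no_rates(self):
        assert slow_exchange_intensity(5.0, 1.0, 0.0, 0.0) == 1.0


class TestSlowExchangeThermo:
    def test_printed_rate_pair(self):
        s = derive_slow_exchange_thermo(1.08, 1.23)
        assert s.k_s == pytest.approx(2.31, abs=5e-3)
        assert round(s.p_active, 2) == 0.47
        assert round(s.p_inactive, 2) == 0.53

    def test_symmetric_rates(self):
        s = derive_slow_exchange_thermo(3.3, 3.3)
        assert s.p_active == pytest.approx(0.5)
        assert s.delta_g == pytest.approx(0.0, abs=1e-12)

    def test_ligand_rate_pair_free_energy(self):
        # frozen hand evaluation at R = 1.9872e-3, T = 298.15
        s = derive_slow_exchange_thermo(4.2, 8.3)
        assert s.delta_g == pytest.approx(0.4035826946, rel=1e-8)

    def test_direction_antisymmetry(self):
        fwd = derive_slow_exchange_thermo(1.08, 1.23)
        rev = derive_slow_exchange_thermo(1.23, 1.08)
        assert fwd.delta_g == pytest.approx(-rev.delta_g, rel=1e-12)

    def test_detailed_balance_exact(self):
        s = derive_slow_exchange_thermo(0.7, 2.9)
        assert s.p_active * s.k_nm == pytest.approx(s.p_inactive * s.k_mn, rel=1e-12)

    def test_error_propagation_scales(self):
        s = derive_slow_exchange_thermo(1.08, 1.23, k_mn_err=0.05, k_nm_err=0.04)
        assert s.uncertainties["k_s"] == pytest.approx(math.hypot(0.05, 0.04))
        assert s.uncertainties["delta_g"] > 0

    @pytest.mark.parametrize("kmn, knm", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rate_rejected(self, kmn, knm):
        with pytest.raises(ValueError):
            derive_slow_exchange_thermo(kmn, knm)


class TestShiftConversion:
    def test_zero(self):
        assert delta_omega_from_ppm(0.0, 564.0) == 0.0

    def test_direct_arithmetic(self):
        assert delta_omega_from_ppm(1.2, 564.0) == pytest.approx(4252.4598159, rel=1e-9)

    def test_round_trip(self):
        dw = delta_omega_from_ppm(2.9, 659.0)
        assert dw == pytest.approx(12007.7954406, rel=1e-9)
        assert ppm_from_delta_omega(dw, 659.0) == pytest.approx(2.9, rel=1e-12)


class TestDomainTypes:
    def test_cpmg_point_validation(self):
        with pytest.raises(ValueError):
            CPMGPoint(nu_cpmg=0.0, intensity=1.0)
        with pytest.raises(ValueError):
            CPMGPoint(nu_cpmg=100.0, intensity=math.inf)

    def test_dataset_needs_two_points(self):
        with pytest.raises(ValueError):
            CPMGDataset(564.0, T_CT, 1.0, (CPMGPoint(130.0, 0.9),))

    def test_populations_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TwoStateFastParams(k_i=100.0, p_a=0.6, p_b=0.6, delta_delta=1.0)
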