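"""Parameter estimation: identifiability, degeneracy flags, uncertainties."""

import math

import lmfit
import numpy as np
import pytest

from fluorex.exchange_models import (
    LuzMeiboomParams,
    delta_omega_from_ppm,
    luz_meiboom_r2,
)
from fluorex.fitting import (
    RelaxationSeries,
    SaturationSeries,
    estimate_uncertainties,
    fit_carver_richards_global,
    fit_inversion_recovery,
    fit_luz_meiboom,
    fit_saturation_transfer,
)
from fluorex.synthetic_data import (
    default_ground_truth,
    generate_cpmg_series,
    generate_inversion_recovery,
    generate_saturation_series,
)

T_CT = 3.84e-3


class TestInversionRecovery:
    def test_noiseless_exact(self, truth_noiseless):
        series = generate_inversion_recovery(truth_noiseless, "active", "apo")
        fit = fit_inversion_recovery(series)
        assert fit.converged
        assert fit.values["r1"] == pytest.approx(1.5, rel=1e-6)

    def test_one_percent_noise_within_five_percent(self):
        truth = default_ground_truth(noise_sigma=0.01, seed=21)
        series = generate_inversion_recovery(truth, "inactive", "apo", seed=21)
        fit = fit_inversion_recovery(series)
        assert fit.values["r1"] == pytest.approx(1.5, rel=0.05)
        assert fit.stderr["r1"] > 0

    def test_constant_series_flagged(self):
        series = RelaxationSeries(
            taus=np.linspace(0.025, 0.8, 10), intensities=np.ones(10)
        )
        fit = fit_inversion_recovery(series)
        assert not fit.converged
        assert "no_decay" in fit.flags

    def test_imperfect_inversion_does_not_bias_r1(self):
        taus = np.linspace(0.025, 0.8, 12)
        y = 1.0 - 1.6 * np.exp(-2.0 * taus)  # B != 2A
        fit = fit_inversion_recovery(RelaxationSeries(taus, y))
        assert fit.values["r1"] == pytest.approx(2.0, rel=1e-6)


class TestLuzMeiboom:
    def _fast_dataset(self, k_app=30000.0, c=4e5, r2_0=20.0):
        from fluorex.exchange_models import CPMGDataset, CPMGPoint

        nus = np.array([n / (2 * T_CT) for n in range(1, 47, 3)])
        r2 = luz_meiboom_r2(nus, LuzMeiboomParams(k_app, c, r2_0))
        points = tuple(
            CPMGPoint(nu, math.exp(-T_CT * r)) for nu, r in zip(nus, r2)
        )
        return CPMGDataset(564.0, T_CT, 1.0, points)

    def test_noiseless_fast_exchange_recovery(self):
        fit = fit_luz_meiboom(self._fast_dataset())
        assert fit.converged
        assert fit.values["k_app"] == pytest.approx(30000.0, rel=0.02)
        assert fit.values["r2_0"] == pytest.approx(20.0, rel=0.02)

    def test_flat_dispersion_flagged(self):
        fit = fit_luz_meiboom(self._fast_dataset(c=0.0))
        assert not fit.converged
        assert fit.values["c"] == 0.0
        assert "flat_dispersion" in fit.flags or "exchange_unidentifiable" in fit.flags

    def test_replicate_seeds_agree(self):
        truth_a = default_ground_truth(noise_sigma=0.01, seed=100)
        truth_b = default_ground_truth(noise_sigma=0.01, seed=200)
        fits = []
        for truth, seed in ((truth_a, 100), (truth_b, 200)):
            ds = generate_cpmg_series(truth, "active", "apo", 564.0, seed=seed)
            fits.append(fit_luz_meiboom(ds))
        ka, kb = fits[0].values["k_app"], fits[1].values["k_app"]
        joint = math.hypot(fits[0].stderr["k_app"], fits[1].stderr["k_app"])
        assert abs(ka - kb) < 3 * joint


class TestCarverRichardsGlobal:
    def test_noiseless_two_field_recovery(self, truth_noiseless):
        # sparsely populated extended state of the inactive manifold
        datasets = [
            generate_cpmg_series(truth_noiseless, "inactive", "apo", f)
            for f in (564.0, 659.0)
        ]
        fit = fit_carver_richards_global(datasets)
        assert fit.converged
        assert fit.delta_delta == pytest.approx(2.9, rel=1e-3)
        apo = fit.per_condition["apo"]
        assert apo.k_i == pytest.approx(8000.0, rel=1e-2)
        assert min(apo.p_a, apo.p_b) == pytest.approx(0.009, rel=1e-2)

    def test_noiseless_recovery_majority_minor_state(self, truth_noiseless):
        datasets = [
            generate_cpmg_series(truth_noiseless, "active", "apo", f)
            for f in (564.0, 659.0)
        ]
        fit = fit_carver_richards_global(datasets)
        assert fit.delta_delta == pytest.approx(1.2, rel=1e-3)
        assert fit.per_condition["apo"].k_i == pytest.approx(4300.0, rel=1e-2)
        assert min(fit.per_condition["apo"].p_a,
                   fit.per_condition["apo"].p_b) == pytest.approx(0.19, rel=1e-2)

    def test_conditions_share_ddelta_but_not_rates(self, truth_noiseless):
        datasets = [
            generate_cpmg_series(truth_noiseless, "active", cond, f)
            for cond in ("apo", "ligand") for f in (564.0, 659.0)
        ]
        fit = fit_carver_richards_global(datasets)
        assert set(fit.per_condition) == {"apo", "ligand"}
        assert fit.per_condition["apo"].delta_delta == fit.per_condition[
            "ligand"].delta_delta
        assert fit.per_condition["apo"].k_i == pytest.approx(4300.0, rel=0.02)
        assert fit.per_condition["ligand"].k_i == pytest.approx(7300.0, rel=0.02)

    def test_flat_dispersion_flagged_unidentifiable(self):
        from fluorex.exchange_models import CPMGDataset, CPMGPoint

        nus = [n / (2 * T_CT) for n in range(1, 47, 4)]
        points = tuple(CPMGPoint(nu, math.exp(-T_CT * 25.0)) for nu in nus)
        ds = CPMGDataset(564.0, T_CT, 1.0, points)
        fit = fit_carver_richards_global([ds])
        assert ("exchange_unidentifiable" in fit.flags
                or fit.delta_delta < 0.05
                or min(fit.per_condition[ds.condition].p_a,
                       fit.per_condition[ds.condition].p_b) < 1e-3)

    def test_single_field_records_degeneracy_warning(self, truth_noiseless):
        ds = generate_cpmg_series(truth_noiseless, "active", "apo", 564.0)
        fit = fit_carver_richards_global([ds])
        assert "single_field_degenerate" in fit.flags

    def test_mixed_resonances_rejected(self, truth_noiseless):
        a = generate_cpmg_series(truth_noiseless, "active", "apo", 564.0)
        b = generate_cpmg_series(truth_noiseless, "inactive", "apo", 564.0)
        with pytest.raises(ValueError):
            fit_carver_richards_global([a, b])


class TestSaturationTransfer:
    def test_noiseless_recovery(self, truth_noiseless):
        series = generate_saturation_series(truth_noiseless, "inactive", "apo")
        fit = fit_saturation_transfer(series)
        assert fit.converged
        assert fit.values["k_mn"] == pytest.approx(1.08, rel=1e-4)

    def test_flat_trace_flagged(self):
        series = SaturationSeries(
            taus=np.geomspace(0.025, 1.0, 8), intensities=np.ones(8),
            observed="inactive", saturated="active", r1=1.5,
        )
        fit = fit_saturation_transfer(series)
        assert "rate_indistinguishable_from_zero" in fit.flags

    def test_missing_r1_is_precondition_error(self):
        series = SaturationSeries(
            taus=np.geomspace(0.025, 1.0, 8),
            intensities=np.linspace(1, 0.5, 8),
            observed="inactive", saturated="active", r1=None,
        )
        with pytest.raises(ValueError):
            fit_saturation_transfer(series)

    def test_noisy_recovery_fast_fold_switch(self):
        # ligand-enhanced rate out of the active state
        errs = []
        for seed in range(20):
            truth = default_ground_truth(noise_sigma=0.01, seed=seed)
            series = generate_saturation_series(truth, "active", "ligand",
                                                seed=seed)
            fit = fit_saturation_transfer(series)
            errs.append(abs(fit.values["k_mn"] - 8.3) / 8.3)
        assert np.median(errs) < 0.10


class TestEstimateUncertainties:
    def _linear_fit(self, sigma=0.1, n=30, seed=4):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, n)
        y = 2.0 + 3.0 * x + rng.normal(0, sigma, n)
        params = lmfit.Parameters()
        params.add("a", value=0.0)
        params.add("b", value=0.0)

        def resid(p, data):
            return p["a"] + p["b"] * x - data

        out = lmfit.minimize(resid, params, args=(y,), method="least_squares")
        return x, y, out, resid

    def test_covariance_matches_ols_closed_form(self):
        x, y, out, _ = self._linear_fit()
        n = len(x)
        yhat = out.params["a"].value + out.params["b"].value * x
        s2 = np.sum((y - yhat) ** 2) / (n - 2)
        sxx = np.sum((x - x.mean()) ** 2)
        se_b = math.sqrt(s2 / sxx)
        se_a = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
        unc = estimate_uncertainties(out, method="covariance")
        assert unc["a"]["covariance"] == pytest.approx(se_a, rel=1e-6)
        assert unc["b"]["covariance"] == pytest.approx(se_b, rel=1e-6)

    def test_bootstrap_deterministic_under_seed(self):
        x, y, out, resid = self._linear_fit()
        yhat = out.params["a"].value + out.params["b"].value * x

        def refit(resampled):
            params = lmfit.Parameters()
            params.add("a", value=0.0)
            params.add("b", value=0.0)
            boot = lmfit.minimize(resid, params, args=(yhat + resampled,),
                                  method="least_squares")
            return {k: boot.params[k].value for k in boot.params}

        u1 = estimate_uncertainties(out, method="residual-bootstrap",
                                    n_boot=50, seed=9, refit=refit)
        u2 = estimate_uncertainties(out, method="residual-bootstrap",
                                    n_boot=50, seed=9, refit=refit)
        assert u1["b"]["bootstrap"] == u2["b"]["bootstrap"]
        # bootstrap and covariance agree to leading order
        unc = estimate_uncertainties(out, method="covariance")
        assert u1["b"]["bootstrap"] == pytest.approx(
            unc["b"]["covariance"], rel=0.5
        )

    def test_noiseless_fit_has_negligible_uncertainty(self):
        x = np.linspace(0, 1, 20)
        y = 2.0 + 3.0 * x
        params = lmfit.Parameters()
        params.add("a", value=0.1)
        params.add("b", value=0.1)
        out = lmfit.minimize(lambda p: p["a"] + p["b"] * x - y, params,
                             method="least_squares")
        unc = estimate_uncertainties(out, method="covariance")
        assert unc["a"]["covariance"] < 1e-7

    def test_unknown_method_rejected(self):
        _, _, out, _ = self._linear_fit()
        with pytest.raises(ValueError):
            estimate_uncertainties(out, method="magic")
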