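import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from dungsight.integrated import (ModelSpec, _bin_integrals, aicc,
                                  build_model_data, fit, integrated_loglik,
                                  predict_density)
from dungsight.survey_data import bin_distances, filter_middens
from dungsight.synthetic import SimulationScenario, simulate_survey


@pytest.fixture(scope="module")
def oryx_data(default_survey, default_binned):
    spec = ModelSpec(species="oryx", terms=("rock_cover", "richness"))
    data = build_model_data(default_binned, default_survey.transects,
                            default_survey.covariates, spec,
                            default_survey.cutpoints)
    return spec, data


def brute_force_loglik(data, beta, sigma_b, sigma_det, n_grid=100_001,
                       span=6.0):
    """Independent trapezoid integration of the random effect, per system."""
    I = _bin_integrals(sigma_det, data.cutpoints, "half_normal")
    eta = data.X @ beta
    A = data.exposure[:, None] * I[None, :]
    b = np.linspace(-span * sigma_b, span * sigma_b, n_grid)
    total = 0.0
    for s in range(data.n_systems):
        rows = data.system_idx == s
        lam = (np.exp(eta[rows])[:, None, None] * A[rows][:, :, None]
               * np.exp(b)[None, None, :])
        logf = (data.counts[rows][:, :, None] * np.log(lam) - lam
                - special.gammaln(data.counts[rows] + 1)[:, :, None]
                ).sum(axis=(0, 1))
        dens = stats.norm.pdf(b, 0, sigma_b)
        total += np.log(np.trapezoid(np.exp(logf) * dens, b))
    return total


class TestIntegratedLoglik:
    def test_matches_brute_force_single_system(self, default_survey):
        tr = default_survey.transects[default_survey.transects.wadi_system == "W1"]
        ev = default_survey.events[
            default_survey.events.transect_id.isin(tr.transect_id)]
        retained, _ = filter_middens(ev)
        binned = bin_distances(retained, tr, default_survey.cutpoints)
        spec = ModelSpec(species="oryx", terms=("rock_cover",))
        cov = default_survey.covariates[
            default_survey.covariates.transect_id.isin(tr.transect_id)]
        data = build_model_data(binned, tr, cov, spec,
                                default_survey.cutpoints)
        theta = np.array([-4.5, -0.03, np.log(0.3), np.log(1.5)])
        ll = integrated_loglik(data, theta)
        ll_bf = brute_force_loglik(data, theta[:2], 0.3, 1.5)
        assert ll == pytest.approx(ll_bf, abs=1e-6)

    def test_matches_brute_force_all_systems(self, oryx_data):
        spec, data = oryx_data
        theta = np.array([-4.7, -0.031, 0.208, np.log(0.3), np.log(1.5)])
        ll = integrated_loglik(data, theta)
        ll_bf = brute_force_loglik(data, theta[:3], 0.3, 1.5)
        assert ll == pytest.approx(ll_bf, abs=1e-6)

    def test_degenerate_random_effect_is_poisson(self, oryx_data):
        """sigma_b -> 0 collapses to the fixed-effects Poisson likelihood."""
        spec, data = oryx_data
        beta = np.array([-4.7, -0.031, 0.208])
        theta = np.concatenate([beta, [np.log(1e-7), np.log(1.5)]])
        ll = integrated_loglik(data, theta)
        I = _bin_integrals(1.5, data.cutpoints, "half_normal")
        lam = np.exp(data.X @ beta)[:, None] * data.exposure[:, None] * I[None, :]
        ll_pois = stats.poisson.logpmf(data.counts, lam).sum()
        assert ll == pytest.approx(ll_pois, abs=1e-6)

    def test_exposure_reparameterization_invariance(self, oryx_data):
        spec, data = oryx_data
        theta = np.array([-4.7, -0.031, 0.208, np.log(0.3), np.log(1.5)])
        ll = integrated_loglik(data, theta)
        c = 3.7
        data2 = type(data)(counts=data.counts, X=data.X,
                           exposure=data.exposure * c,
                           system_idx=data.system_idx,
                           n_systems=data.n_systems, cutpoints=data.cutpoints,
                           colnames=data.colnames,
                           transect_ids=data.transect_ids)
        theta2 = theta.copy()
        theta2[0] -= np.log(c)
        assert integrated_loglik(data2, theta2) == pytest.approx(ll, abs=1e-9)

    def test_node_doubling_stable_at_optimum(self, oryx_data, fitted_oryx):
        spec, data = oryx_data
        ll15 = integrated_loglik(data, fitted_oryx.theta, n_nodes=15)
        ll30 = integrated_loglik(data, fitted_oryx.theta, n_nodes=30)
        assert ll15 == pytest.approx(ll30, abs=1e-6)


@pytest.fixture(scope="module")
def fitted_oryx(oryx_data):
    spec, data = oryx_data
    return fit(data, spec, seed=0)


class TestFit:
    def test_converges_near_truth(self, fitted_oryx):
        assert fitted_oryx.converged
        # generator truth: beta0 -4.68, rock -0.031, richness 0.208
        assert fitted_oryx.beta[0] == pytest.approx(-4.68, abs=1.0)
        assert fitted_oryx.beta[1] == pytest.approx(-0.031, abs=0.03)
        assert fitted_oryx.beta[2] == pytest.approx(0.208, abs=0.15)
        assert 0.5 < fitted_oryx.sigma_det < 3.0

    def test_parameter_count_convention(self, default_survey, default_binned):
        """k = fixed effects + sigma_b + sigma_det: null 3, 1-cov 4,
        2-cov 5, interaction 6."""
        expected = {(): 3, ("rock_cover",): 4,
                    ("rock_cover", "richness"): 5}
        for terms, k in expected.items():
            assert ModelSpec(species="oryx", terms=terms).k == k
        inter = ModelSpec(species="oryx", terms=("rock_cover", "richness"),
                          interactions=(("rock_cover", "richness"),))
        assert inter.k == 6

    def test_nested_model_never_beats_superset(self, default_survey,
                                               default_binned, fitted_oryx):
        null = ModelSpec(species="oryx", terms=())
        data0 = build_model_data(default_binned, default_survey.transects,
                                 default_survey.covariates, null,
                                 default_survey.cutpoints)
        f0 = fit(data0, null, seed=0)
        assert f0.loglik <= fitted_oryx.loglik + 1e-6

    def test_all_zero_counts_rejected(self, default_survey, default_binned):
        spec = ModelSpec(species="oryx", terms=())
        data = build_model_data(default_binned, default_survey.transects,
                                default_survey.covariates, spec,
                                default_survey.cutpoints)
        data.counts[:] = 0.0
        with pytest.raises(ValueError, match="all counts zero"):
            fit(data, spec)

    def test_zero_variance_truth_hits_boundary(self):
        """Data simulated without system heterogeneity drives sigma_b to
        its floor and the fit flags the boundary."""
        import dataclasses
        from dungsight.synthetic import DEFAULT_SPECIES
        sc = SimulationScenario(seed=21)
        sc.species = {"oryx": dataclasses.replace(
            DEFAULT_SPECIES["oryx"], sigma_b=0.0, effects={})}
        ds = simulate_survey(sc)
        retained, _ = filter_middens(ds.events)
        binned = bin_distances(retained, ds.transects, ds.cutpoints)
        spec = ModelSpec(species="oryx", terms=())
        data = build_model_data(binned, ds.transects, ds.covariates, spec,
                                ds.cutpoints)
        f = fit(data, spec, seed=0)
        # near-zero: well below the heterogeneity a real system shows
        assert f.diagnostics["sigma_b_boundary"] or f.sigma_b < 0.15

    def test_fixed_detection_matches_offset_poisson_fit(self, default_survey,
                                                        default_binned):
        """With sigma_det held fixed, the model is a Poisson mixed model
        with offset log(2L I_k); an independent brute-force-integrated
        optimization lands on the same estimates."""
        spec = ModelSpec(species="oryx", terms=())
        data = build_model_data(default_binned, default_survey.transects,
                                default_survey.covariates, spec,
                                default_survey.cutpoints)
        f = fit(data, spec, sigma_det_fixed=1.5, seed=0)
        assert f.k == 2  # beta0 + sigma_b only

        def nll_bf(theta):
            return -brute_force_loglik(data, theta[:1], np.exp(theta[1]), 1.5,
                                       n_grid=4001)
        res = optimize.minimize(nll_bf, np.array([-4.0, np.log(0.4)]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert f.theta[0] == pytest.approx(res.x[0], abs=1e-4)
        assert f.theta[1] == pytest.approx(res.x[1], abs=1e-3)

    def test_standardization_is_affine_reparameterization(self, default_survey,
                                                          default_binned):
        """z-scoring covariates spans the same model space, so the
        maximized likelihood is unchanged and the slope rescales by the
        covariate SD."""
        spec = ModelSpec(species="oryx", terms=("rock_cover",))
        raw = build_model_data(default_binned, default_survey.transects,
                               default_survey.covariates, spec,
                               default_survey.cutpoints)
        std = build_model_data(default_binned, default_survey.transects,
                               default_survey.covariates, spec,
                               default_survey.cutpoints, standardize=True)
        f_raw = fit(raw, spec, seed=0)
        f_std = fit(std, spec, seed=0)
        assert f_std.loglik == pytest.approx(f_raw.loglik, abs=1e-5)
        sd = default_survey.covariates["rock_cover"].std(ddof=0)
        assert f_std.beta[1] == pytest.approx(f_raw.beta[1] * sd, rel=1e-3)

    def test_deterministic_given_seed(self, oryx_data):
        spec, data = oryx_data
        f1 = fit(data, spec, seed=4)
        f2 = fit(data, spec, seed=4)
        assert np.array_equal(f1.theta, f2.theta)


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-100.0, 3, 36) == pytest.approx(206.75)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10 ** 9) == pytest.approx(206.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-100.0, 3, 4)


class TestPredictDensity:
    def test_null_model_constant(self, default_survey, default_binned):
        spec = ModelSpec(species="oryx", terms=())
        data = build_model_data(default_binned, default_survey.transects,
                                default_survey.covariates, spec,
                                default_survey.cutpoints)
        f = fit(data, spec, seed=0)
        pred = predict_density(f, default_survey.covariates)
        assert pred["density_per_m2"].nunique() == 1

    def test_coefficient_scales_density_ratio(self, fitted_oryx,
                                              default_survey):
        """A unit richness difference multiplies density by exp(beta)."""
        cov = default_survey.covariates.iloc[:1].copy()
        cov5 = cov.copy(); cov5["richness"] = 5.0
        cov4 = cov.copy(); cov4["richness"] = 4.0
        d5 = predict_density(fitted_oryx, cov5)["density_per_m2"].iloc[0]
        d4 = predict_density(fitted_oryx, cov4)["density_per_m2"].iloc[0]
        beta_rich = fitted_oryx.beta[
            fitted_oryx.data.colnames.index("richness")]
        assert d5 / d4 == pytest.approx(np.exp(beta_rich), rel=1e-9)

    def test_marginal_conditional_lognormal_ratio(self, fitted_oryx,
                                                  default_survey):
        cov = default_survey.covariates.iloc[:3]
        m = predict_density(fitted_oryx, cov, marginal=True)["density_per_m2"]
        c = predict_density(fitted_oryx, cov, marginal=False)["density_per_m2"]
        np.testing.assert_allclose(
            (m / c).to_numpy(), np.exp(0.5 * fitted_oryx.sigma_b ** 2))

    def test_missing_covariate_raises(self, fitted_oryx, default_survey):
        cov = default_survey.covariates.drop(columns=["richness"]).iloc[:1]
        with pytest.raises(KeyError):
            predict_density(fitted_oryx, cov)
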