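"""Objectives, degrees of freedom, scenario masks and parameter encoding."""

import numpy as np
import pytest

from instmfa.estimate import (CAPPED_RAW, Dataset, ParameterSpace,
                              chi2_interval, degrees_of_freedom, fit,
                              scenario_a, scenario_b, scenario_c, vwss_content,
                              vwss_time)
from instmfa.simulate import PredictedContentSeries, default_observation_map


def _tiny_dataset():
    times = np.array([1.0, 2.0])
    mets = ("M",)
    z = np.array([[0.5], [0.3]])
    var = np.array([[0.01], [0.03]])
    return Dataset(times, mets, z, var, ("P",), np.array([100.0]),
                   np.array([10.0]))


class TestVWSS:
    def test_perfect_prediction_gives_zero(self):
        d = _tiny_dataset()
        pred = PredictedContentSeries(d.times, d.metabolites, d.z_obs.copy())
        assert vwss_time(pred, d) == 0.0

    def test_mean_variance_weighting(self):
        # obs (0.5, 0.3), pred (0.4, 0.2), variances (0.01, 0.03):
        # the metabolite-mean variance 0.02 weights both residuals
        d = _tiny_dataset()
        pred = PredictedContentSeries(d.times, d.metabolites,
                                      np.array([[0.4], [0.2]]))
        assert vwss_time(pred, d) == pytest.approx(1.0)

    def test_doubling_variances_halves_error(self):
        d = _tiny_dataset()
        d2 = Dataset(d.times, d.metabolites, d.z_obs, 2 * d.z_var,
                     d.content_pools, d.c_obs, d.c_sigma)
        pred = PredictedContentSeries(d.times, d.metabolites,
                                      np.array([[0.4], [0.2]]))
        assert vwss_time(pred, d2) == pytest.approx(vwss_time(pred, d) / 2)

    def test_grid_mismatch_rejected(self):
        d = _tiny_dataset()
        pred = PredictedContentSeries(d.times + 1, d.metabolites, d.z_obs)
        with pytest.raises(ValueError, match="grids differ"):
            vwss_time(pred, d)

    def test_content_error_single_pool(self):
        assert vwss_content(np.array([110.0]), np.array([100.0]),
                            np.array([10.0])) == pytest.approx(1.0)

    def test_content_error_zero_at_truth(self):
        c = np.array([3.0, 4.0])
        assert vwss_content(c, c, np.array([1.0, 1.0])) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            vwss_content(np.array([1.0]), np.array([1.0]), np.array([0.0]))


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("n_data,n_params,df",
                             [(98, 24, 73), (116, 42, 73), (10, 4, 5)])
    def test_convention(self, n_data, n_params, df):
        assert degrees_of_freedom(n_data, n_params) == df

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(5, 4)

    def test_chi2_interval_printed_values(self):
        assert tuple(round(v) for v in chi2_interval(73)) == (54, 94)
        assert tuple(round(v) for v in chi2_interval(59)) == (42, 78)

    def test_chi2_interval_df1(self):
        lo, hi = chi2_interval(1)
        assert lo == pytest.approx(0.0039, abs=5e-5)
        assert hi == pytest.approx(3.8415, abs=5e-5)


class TestScenarios:
    def test_scenario_a_has_24_free_parameters(self, noisefree_data):
        ds, _ = noisefree_data
        assert scenario_a(ds).n_free_parameters() == 24

    def test_scenario_b_has_42_free_parameters(self, noisefree_data):
        ds, _ = noisefree_data
        sc = scenario_b(ds)
        assert sc.n_free_parameters() == 42
        assert sc.objective == "vwss_all"
        for pool, mean, sd in zip(ds.content_pools, ds.c_obs, ds.c_sigma):
            lo, hi = sc.content_bounds[pool]
            assert lo == pytest.approx(max(1e-5, mean - 4 * sd))
            assert hi == pytest.approx(mean + 4 * sd)

    def test_scenario_c_masks(self, noisefree_data):
        ds, _ = noisefree_data
        sc = scenario_c(ds)
        assert set(ds.content_pools) - set(sc.free_contents) == \
            {"3PGA", "DHAP", "2PGA"}
        assert sc.fixed_exchange_raw == {"pga_dhap": CAPPED_RAW,
                                         "pga_2pga": CAPPED_RAW}
        assert sc.df_override == 59
        for lo, hi in sc.content_bounds.values():
            assert (lo, hi) == (1e-5, 4e4)

    def test_objective_decomposition(self, basis, noisefree_data):
        from instmfa.estimate import _Objective
        ds, rec = noisefree_data
        omap = default_observation_map(basis.network)
        obj = _Objective(scenario_b(ds), ds, basis, omap, rec.input_models)
        theta = obj.space.heuristic_start()
        vt, vc = obj.components(theta)
        assert obj(theta) == pytest.approx(vt + vc, rel=1e-12)
        res = obj.residuals(theta)
        assert np.sum(res ** 2) == pytest.approx(vt + vc, rel=1e-6)

    def test_encode_decode_roundtrip(self, basis, noisefree_data, table1_truth):
        ds, rec = noisefree_data
        omap = default_observation_map(basis.network)
        space = ParameterSpace(scenario_b(ds), ds, basis, omap)
        params = table1_truth.flux_parameters(basis)
        phi = {m: table1_truth.phi[m] for m in omap.free_phi_metabolites}
        theta = space.encode(params, phi, table1_truth.contents)
        p2, phi2, c2 = space.decode(theta)
        assert np.allclose(p2.net_weights, params.net_weights, rtol=1e-12)
        assert np.allclose(p2.exchange_raw, params.exchange_raw, atol=1e-12)
        assert phi2 == pytest.approx(phi)
        for k, v in table1_truth.contents.items():
            assert c2[k] == pytest.approx(v, rel=1e-9)


class TestFitSmallScale:
    def test_scenario_a_never_changes_contents(self, basis, noisefree_data):
        ds, rec = noisefree_data
        res = fit(scenario_a(ds), ds, basis, rec.input_models, restarts=1,
                  seed=0, maxfev=60, screen_maxfev=60, polish=False,
                  polish_rounds=0)
        for pool, c in zip(ds.content_pools, ds.c_obs):
            assert res.contents[pool] == c

    def test_scenario_c_keeps_pinned_contents(self, basis, noisefree_data):
        ds, rec = noisefree_data
        res = fit(scenario_c(ds), ds, basis, rec.input_models, restarts=1,
                  seed=0, maxfev=60, screen_maxfev=60, polish=False,
                  polish_rounds=0)
        for pool in ("3PGA", "DHAP", "2PGA"):
            assert res.contents[pool] == ds.contents_dict()[pool]
        raw = dict(zip(basis.exchange_reactions, res.params.exchange_raw))
        assert raw["pga_dhap"] == CAPPED_RAW
        assert raw["pga_2pga"] == CAPPED_RAW

    def test_mc_interval_width_vanishes_without_noise(self, basis,
                                                      noisefree_data):
        # with (near-)zero observation noise every bootstrap replicate sees
        # the same data, so the confidence intervals collapse onto the
        # optimum
        from instmfa.estimate import monte_carlo_ci
        ds, rec = noisefree_data
        tiny = Dataset(ds.times, ds.metabolites, ds.z_obs,
                       np.full_like(ds.z_var, 1e-16), ds.content_pools,
                       ds.c_obs, np.full_like(ds.c_sigma, 1e-12))
        res = fit(scenario_a(tiny), tiny, basis, rec.input_models,
                  restarts=1, seed=0, maxfev=80, screen_maxfev=80,
                  polish=False, polish_rounds=0)
        ci = monte_carlo_ci(res, tiny, basis, rec.input_models, replicates=3,
                            seed=1, restarts_per_replicate=1,
                            quantities=("mode_sucrose", "gross_fixation"),
                            fit_options={"maxfev": 40, "screen_maxfev": 40,
                                         "n_continue": 1, "polish_rounds": 0})
        for opt, lo, hi in ci.quantities.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-4 * max(abs(opt), 1))

    def test_restart_log_and_vwss_decomposition(self, basis, noisefree_data):
        ds, rec = noisefree_data
        res = fit(scenario_a(ds), ds, basis, rec.input_models, restarts=2,
                  seed=0, maxfev=60, screen_maxfev=40, polish=False,
                  polish_rounds=0)
        assert len(res.restart_log) == 2
        assert res.vwss_all == pytest.approx(res.vwss_t + res.vwss_c)
        assert res.df == 73
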