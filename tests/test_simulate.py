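"""Simulator oracles: closed forms, convolution solution, limits, invariances."""

import numpy as np
import pytest
from scipy.integrate import quad

from instmfa.label_transfer import InputModel
from instmfa.network import FluxParameters, flux_from_modes
from instmfa.simulate import (ActivePoolSizes, ODESystem, assemble_system,
                              default_observation_map, integrate, observe,
                              TrajectorySet)
from instmfa.synthetic_data import make_truth, build_input_models


def single_pool_system(k, forcing_model=None, p=1.0):
    n = 1
    F = np.array([k * p])
    forcing = []
    if forcing_model is not None:
        forcing = [(forcing_model, F.copy())]
    return ODESystem(("A",), np.array([p]), np.zeros((1, 1)), [], forcing, F)


class TestIntegrateOracles:
    def test_single_pool_closed_form(self):
        # h == 0: pure decay x(t) = exp(-k t)
        sys_ = single_pool_system(k=0.1)
        traj = integrate(sys_, np.array([10.0]))
        assert traj.values[0, 0] == pytest.approx(np.exp(-1), abs=5e-5)

    def test_zero_fluxes_keep_state_at_one(self):
        sys_ = ODESystem(("A", "B"), np.ones(2), np.zeros((2, 2)), [], [],
                         np.zeros(2))
        traj = integrate(sys_, np.array([100.0, 1000.0]))
        assert np.allclose(traj.values, 1.0)

    def test_two_pool_chain_matches_convolution_quadrature(self):
        # upstream pool A driven by y(t) = exp(-a t); downstream pool B fed
        # by A.  Oracle: x_B(t) = e^{-kB t} + kB int_0^t x_A(t-u) e^{-kB u} du
        # with the analytic x_A.
        a, kA, kB = 0.01, 0.05, 0.008
        pA, pB = 1.0, 1.0
        y = InputModel(1, 1.0, a, 0.0, 0.0)
        L = np.array([[0.0, 0.0], [kB * pB, 0.0]])
        F = np.array([kA * pA, kB * pB])
        sys_ = ODESystem(("A", "B"), np.array([pA, pB]), L, [],
                         [(y, np.array([kA * pA, 0.0]))], F)
        times = np.array([5.0, 30.0, 120.0, 600.0, 1800.0])
        traj = integrate(sys_, times, rtol=1e-10, atol=1e-12)

        def xA(t):
            return np.exp(-kA * t) + kA * (np.exp(-a * t) - np.exp(-kA * t)) / (kA - a)

        for i, t in enumerate(times):
            conv, _ = quad(lambda u: xA(t - u) * np.exp(-kB * u), 0, t,
                           limit=200, epsabs=1e-12)
            oracle = np.exp(-kB * t) + kB * conv
            assert abs(traj.values[i, 1] - oracle) < 1e-6

    def test_large_k_tracks_effective_production(self):
        y = InputModel(1, 1.0, 1e-3, 0.0, 0.0)
        sys_ = single_pool_system(k=1e3, forcing_model=y)
        times = np.array([1.0, 10.0, 100.0, 1000.0])
        traj = integrate(sys_, times)
        assert np.max(np.abs(traj.values[:, 0] - y(times))) < 1e-3

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            integrate(single_pool_system(0.1), np.array([10.0, 5.0]))


@pytest.fixture(scope="module")
def setup(basis, table1_truth):
    truth = table1_truth
    inputs = build_input_models(truth)
    omap = default_observation_map(basis.network, truth.phi)
    pools = ActivePoolSizes.from_contents(truth.contents, basis.network, omap)
    dist = flux_from_modes(truth.flux_parameters(basis), basis)
    return basis, truth, inputs, omap, pools, dist


class TestReferenceSystem:
    def test_carboxylation_forcing_coefficient(self, setup):
        # starch-only flux: carboxylation delivers 6 C to 3PGA per fixed C,
        # at unlabeled probability y3/2, so the y3 forcing coefficient is 3
        basis, truth, inputs, omap, pools, _ = setup
        dist = flux_from_modes(FluxParameters(np.array([1.0, 0, 0, 0]),
                                              np.zeros(7)), basis)
        sys_ = assemble_system(basis.network, dist, pools, inputs)
        i3pga = sys_.pool_ids.index("3PGA")
        coef = {m.size: c for m, c in sys_.forcing}
        assert coef[3][i3pga] == pytest.approx(3.0)

    def test_zero_pool_size_with_influx_rejected(self, setup):
        basis, truth, inputs, omap, pools, dist = setup
        broken = ActivePoolSizes(pools.pool_ids, pools.contents,
                                 pools.active * (pools.pool_ids != "Tre6P"))
        bad = ActivePoolSizes(pools.pool_ids, pools.contents,
                              np.where([p == "Tre6P" for p in pools.pool_ids],
                                       0.0, pools.active))
        with pytest.raises(ValueError, match="Tre6P"):
            assemble_system(basis.network, dist, bad, inputs)

    def test_bounds_over_random_parameter_draws(self, basis):
        rng = np.random.default_rng(7)
        inputs = build_input_models(make_truth(0, "table1_like"))
        grid = np.array([5., 60., 600., 3600.])
        for k in range(200):
            truth = make_truth(int(rng.integers(2 ** 31)), "random")
            omap = default_observation_map(basis.network, truth.phi)
            pools = ActivePoolSizes.from_contents(truth.contents,
                                                  basis.network, omap)
            dist = flux_from_modes(truth.flux_parameters(basis), basis)
            sys_ = assemble_system(basis.network, dist, pools, inputs)
            traj = integrate(sys_, grid, rtol=1e-6, atol=1e-8,
                             method="lsoda", clip=False)
            assert np.all(traj.values > -1e-6)
            assert np.all(traj.values < 1 + 1e-6)

    def test_delay_ordering_along_plastidic_chain(self, setup):
        basis, truth, inputs, omap, pools, dist = setup
        grid = np.geomspace(1, 3600, 200)
        traj = integrate(assemble_system(basis.network, dist, pools, inputs),
                         grid, method="lsoda")
        chain = ["DHAP", "FBPpl", "F6Ppl", "G6Ppl", "ADPG"]
        crossings = []
        for pid in chain:
            x = traj.pool(pid)
            below = np.nonzero(x < 0.5)[0]
            crossings.append(grid[below[0]] if below.size else np.inf)
        assert all(a <= b + 1e-9 for a, b in zip(crossings, crossings[1:]))

    def test_scale_invariance_of_trajectories(self, setup):
        # multiplying all fluxes and all pool sizes by one factor leaves the
        # unlabeled-fraction dynamics unchanged (only k_m = F/p matters)
        basis, truth, inputs, omap, pools, dist = setup
        grid = np.array([5., 60., 600., 3600.])
        sys1 = assemble_system(basis.network, dist, pools, inputs)
        w = np.array(truth.net_weights) * 7.3
        dist2 = flux_from_modes(
            FluxParameters(w, np.array([truth.exchange_raw[r]
                                        for r in basis.exchange_reactions])),
            basis, exchange_scale=7.3 * sum(truth.net_weights))
        pools2 = ActivePoolSizes(pools.pool_ids, pools.contents * 7.3,
                                 pools.active * 7.3)
        sys2 = assemble_system(basis.network, dist2, pools2, inputs)
        t1 = integrate(sys1, grid)
        t2 = integrate(sys2, grid)
        assert np.allclose(t1.values, t2.values, atol=1e-6)

    def test_rapid_equilibrium_acts_as_combined_pool(self):
        # high exchange between two pools merges them into one effective
        # pool of summed size
        v, E = 1.0, 1e3
        pA, pB = 30.0, 70.0
        y = InputModel(1, 1.0, 0.01, 0.0, 0.0)
        L = np.array([[0.0, E], [v + E, 0.0]])
        sys2 = ODESystem(("A", "B"), np.array([pA, pB]), L, [],
                         [(y, np.array([v, 0.0]))],
                         np.array([v + E, v + E]))
        sysc = single_pool_system(k=v / (pA + pB), forcing_model=y,
                                  p=pA + pB)
        grid = np.array([5., 50., 500., 3000.])
        t2 = integrate(sys2, grid, rtol=1e-9, atol=1e-11)
        tc = integrate(sysc, grid, rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(t2.values[:, 0] - t2.values[:, 1])) < 1e-3
        assert np.max(np.abs(t2.values[:, 0] - tc.values[:, 0])) < 1e-3


class TestObserve:
    def _traj(self, values, pools=("P1", "P2")):
        return TrajectorySet(np.array([0.0]), pools,
                             np.array([values], dtype=float))

    def _pools(self, ids, active):
        return ActivePoolSizes(tuple(ids), np.array(active, float),
                               np.array(active, float))

    def _map(self, pools_of, phi):
        from instmfa.simulate import ObservationMap
        mets = tuple(pools_of)
        return ObservationMap(mets, pools_of, phi,
                              {m: False for m in mets})

    def test_zero_phi_single_pool_identity(self):
        omap = self._map({"M": ("P1",)}, {"M": 0.0})
        z = observe(self._traj([0.42, 0.0]), self._pools(["P1", "P2"], [1, 1]),
                    omap)
        assert z.values[0, 0] == pytest.approx(0.42)

    def test_two_pool_mixture_with_inactive_fraction(self):
        omap = self._map({"M": ("P1", "P2")}, {"M": 0.5})
        z = observe(self._traj([0.4, 0.6]), self._pools(["P1", "P2"], [2, 2]),
                    omap)
        assert z.values[0, 0] == pytest.approx(0.75)

    def test_plateau_at_phi(self):
        omap = self._map({"M": ("P1",)}, {"M": 0.3})
        z = observe(self._traj([0.0, 0.0]), self._pools(["P1", "P2"], [1, 1]),
                    omap)
        assert z.values[0, 0] == pytest.approx(0.3)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            self._map({"M": ("P1",)}, {"M": 1.0})

    def test_reference_map_shape(self, network):
        omap = default_observation_map(network)
        assert len(omap.metabolites) == 14
        two_pool = {m for m in omap.metabolites
                    if len(omap.pools_of[m]) == 2}
        assert two_pool == {"FBP", "F6P", "G6P", "G1P"}
        assert len(omap.free_phi_metabolites) == 13
        assert omap.phi_fixed["Tre6P"]
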