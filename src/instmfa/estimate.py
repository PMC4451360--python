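"""Variance-weighted fitting of fluxes, inactive fractions and pool sizes.

Three fitting scenarios differ in how compartmentalized contents enter:

* Scenario A: contents fixed to the measured values; 11 flux parameters and
  13 free inactive fractions are fitted to the 98 time-course points by
  minimizing VWSS_t.
* Scenario B: the 18 contents are additionally optimized within measurement-
  derived bounds and the 18 content measurements join the data, so the
  objective is VWSS_all = VWSS_t + VWSS_c.
* Scenario C: 15 contents are free over a practically unbounded range while
  3PGA, DHAP and 2PGA stay at their measured values with the exchange fluxes
  among them pinned at the cap (the three pools act as one combined pool of
  fixed size, which normalizes the otherwise scale-invariant problem);
  objective VWSS_t.

Time-course residuals are weighted by the metabolite-mean variance rather
than the per-point variance, which guards against over-fitting single
points.  Optimization is multistart derivative-free local search (Powell or
Nelder-Mead through scipy, 100 repetitions by default, best kept);
confidence intervals come from a parametric Monte-Carlo bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import chi2

from .label_transfer import InputModel
from .network import (FluxDistribution, FluxModeBasis, FluxParameters,
                      NET_MODE_ORDER)
from .simulate import (ActivePoolSizes, ObservationMap, PredictedContentSeries,
                       assemble_system, default_observation_map, integrate,
                       observe)

__all__ = [
    "Dataset",
    "ScenarioSpec",
    "scenario_a",
    "scenario_b",
    "scenario_c",
    "FitResult",
    "ConfidenceReport",
    "vwss_time",
    "vwss_content",
    "degrees_of_freedom",
    "chi2_interval",
    "fit",
    "monte_carlo_ci",
]

#: raw exchange value used where a scenario pins an exchange flux at the cap
CAPPED_RAW = 0.999999


@dataclass(frozen=True)
class Dataset:
    """Observed labeling time courses and content measurements."""

    times: np.ndarray            # (T,) seconds
    metabolites: tuple[str, ...]
    z_obs: np.ndarray            # (T, M) unlabeled fractional contents
    z_var: np.ndarray            # (T, M) per-point variances
    content_pools: tuple[str, ...]
    c_obs: np.ndarray            # (P,) measured contents, nmol C gFW^-1
    c_sigma: np.ndarray          # (P,) standard deviations

    def __post_init__(self) -> None:
        if np.any(self.z_var <= 0) or np.any(self.c_sigma <= 0):
            raise ValueError("variances must be positive")
        if self.z_obs.shape != (self.times.size, len(self.metabolites)):
            raise ValueError("z_obs shape mismatch")

    @property
    def n_timecourse_points(self) -> int:
        return self.z_obs.size

    @property
    def metabolite_mean_var(self) -> np.ndarray:
        return self.z_var.mean(axis=0)

    def contents_dict(self) -> dict[str, float]:
        return dict(zip(self.content_pools, self.c_obs))


def vwss_time(pred: PredictedContentSeries, data: Dataset) -> float:
    """Time-course error, weighted by the metabolite-mean variance."""
    if pred.times.shape != data.times.shape or np.any(pred.times != data.times):
        raise ValueError("prediction and data time grids differ")
    if pred.metabolites != data.metabolites:
        raise ValueError("prediction and data metabolites differ")
    res = (data.z_obs - pred.values) ** 2 / data.metabolite_mean_var
    return float(res.sum())


def vwss_time_per_metabolite(pred: PredictedContentSeries,
                             data: Dataset) -> dict[str, float]:
    res = (data.z_obs - pred.values) ** 2 / data.metabolite_mean_var
    return dict(zip(data.metabolites, res.sum(axis=0)))


def vwss_content(c_sim: np.ndarray, c_obs: np.ndarray,
                 c_sigma: np.ndarray) -> float:
    """Content error: variance-weighted squared deviations."""
    c_sigma = np.asarray(c_sigma, float)
    if np.any(c_sigma <= 0):
        raise ValueError("content standard deviations must be positive")
    return float(np.sum((np.asarray(c_obs, float) - np.asarray(c_sim, float)) ** 2
                        / c_sigma ** 2))


def degrees_of_freedom(n_data: int, n_params: int) -> int:
    """df = n_data - n_params - 1."""
    df = n_data - n_params - 1
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({df})")
    return df


def chi2_interval(df: int) -> tuple[float, float]:
    """95%-confidence acceptance interval for the fit error.

    The (5th, 95th) percentiles of the chi-square distribution with ``df``
    degrees of freedom; a variance-weighted error outside this interval
    flags a statistically unacceptable fit.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    return tuple(chi2.ppf([0.05, 0.95], df))


# ---------------------------------------------------------------------------
# scenarios and the parameter space
# ---------------------------------------------------------------------------

WEIGHT_LOG10_BOUNDS = (-6.0, 3.0)
PHI_BOUNDS = (0.0, 0.95)
RAW_BOUNDS = (0.0, CAPPED_RAW)


@dataclass(frozen=True)
class ScenarioSpec:
    """Free/fixed parameter masks, bounds and objective for one scenario."""

    scenario_id: str
    objective: str                       # "vwss_t" or "vwss_all"
    free_contents: tuple[str, ...]
    content_bounds: dict[str, tuple[float, float]]
    fixed_exchange_raw: dict[str, float]  # reaction id -> raw value
    df_override: int | None = None
    #: contents pinned to a value other than the measurement (used by the
    #: perturb-and-reoptimize sensitivity analysis)
    fixed_content_overrides: dict[str, float] = field(default_factory=dict)

    def n_free_parameters(self, n_phi: int = 13) -> int:
        n_exch = 7 - len(self.fixed_exchange_raw)
        return 4 + n_exch + n_phi + len(self.free_contents)


def scenario_a(dataset: Dataset) -> ScenarioSpec:
    """Contents fixed to the measured values; objective VWSS_t."""
    return ScenarioSpec("A", "vwss_t", (), {}, {})


def scenario_b(dataset: Dataset, sigma_span: float = 4.0,
               eps: float = 1e-5) -> ScenarioSpec:
    """Contents free within mean +/- 4 sigma; objective VWSS_all."""
    bounds = {}
    for pool, mean, sd in zip(dataset.content_pools, dataset.c_obs,
                              dataset.c_sigma):
        bounds[pool] = (max(eps, mean - sigma_span * sd), mean + sigma_span * sd)
    return ScenarioSpec("B", "vwss_all", tuple(dataset.content_pools), bounds, {})


def scenario_c(dataset: Dataset, lo: float = 1e-5, hi: float = 4e4,
               df: int = 59) -> ScenarioSpec:
    """Contents practically unbounded; 3PGA/DHAP/2PGA pinned; objective VWSS_t.

    Only flux/pool-size ratios are identifiable in this setting; fixing the
    combined 3PGA-DHAP-2PGA pool (contents at measured values, mutual
    exchange at the cap) normalizes the scale.
    """
    fixed = ("3PGA", "DHAP", "2PGA")
    free = tuple(p for p in dataset.content_pools if p not in fixed)
    bounds = {p: (lo, hi) for p in free}
    return ScenarioSpec("C", "vwss_t", free, bounds,
                        {"pga_dhap": CAPPED_RAW, "pga_2pga": CAPPED_RAW},
                        df_override=df)


class ParameterSpace:
    """Flat optimizer vector <-> (FluxParameters, phi, contents).

    Net-mode weights and free contents are optimized in log10 space; raw
    exchange parameters and inactive fractions are linear.
    """

    def __init__(self, scenario: ScenarioSpec, dataset: Dataset,
                 basis: FluxModeBasis, obs_map: ObservationMap):
        self.scenario = scenario
        self.dataset = dataset
        self.basis = basis
        self.obs_map = obs_map
        self.free_exchange = tuple(r for r in basis.exchange_reactions
                                   if r not in scenario.fixed_exchange_raw)
        self.phi_names = obs_map.free_phi_metabolites
        self.bounds: list[tuple[float, float]] = []
        self.bounds += [WEIGHT_LOG10_BOUNDS] * 4
        self.bounds += [RAW_BOUNDS] * len(self.free_exchange)
        self.bounds += [PHI_BOUNDS] * len(self.phi_names)
        for p in scenario.free_contents:
            lo, hi = scenario.content_bounds[p]
            self.bounds.append((np.log10(lo), np.log10(hi)))
        self.n = len(self.bounds)

    def decode(self, theta: np.ndarray):
        theta = np.asarray(theta, float)
        k = 0
        w = 10.0 ** theta[k:k + 4]; k += 4
        ne = len(self.free_exchange)
        raw_free = theta[k:k + ne]; k += ne
        raw = np.empty(7)
        for i, rid in enumerate(self.basis.exchange_reactions):
            if rid in self.scenario.fixed_exchange_raw:
                raw[i] = self.scenario.fixed_exchange_raw[rid]
            else:
                raw[i] = raw_free[self.free_exchange.index(rid)]
        nphi = len(self.phi_names)
        phi = dict(zip(self.phi_names, theta[k:k + nphi])); k += nphi
        contents = self.dataset.contents_dict()
        contents.update(self.scenario.fixed_content_overrides)
        for p, v in zip(self.scenario.free_contents, theta[k:]):
            contents[p] = 10.0 ** v
        return FluxParameters(w, np.clip(raw, 0.0, CAPPED_RAW)), phi, contents

    def encode(self, params: FluxParameters, phi: dict[str, float],
               contents: dict[str, float]) -> np.ndarray:
        theta = list(np.log10(np.maximum(params.net_weights, 10 ** WEIGHT_LOG10_BOUNDS[0])))
        for rid in self.free_exchange:
            theta.append(params.exchange_raw[self.basis.exchange_reactions.index(rid)])
        theta += [phi[m] for m in self.phi_names]
        for p in self.scenario.free_contents:
            lo, hi = self.scenario.content_bounds[p]
            theta.append(np.log10(np.clip(contents[p], lo, hi)))
        return self.clip(np.array(theta))

    def clip(self, theta: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(theta, lo, hi)

    def random_start(self, rng: np.random.Generator,
                     weight_range=(1e-3, 1e2)) -> np.ndarray:
        """Draw a start: log-uniform weights, uniform raws and phis,
        log-uniform contents within bounds."""
        theta = []
        theta += list(rng.uniform(np.log10(weight_range[0]),
                                  np.log10(weight_range[1]), 4))
        theta += list(rng.uniform(0.0, 0.98, len(self.free_exchange)))
        theta += list(rng.uniform(0.0, PHI_BOUNDS[1], len(self.phi_names)))
        for p in self.scenario.free_contents:
            lo, hi = self.scenario.content_bounds[p]
            theta.append(rng.uniform(np.log10(lo), np.log10(hi)))
        return np.array(theta)

    def heuristic_start(self) -> np.ndarray:
        """Data-informed start: plateau-level inactive fractions, measured
        contents, mid-range fluxes."""
        d = self.dataset
        phi = {}
        for m in self.phi_names:
            j = d.metabolites.index(m)
            phi[m] = float(np.clip(d.z_obs[-1, j] * 0.9, 0.0, PHI_BOUNDS[1]))
        params = FluxParameters(np.array([1.0, 1.0, 0.01, 1.0]), np.full(7, 0.5))
        return self.encode(params, phi, d.contents_dict())


@dataclass
class FitResult:
    scenario: ScenarioSpec
    theta: np.ndarray
    params: FluxParameters
    phi: dict[str, float]
    contents: dict[str, float]
    vwss_t: float
    vwss_c: float
    vwss_all: float
    per_metabolite: dict[str, float]
    df: int
    derived: dict[str, float]
    restart_log: list[dict] = field(default_factory=list)
    n_restarts: int = 0
    seed: int | None = None

    @property
    def objective_value(self) -> float:
        return self.vwss_all if self.scenario.objective == "vwss_all" else self.vwss_t

    def chi2_acceptable(self) -> bool:
        lo, hi = chi2_interval(self.df)
        return lo <= self.objective_value <= hi


@dataclass
class ConfidenceReport:
    quantities: dict[str, tuple[float, float, float]]  # name -> (opt, lo, hi)
    replicates: int
    failed: int
    seed: int

    def contains(self, name: str, value: float) -> bool:
        opt, lo, hi = self.quantities[name]
        return lo <= value <= hi


class _Objective:
    """Callable scenario objective with penalty handling for failed solves."""

    PENALTY = 1e12

    def __init__(self, scenario: ScenarioSpec, dataset: Dataset,
                 basis: FluxModeBasis, obs_map: ObservationMap,
                 inputs: dict[int, InputModel], rtol: float = 1e-6,
                 atol: float = 1e-8, solver: str = "lsoda"):
        self.space = ParameterSpace(scenario, dataset, basis, obs_map)
        self.scenario = scenario
        self.dataset = dataset
        self.basis = basis
        self.obs_map = obs_map
        self.inputs = inputs
        self.rtol, self.atol, self.solver = rtol, atol, solver
        self.n_calls = 0
        self.any_success = False

    def predict(self, theta: np.ndarray):
        params, phi, contents = self.space.decode(theta)
        dist = flux_distribution(params, self.basis)
        omap = self.obs_map.with_phi(phi)
        pools = ActivePoolSizes.from_contents(contents, self.basis.network, omap)
        system = assemble_system(self.basis.network, dist, pools, self.inputs)
        traj = integrate(system, self.dataset.times, rtol=self.rtol,
                         atol=self.atol, method=self.solver)
        return observe(traj, pools, omap), contents

    def components(self, theta: np.ndarray) -> tuple[float, float]:
        pred, contents = self.predict(theta)
        vt = vwss_time(pred, self.dataset)
        c_sim = np.array([contents[p] for p in self.dataset.content_pools])
        vc = vwss_content(c_sim, self.dataset.c_obs, self.dataset.c_sigma)
        return vt, vc

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Variance-scaled residual vector; sum of squares = objective."""
        d = self.dataset
        try:
            pred, contents = self.predict(theta)
        except Exception:
            n = d.z_obs.size + (len(d.content_pools)
                                if self.scenario.objective == "vwss_all" else 0)
            return np.full(n, 1e6)
        rt = ((d.z_obs - pred.values)
              / np.sqrt(d.metabolite_mean_var)).ravel()
        if self.scenario.objective != "vwss_all":
            return rt
        c_sim = np.array([contents[p] for p in d.content_pools])
        rc = (d.c_obs - c_sim) / d.c_sigma
        return np.concatenate([rt, rc])

    def __call__(self, theta: np.ndarray) -> float:
        self.n_calls += 1
        try:
            vt, vc = self.components(theta)
        except Exception:
            return self.PENALTY
        val = vt + vc if self.scenario.objective == "vwss_all" else vt
        if not np.isfinite(val):
            return self.PENALTY
        self.any_success = True
        return val


def flux_distribution(params: FluxParameters,
                      basis: FluxModeBasis) -> FluxDistribution:
    from .network import flux_from_modes
    return flux_from_modes(params, basis)


def _derived_quantities(params: FluxParameters, basis: FluxModeBasis,
                        contents: dict[str, float],
                        phi: dict[str, float]) -> dict[str, float]:
    dist = flux_distribution(params, basis)
    gross = dist.gross_fixation
    out = {
        "gross_fixation": gross,
        "net_fixation": dist.net_fixation,
        "photorespiration_fraction": params.net_weights[3] / gross,
    }
    for label, w in zip(NET_MODE_ORDER, params.net_weights):
        out[f"mode_{label}"] = float(w)
        out[f"fraction_{label}"] = float(w / gross)
    for rid in basis.exchange_reactions:
        out[f"exchange_{rid}"] = dist.backward[rid]
    for m, v in phi.items():
        out[f"phi_{m}"] = float(v)
    for p, v in contents.items():
        out[f"content_{p}"] = float(v)
    return out


def _local_search(obj: _Objective, x0: np.ndarray, method: str,
                  maxfev: int, ftol: float):
    scipy_method = {"powell": "Powell", "nelder-mead": "Nelder-Mead"}[method]
    options = ({"maxfev": maxfev, "xtol": 1e-8, "ftol": ftol}
               if method == "powell"
               else {"maxfev": maxfev, "xatol": 1e-8, "fatol": ftol})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minimize(obj, x0, method=scipy_method, bounds=obj.space.bounds,
                        options=options)


def _leastsq_polish(obj: _Objective, x0: np.ndarray) -> tuple[np.ndarray, float]:
    """Bounded trust-region least-squares refinement of a candidate optimum."""
    lo = np.array([b[0] for b in obj.space.bounds])
    hi = np.array([b[1] for b in obj.space.bounds])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(obj.residuals, x0, bounds=(lo, hi),
                            x_scale="jac", ftol=1e-14, xtol=1e-12, gtol=1e-12,
                            max_nfev=400)
    return np.asarray(sol.x), float(2 * sol.cost)


def fit(scenario: ScenarioSpec, dataset: Dataset, basis: FluxModeBasis,
        inputs: dict[int, InputModel], obs_map: ObservationMap | None = None,
        restarts: int = 100, seed: int | None = None, method: str = "powell",
        maxfev: int = 4000, screen_maxfev: int = 700, n_continue: int = 3,
        polish: bool = True, polish_rounds: int = 3, ftol: float = 1e-9,
        initial_points: list[np.ndarray] | None = None,
        include_heuristic_start: bool = True,
        rtol: float = 1e-6, atol: float = 1e-8) -> FitResult:
    """Multistart derivative-free minimization of the scenario objective.

    ``restarts`` local searches are launched from user-supplied points, a
    data-informed heuristic start and random draws from the configured start
    distributions.  Each start gets a short screening search; the most
    promising candidates are continued with the full budget and the best is
    refined by repeated restarts plus a bounded least-squares polish of the
    residual vector.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    obs_map = obs_map or default_observation_map(basis.network)
    obj = _Objective(scenario, dataset, basis, obs_map, inputs, rtol, atol)
    space = obj.space
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = [space.clip(np.asarray(p, float))
                                for p in (initial_points or [])]
    if include_heuristic_start and len(starts) < restarts:
        starts.append(space.heuristic_start())
    while len(starts) < restarts:
        starts.append(space.random_start(rng))
    starts = starts[:restarts]

    log: list[dict] = []
    screened: list[tuple[float, np.ndarray]] = []
    for i, x0 in enumerate(starts):
        res = _local_search(obj, x0, method,
                            screen_maxfev if restarts > 1 else maxfev, ftol)
        log.append({"restart": i, "start_value": float(obj(x0)),
                    "final_value": float(res.fun), "nfev": int(res.nfev)})
        screened.append((float(res.fun), np.asarray(res.x)))
    screened.sort(key=lambda t: t[0])
    if not obj.any_success:
        raise RuntimeError(f"no restart converged; log: {log}")

    best_f, best_x = screened[0]
    for f0, x0 in screened[:max(1, n_continue)]:
        if f0 >= _Objective.PENALTY:
            continue
        if polish:
            x_ls, f_ls = _leastsq_polish(obj, x0)
            if f_ls < best_f:
                best_f, best_x = f_ls, x_ls
        elif f0 < best_f:
            best_f, best_x = f0, x0

    for _ in range(polish_rounds):
        improved = False
        res = _local_search(obj, best_x, method, maxfev, ftol)
        if res.fun < best_f - max(ftol, 1e-12 * abs(best_f)):
            best_f, best_x, improved = float(res.fun), np.asarray(res.x), True
        if polish:
            x_ls, f_ls = _leastsq_polish(obj, best_x)
            if f_ls < best_f - max(ftol, 1e-12 * abs(best_f)):
                best_f, best_x, improved = f_ls, x_ls, True
        if not improved:
            break

    params, phi, contents = space.decode(best_x)
    pred, _ = obj.predict(best_x)
    vt = vwss_time(pred, dataset)
    c_sim = np.array([contents[p] for p in dataset.content_pools])
    vc = vwss_content(c_sim, dataset.c_obs, dataset.c_sigma)
    n_data = dataset.n_timecourse_points
    if scenario.objective == "vwss_all":
        n_data += len(dataset.content_pools)
    df = (scenario.df_override if scenario.df_override is not None
          else degrees_of_freedom(n_data, space.n))
    return FitResult(
        scenario=scenario, theta=best_x, params=params, phi=phi,
        contents=contents, vwss_t=vt, vwss_c=vc, vwss_all=vt + vc,
        per_metabolite=vwss_time_per_metabolite(pred, dataset), df=df,
        derived=_derived_quantities(params, basis, contents, phi),
        restart_log=log, n_restarts=restarts, seed=seed)


def monte_carlo_ci(fit_result: FitResult, dataset: Dataset,
                   basis: FluxModeBasis, inputs: dict[int, InputModel],
                   replicates: int = 100, seed: int | None = None,
                   restarts_per_replicate: int = 5,
                   obs_map: ObservationMap | None = None,
                   quantities: tuple[str, ...] | None = None,
                   fit_options: dict | None = None) -> ConfidenceReport:
    """Parametric Monte-Carlo confidence intervals.

    Synthetic observations are drawn as model prediction at the optimum plus
    Gaussian noise with the observed variances, and each replicate is
    refitted (warm-started from the optimum plus random restarts).  The 95%
    interval is the pivotal (basic) bootstrap construction: the 2.5/97.5
    percentiles of the replicate deviations from the optimum are reflected
    about the optimum, which keeps nominal coverage when the estimator is
    biased or its error distribution skewed.  Replicate failures are
    excluded; more than 20% failures aborts.
    """
    obs_map = obs_map or default_observation_map(basis.network)
    obj = _Objective(fit_result.scenario, dataset, basis, obs_map, inputs)
    pred, contents = obj.predict(fit_result.theta)
    c_sim = np.array([contents[p] for p in dataset.content_pools])
    rng = np.random.default_rng(seed)
    names = quantities or tuple(fit_result.derived)

    samples: dict[str, list[float]] = {q: [] for q in names}
    failed = 0
    for _ in range(replicates):
        z_star = pred.values + rng.normal(0, np.sqrt(dataset.z_var))
        z_star = np.clip(z_star, 0.0, 1.0)
        c_star = np.maximum(c_sim + rng.normal(0, dataset.c_sigma), 1e-6)
        boot = Dataset(dataset.times, dataset.metabolites, z_star,
                       dataset.z_var, dataset.content_pools, c_star,
                       dataset.c_sigma)
        opts = {"maxfev": 1500, "screen_maxfev": 400, "n_continue": 1,
                "polish_rounds": 1}
        opts.update(fit_options or {})
        try:
            res = fit(fit_result.scenario, boot, basis, inputs, obs_map,
                      restarts=restarts_per_replicate,
                      seed=int(rng.integers(2 ** 31)),
                      initial_points=[fit_result.theta],
                      include_heuristic_start=False, **opts)
        except Exception:
            failed += 1
            continue
        for q in names:
            samples[q].append(res.derived[q])
    if failed > 0.2 * replicates:
        raise RuntimeError(f"{failed}/{replicates} Monte-Carlo replicates failed")

    quants = {}
    for q in names:
        arr = np.array(samples[q])
        opt = float(fit_result.derived[q])
        qlo, qhi = np.percentile(arr, [2.5, 97.5])
        quants[q] = (opt, float(2 * opt - qhi), float(2 * opt - qlo))
    return ConfidenceReport(quants, replicates - failed, failed,
                            seed if seed is not None else -1)
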