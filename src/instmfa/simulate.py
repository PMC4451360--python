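"""Unlabeled-fraction dynamics and the observation model.

Each simulated pool n obeys

    dx_n/dt = (1/p_n) * [ sum_r F^in_{r,n} h_{r,n}(t)  -  F_n x_n ]

where p_n is the active pool size, F^in_{r,n} the carbon influx through
reaction r, F_n the total turnover, and h_{r,n} the probability that a newly
made molecule is fully unlabeled: a product of unlabeled fractions of
simulated substrate pools, RuBP cumomer input models y_s(t), and a zero for
any CO2-derived carbon.  Condensations (aldolase, SPS, TPS, glycine
condensation) make the system bilinear; everything else is linear with
exponential forcing, so the right-hand side and its Jacobian are assembled
once as dense arrays and integrated with a stiff BDF method.

Observed metabolites are compartment mixtures: the unlabeled fractional
content is the active-pool-size-weighted mean of the contributing pools,
shifted by the metabolite's inactive fraction phi, z = (1-phi)*<x> + phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .label_transfer import InputModel
from .network import FluxDistribution, Network

__all__ = [
    "ActivePoolSizes",
    "ObservationMap",
    "default_observation_map",
    "ODESystem",
    "TrajectorySet",
    "PredictedContentSeries",
    "assemble_system",
    "integrate",
    "observe",
]


@dataclass(frozen=True)
class ObservationMap:
    """Observed metabolites -> contributing pools and inactive fractions."""

    metabolites: tuple[str, ...]
    pools_of: dict[str, tuple[str, ...]]
    phi: dict[str, float]
    phi_fixed: dict[str, bool]

    def __post_init__(self) -> None:
        for m, p in self.phi.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"inactive fraction of {m} outside [0, 1)")

    def with_phi(self, phi: dict[str, float]) -> "ObservationMap":
        new = dict(self.phi)
        new.update(phi)
        return ObservationMap(self.metabolites, self.pools_of, new, self.phi_fixed)

    @property
    def free_phi_metabolites(self) -> tuple[str, ...]:
        return tuple(m for m in self.metabolites if not self.phi_fixed[m])


def default_observation_map(network: Network,
                            phi: dict[str, float] | None = None) -> ObservationMap:
    """The reference map: 14 observed metabolites from 18 simulated pools.

    FBP, F6P, G6P and G1P are measured as plastid+cytosol mixtures;
    compartment twins share a single inactive fraction.  The inactive
    fraction of Tre6P (the observed intermediate of the trehalose branch,
    which shows no plateau) is fixed to zero.
    """
    pools_of: dict[str, list[str]] = {}
    for p in network.simulated_pools:
        pools_of.setdefault(p.metabolite, []).append(p.id)
    metabolites = tuple(pools_of)
    phi = dict(phi or {})
    phi_full = {m: phi.get(m, 0.0) for m in metabolites}
    phi_fixed = {m: (m == "Tre6P") for m in metabolites}
    phi_full["Tre6P"] = 0.0
    return ObservationMap(metabolites,
                          {m: tuple(v) for m, v in pools_of.items()},
                          phi_full, phi_fixed)


@dataclass(frozen=True)
class ActivePoolSizes:
    """Compartmentalized contents and the derived active pool sizes.

    The measured content c_n of pool n (nmol C gFW^-1) splits into an active
    part p_n = c_n * (1 - phi_m) that participates in labeling and an
    inactive remainder, where phi_m is the inactive fraction of n's
    metabolite (shared between compartment twins).
    """

    pool_ids: tuple[str, ...]
    contents: np.ndarray   # c_n
    active: np.ndarray     # p_n

    @classmethod
    def from_contents(cls, contents: dict[str, float], network: Network,
                      obs_map: ObservationMap) -> "ActivePoolSizes":
        pids = tuple(p.id for p in network.simulated_pools)
        phi_of_pool = {}
        for m in obs_map.metabolites:
            for pid in obs_map.pools_of[m]:
                phi_of_pool[pid] = obs_map.phi[m]
        c = np.array([contents[p] for p in pids], float)
        if np.any(c <= 0):
            bad = [p for p, v in zip(pids, c) if v <= 0]
            raise ValueError(f"nonpositive contents for pools {bad}")
        act = c * (1.0 - np.array([phi_of_pool[p] for p in pids]))
        return cls(pids, c, act)

    def index(self, pid: str) -> int:
        return self.pool_ids.index(pid)


@dataclass
class ODESystem:
    """Dense arrays for the bilinear labeling ODE system."""

    pool_ids: tuple[str, ...]
    p: np.ndarray                 # active pool sizes (n,)
    L: np.ndarray                 # linear influx matrix (n, n)
    bil: list[tuple[int, int, int, float]]  # (target, i, j, flux*coeff)
    forcing: list[tuple[InputModel, np.ndarray]]  # (y_s model, coeff vector)
    F: np.ndarray                 # total turnover per pool (n,)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        infl = self.L @ x
        for tgt, i, j, c in self.bil:
            infl[tgt] += c * x[i] * x[j]
        for model, coef in self.forcing:
            infl += coef * (model.A * np.exp(-model.a * t)
                            + model.B * np.exp(-model.b * t))
        return (infl - self.F * x) / self.p

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        J = self.L.copy()
        for tgt, i, j, c in self.bil:
            J[tgt, i] += c * x[j]
            J[tgt, j] += c * x[i]
        J[np.diag_indices_from(J)] -= self.F
        return J / self.p[:, None]

    def h_eff(self, t: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Effective unlabeled-production fraction per pool at states x(t)."""
        out = np.empty_like(x)
        for k, (tk, xk) in enumerate(zip(t, x)):
            infl = self.L @ xk
            for tgt, i, j, c in self.bil:
                infl[tgt] += c * xk[i] * xk[j]
            for model, coef in self.forcing:
                infl += coef * float(model(tk))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[k] = np.where(self.F > 0, infl / self.F, xk)
        return out


def assemble_system(network: Network, flux: FluxDistribution,
                    pools: ActivePoolSizes,
                    inputs: dict[int, InputModel]) -> ODESystem:
    """Build the ODE right-hand side from a steady-state flux distribution."""
    pids = pools.pool_ids
    n = len(pids)
    idx = {p: i for i, p in enumerate(pids)}
    L = np.zeros((n, n))
    bil: list[tuple[int, int, int, float]] = []
    force_coef: dict[int, np.ndarray] = {}
    F = np.zeros(n)
    for pid in pids:
        i = idx[pid]
        F[i] = flux.turnover[pid]
        if F[i] > 0 and pools.active[i] <= 0:
            raise ValueError(f"pool {pid} has influx but zero active size")
        for term in flux.influxes[pid]:
            h = term.h
            c = term.flux * h.coeff
            if c == 0.0:
                continue
            for s in h.input_sizes:
                if s not in inputs:
                    raise KeyError(f"no input model for RuBP cumomer size {s}")
            npf = len(h.pool_factors)
            if h.input_sizes:
                if npf:
                    raise NotImplementedError(
                        "mixed pool/input unlabeled-production rules not used "
                        "by the reference network")
                if len(h.input_sizes) != 1:
                    raise NotImplementedError("single input factor expected")
                s = h.input_sizes[0]
                force_coef.setdefault(s, np.zeros(n))[i] += c
            elif npf == 1:
                L[i, idx[h.pool_factors[0]]] += c
            elif npf == 2:
                bil.append((i, idx[h.pool_factors[0]], idx[h.pool_factors[1]], c))
            elif npf == 0:
                # constant unlabeled production (not used; CO2 sources carry 0)
                force_coef.setdefault(0, np.zeros(n))[i] += c
            else:
                raise NotImplementedError("h-rules with >2 pool factors")
    forcing = []
    for s, coef in force_coef.items():
        if s == 0:
            forcing.append((InputModel(0, 1.0, 0.0, 0.0, 0.0), coef))
        else:
            forcing.append((inputs[s], coef))
    return ODESystem(pids, pools.active.copy(), L, bil, forcing, F)


@dataclass(frozen=True)
class TrajectorySet:
    times: np.ndarray
    pool_ids: tuple[str, ...]
    values: np.ndarray  # (T, n) unlabeled fractions

    def pool(self, pid: str) -> np.ndarray:
        return self.values[:, self.pool_ids.index(pid)]


@dataclass(frozen=True)
class PredictedContentSeries:
    times: np.ndarray
    metabolites: tuple[str, ...]
    values: np.ndarray  # (T, m) unlabeled fractional contents

    def metabolite(self, m: str) -> np.ndarray:
        return self.values[:, self.metabolites.index(m)]


def integrate(system: ODESystem, times, rtol: float = 1e-8,
              atol: float = 1e-10, clip: bool = True,
              method: str = "BDF") -> TrajectorySet:
    """Integrate from the fully unlabeled state x(0) = 1 to the given times.

    Implicit multistep methods with the analytic Jacobian: ``method="BDF"``
    (default, scipy's BDF) or ``"lsoda"`` (the Fortran LSODA stiff path,
    several-fold faster at fitting-level tolerances).  Values are clipped to
    [0, 1] only in the returned set, never inside the solver.
    """
    times = np.asarray(times, float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be a sorted nonnegative grid")
    x0 = np.ones(len(system.pool_ids))
    t_eval = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    if method == "lsoda":
        y = odeint(system.rhs, x0, t_eval, Dfun=system.jac, tfirst=True,
                   rtol=rtol, atol=atol, mxstep=200000)
    else:
        sol = solve_ivp(system.rhs, (0.0, float(t_eval[-1])), x0, method=method,
                        t_eval=t_eval, jac=system.jac, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y.T
    if np.any(~np.isfinite(y)):
        raise RuntimeError("non-finite state encountered during integration")
    if times[0] != 0.0:
        y = y[1:]
    if clip:
        y = np.clip(y, 0.0, 1.0)
    return TrajectorySet(times, system.pool_ids, y)


def observe(traj: TrajectorySet, pools: ActivePoolSizes,
            obs_map: ObservationMap) -> PredictedContentSeries:
    """Compartment mixing and inactive-fraction offset.

    Single-pool metabolites: z = (1-phi) x + phi.  Two-pool metabolites: the
    active-pool-size-weighted mean of the compartment trajectories, then the
    same offset.
    """
    cols = []
    for m in obs_map.metabolites:
        phi = obs_map.phi[m]
        pids = obs_map.pools_of[m]
        w = np.array([pools.active[pools.index(p)] for p in pids])
        xs = np.stack([traj.pool(p) for p in pids], axis=1)
        mix = xs @ (w / w.sum())
        cols.append((1.0 - phi) * mix + phi)
    return PredictedContentSeries(traj.times, obs_map.metabolites,
                                  np.stack(cols, axis=1))
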