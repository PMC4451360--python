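"""Perturb-and-reoptimize sensitivity of flux estimates to pool sizes.

For a selected compartmentalized content, the optimum value is scaled over a
grid of multipliers (50% ... 150%, excluding 100%), the content is held
fixed at each level while all remaining parameters are re-optimized
(warm-started from the unperturbed optimum), and an ordinary least-squares
line through (relative content change, relative response change) yields the
sensitivity.  Responses whose correlation with the perturbation is weak
(|r| < 0.5) are reported as zero — such regressions reflect re-optimization
noise rather than a systematic dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimate import Dataset, FitResult, ScenarioSpec, fit
from .label_transfer import InputModel
from .network import FluxModeBasis
from .simulate import ObservationMap

__all__ = [
    "PERTURBATION_GRID",
    "SensitivityRecord",
    "perturbation_grid",
    "regress_sensitivity",
    "local_sensitivity",
    "sensitivity_matrix",
]

PERTURBATION_GRID = (0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 0.99,
                     1.01, 1.05, 1.10, 1.20, 1.30, 1.40, 1.50)

#: quantities selectable as sensitivity responses (keys of FitResult.derived)
DEFAULT_QUANTITIES = ("mode_starch", "mode_sucrose", "mode_trehalose",
                      "mode_photorespiration", "vwss_t")

R_THRESHOLD = 0.5


def regress_sensitivity(rel_change: np.ndarray,
                        rel_response: np.ndarray) -> tuple[float, float, float]:
    """(slope, r, reported sensitivity) of the response regression.

    Ordinary least squares with free intercept; the reported sensitivity is
    the slope when |r| >= 0.5 and zero otherwise.
    """
    x = np.asarray(rel_change, float)
    y = np.asarray(rel_response, float)
    if x.size < 2 or not np.all(np.isfinite(y)) or np.ptp(y) == 0:
        return 0.0, 0.0, 0.0
    slope, _ = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    sens = float(slope) if abs(r) >= R_THRESHOLD else 0.0
    return float(slope), r, sens


def perturbation_grid() -> tuple[float, ...]:
    """The canonical multipliers: 50-150% of the optimum, 100% excluded."""
    return PERTURBATION_GRID


@dataclass(frozen=True)
class SensitivityRecord:
    pool: str
    quantity: str
    levels: tuple[float, ...]
    responses: tuple[float, ...]   # relative change of the quantity per level
    slope: float
    r: float
    sensitivity: float             # slope if |r| >= 0.5 else 0
    dropped_levels: tuple[float, ...] = ()


def _response_value(res: FitResult, quantity: str) -> float:
    if quantity == "vwss_t":
        return res.vwss_t
    return res.derived[quantity]


def _fix_content(scenario: ScenarioSpec, pool: str,
                 value: float) -> ScenarioSpec:
    free = tuple(p for p in scenario.free_contents if p != pool)
    bounds = {p: b for p, b in scenario.content_bounds.items() if p != pool}
    overrides = dict(scenario.fixed_content_overrides)
    overrides[pool] = value
    return replace(scenario, free_contents=free, content_bounds=bounds,
                   fixed_content_overrides=overrides)


def local_sensitivity(fit_result: FitResult, dataset: Dataset,
                      basis: FluxModeBasis, inputs: dict[int, InputModel],
                      pool: str, quantity: str,
                      levels: tuple[float, ...] | None = None,
                      obs_map: ObservationMap | None = None,
                      restarts: int = 3, seed: int | None = None,
                      fit_options: dict | None = None) -> SensitivityRecord:
    """Sensitivity of one quantity to one optimized content."""
    scenario = fit_result.scenario
    if pool not in scenario.free_contents:
        raise ValueError(f"content {pool} is not optimized in scenario "
                         f"{scenario.scenario_id}")
    levels = tuple(levels if levels is not None else PERTURBATION_GRID)
    if not set(levels) <= set(PERTURBATION_GRID):
        raise ValueError("levels must be a subset of the canonical grid")
    c_opt = fit_result.contents[pool]
    q_opt = _response_value(fit_result, quantity)
    rng = np.random.default_rng(seed)
    opts = {"maxfev": 1500, "screen_maxfev": 400, "n_continue": 1,
            "polish_rounds": 1}
    opts.update(fit_options or {})

    used, resp, dropped = [], [], []
    for lv in levels:
        fixed_value = lv * c_opt
        sub = _fix_content(scenario, pool, fixed_value)
        try:
            res = fit(sub, dataset, basis, inputs, obs_map,
                      restarts=restarts, seed=int(rng.integers(2 ** 31)),
                      initial_points=[_drop_param(fit_result, basis, sub,
                                                  dataset, obs_map)],
                      include_heuristic_start=True, **opts)
        except Exception:
            dropped.append(lv)
            continue
        used.append(lv - 1.0)
        q = _response_value(res, quantity)
        resp.append((q - q_opt) / q_opt if q_opt != 0 else np.nan)
    if len(dropped) > len(levels) / 2:
        raise RuntimeError(f"re-optimization failed at {len(dropped)} of "
                           f"{len(levels)} levels for {pool}")

    x, y = np.array(used), np.array(resp)
    slope, r, sens = regress_sensitivity(x, y)
    return SensitivityRecord(pool, quantity, tuple(lv + 1.0 for lv in used),
                             tuple(y), float(slope), r, sens, tuple(dropped))


def _drop_param(fit_result: FitResult, basis, sub_scenario, dataset,
                obs_map) -> np.ndarray:
    """Warm start for the reduced parameter space (perturbed content removed)."""
    from .estimate import ParameterSpace
    from .simulate import default_observation_map
    obs_map = obs_map or default_observation_map(basis.network)
    space = ParameterSpace(sub_scenario, dataset, basis, obs_map)
    contents = dict(fit_result.contents)
    return space.encode(fit_result.params, fit_result.phi, contents)


def sensitivity_matrix(fit_result: FitResult, dataset: Dataset,
                       basis: FluxModeBasis, inputs: dict[int, InputModel],
                       pools: tuple[str, ...] | None = None,
                       quantities: tuple[str, ...] = DEFAULT_QUANTITIES,
                       levels: tuple[float, ...] | None = None,
                       obs_map: ObservationMap | None = None,
                       seed: int | None = None,
                       **kwargs) -> pd.DataFrame:
    """Full pool x quantity sensitivity table (heatmap-ready).

    Contents fixed by the scenario are skipped with a notice row.
    """
    scenario = fit_result.scenario
    pools = pools or tuple(dataset.content_pools)
    rng = np.random.default_rng(seed)
    rows = []
    for pool in pools:
        if pool not in scenario.free_contents:
            rows.append({"pool": pool, "quantity": None, "slope": np.nan,
                         "r": np.nan, "sensitivity": np.nan,
                         "note": "content fixed by scenario; skipped"})
            continue
        for q in quantities:
            rec = local_sensitivity(fit_result, dataset, basis, inputs, pool,
                                    q, levels, obs_map,
                                    seed=int(rng.integers(2 ** 31)), **kwargs)
            rows.append({"pool": pool, "quantity": q, "slope": rec.slope,
                         "r": rec.r, "sensitivity": rec.sensitivity,
                         "note": ""})
    return pd.DataFrame(rows)


def sensitivity_heatmap(table: pd.DataFrame, path: str) -> None:
    """Render the sensitivity table as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    piv = (table.dropna(subset=["quantity"])
           .pivot(index="quantity", columns="pool", values="sensitivity"))
    fig, ax = plt.subplots(figsize=(1 + 0.6 * piv.shape[1],
                                    1 + 0.5 * piv.shape[0]))
    vmax = np.nanmax(np.abs(piv.values)) or 1.0
    im = ax.imshow(piv.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=90)
    ax.set_yticks(range(piv.shape[0]), piv.index)
    fig.colorbar(im, ax=ax, label="sensitivity (slope)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
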