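"""File formats: dataset CSVs, input-model JSON, flux reports, run config.

CSV dialects
------------
time-course:  metabolite, time_s, value, variance
contents:     pool, mean, std
RuBP:         time_s, m0 .. m5
flux report:  reaction/quantity, net, forward, backward, units
              (capped exchange fluxes are printed as "Inf.")
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimate import ConfidenceReport, Dataset, FitResult, chi2_interval
from .label_transfer import InputModel, MassIsotopomerSeries
from .network import FluxDistribution, NET_MODE_ORDER, Network

__all__ = [
    "RunConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_contents_csv",
    "write_contents_csv",
    "read_rubp_csv",
    "write_rubp_csv",
    "read_dataset",
    "write_dataset",
    "input_models_to_json",
    "input_models_from_json",
    "flux_table",
    "fit_report",
    "write_network_model",
]


@dataclass
class RunConfig:
    """Paths, scenario and solver/optimizer settings for one pipeline run."""

    timecourse_csv: str = "timecourse.csv"
    contents_csv: str = "contents.csv"
    rubp_csv: str = "rubp.csv"
    input_models_json: str | None = None
    scenario: str = "A"
    restarts: int = 100
    seed: int = 0
    mc_replicates: int = 100
    rtol: float = 1e-6
    atol: float = 1e-8
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise ValueError(f"scenario must be A, B or C, got {self.scenario}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_timecourse_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a labeling time-course CSV.

    Required columns: metabolite, time_s, value, variance.  Duplicate
    (metabolite, time) pairs and nonpositive variances are rejected with the
    offending rows named.
    """
    df = pd.read_csv(path)
    required = {"metabolite", "time_s", "value", "variance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_s", "value", "variance"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in column {col}")
    bad = df[df.variance <= 0]
    if len(bad):
        raise ValueError(f"{path}: nonpositive variance in rows "
                         f"{bad.index.tolist()}")
    dup = df.duplicated(subset=["metabolite", "time_s"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (metabolite, time) rows "
                         f"{df.index[dup].tolist()}")
    return df


def write_timecourse_csv(dataset: Dataset, path: str | Path) -> None:
    rows = []
    for j, m in enumerate(dataset.metabolites):
        for i, t in enumerate(dataset.times):
            rows.append({"metabolite": m, "time_s": t,
                         "value": dataset.z_obs[i, j],
                         "variance": dataset.z_var[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contents_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pool", "mean", "std"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["std"] <= 0).any():
        raise ValueError(f"{path}: nonpositive std")
    return df


def write_contents_csv(dataset: Dataset, path: str | Path) -> None:
    pd.DataFrame({"pool": dataset.content_pools, "mean": dataset.c_obs,
                  "std": dataset.c_sigma}).to_csv(path, index=False)


def read_rubp_csv(path: str | Path) -> MassIsotopomerSeries:
    df = pd.read_csv(path)
    mcols = [c for c in df.columns if c.startswith("m")]
    return MassIsotopomerSeries(df["time_s"].to_numpy(),
                                df[mcols].to_numpy())


def write_rubp_csv(series: MassIsotopomerSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.fractions,
                      columns=[f"m{i}" for i in range(series.n_carbons + 1)])
    df.insert(0, "time_s", series.times)
    df.to_csv(path, index=False)


def read_dataset(timecourse_path: str | Path,
                 contents_path: str | Path) -> Dataset:
    tc = read_timecourse_csv(timecourse_path)
    co = read_contents_csv(contents_path)
    times = np.sort(tc["time_s"].unique())
    metabolites = tuple(dict.fromkeys(tc["metabolite"]))
    z = tc.pivot(index="time_s", columns="metabolite", values="value")
    v = tc.pivot(index="time_s", columns="metabolite", values="variance")
    z = z.reindex(index=times, columns=list(metabolites))
    v = v.reindex(index=times, columns=list(metabolites))
    if z.isna().any().any():
        raise ValueError("time-course grid is not complete")
    return Dataset(times, metabolites, z.to_numpy(), v.to_numpy(),
                   tuple(co["pool"]), co["mean"].to_numpy(),
                   co["std"].to_numpy())


def write_dataset(dataset: Dataset, timecourse_path: str | Path,
                  contents_path: str | Path) -> None:
    write_timecourse_csv(dataset, timecourse_path)
    write_contents_csv(dataset, contents_path)


def input_models_to_json(models: dict[int, InputModel],
                         path: str | Path) -> None:
    data = [{"size": m.size, "A": m.A, "a": m.a, "B": m.B, "b": m.b,
             "residual": m.residual} for m in models.values()]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def input_models_from_json(path: str | Path) -> dict[int, InputModel]:
    with open(path) as fh:
        data = json.load(fh)
    return {d["size"]: InputModel(d["size"], d["A"], d["a"], d["B"], d["b"],
                                  d.get("residual", 0.0)) for d in data}


def flux_table(dist: FluxDistribution) -> pd.DataFrame:
    """Per-reaction net/forward/backward fluxes; capped exchange as "Inf."."""
    rows = []
    for rid in dist.basis.reaction_ids:
        bwd = "Inf." if dist.exchange_capped[rid] else f"{dist.backward[rid]:.6g}"
        fwd = "Inf." if dist.exchange_capped[rid] else f"{dist.forward[rid]:.6g}"
        rows.append({"reaction": rid, "net": f"{dist.net[rid]:.6g}",
                     "forward": fwd, "backward": bwd,
                     "units": "nmol C gFW-1 s-1"})
    rows.append({"reaction": "gross_C_fixation",
                 "net": f"{dist.gross_fixation:.6g}", "forward": "",
                 "backward": "", "units": "nmol C gFW-1 s-1"})
    rows.append({"reaction": "net_C_fixation",
                 "net": f"{dist.net_fixation:.6g}", "forward": "",
                 "backward": "", "units": "nmol C gFW-1 s-1"})
    return pd.DataFrame(rows)


def fit_report(result: FitResult, out_dir: str | Path,
               ci: ConfidenceReport | None = None) -> dict:
    """Write JSON + CSV artifacts for a fit and return the JSON payload."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = chi2_interval(result.df)
    payload = {
        "scenario": result.scenario.scenario_id,
        "objective": result.scenario.objective,
        "vwss_t": result.vwss_t,
        "vwss_c": result.vwss_c,
        "vwss_all": result.vwss_all,
        "df": result.df,
        "chi2_interval": [lo, hi],
        "chi2_acceptable": bool(result.chi2_acceptable()),
        "n_restarts": result.n_restarts,
        "seed": result.seed,
        "derived": result.derived,
        "per_metabolite_vwss_t": result.per_metabolite,
        "restart_log": result.restart_log,
    }
    with open(out / "fit.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)

    from .estimate import flux_distribution
    basis_dist = flux_distribution(result.params, _basis_of(result))
    flux_table(basis_dist).to_csv(out / "fluxes.csv", index=False)
    fractions = pd.DataFrame(
        {"mode": NET_MODE_ORDER,
         "flux": [result.derived[f"mode_{m}"] for m in NET_MODE_ORDER],
         "fraction_of_gross_fixation":
             [result.derived[f"fraction_{m}"] for m in NET_MODE_ORDER]})
    fractions.to_csv(out / "mode_fractions.csv", index=False)
    if ci is not None:
        rows = [{"quantity": q, "opt": o, "lower": l, "upper": u}
                for q, (o, l, u) in ci.quantities.items()]
        pd.DataFrame(rows).to_csv(out / "confidence_intervals.csv", index=False)
    return payload


def _basis_of(result: FitResult):
    from .network import build_flux_mode_basis
    return build_flux_mode_basis()


def write_network_model(network: Network, path: str | Path) -> None:
    """Serialize the network as a structured text model file."""
    lines = ["[pools]"]
    for p in network.pools:
        lines.append(f"{p.id}\tmetabolite={p.metabolite}\t"
                     f"compartment={p.compartment}\tcarbons={p.carbons}\t"
                     f"simulated={int(p.simulated)}")
    lines.append("")
    lines.append("[reactions]")
    for r in network.reactions:
        subs = " + ".join(f"{s:.4g} {p}" for p, s in r.substrates)
        prods = " + ".join(f"{s:.4g} {p}" for p, s in r.products)
        arrow = "<=>" if r.reversible else "->"
        rel = f" + {r.co2_release_share:.4g} CO2(released)" \
            if r.co2_release_share else ""
        lines.append(f"{r.id}\t{subs} {arrow} {prods}{rel}")
    Path(path).write_text("\n".join(lines) + "\n")
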