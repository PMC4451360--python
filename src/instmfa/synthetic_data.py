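"""Synthetic ground truths and datasets for the full pipeline.

The generator emulates the structure of a 13CO2 pulse-labeling experiment on
photoautotrophic rosette tissue: 14 observed metabolites (four of them
plastid/cytosol mixtures) sampled at 7 time points between 5 s and 60 min,
unlabeled fractional contents decaying toward metabolite-specific plateaus
set by inactive fractions, RuBP labeling following a per-carbon binomial
model, and Gaussian measurement noise.  Compartmentalized content
"measurements" come with realistic means and standard deviations
(REFERENCE_CONTENTS, nmol C gFW^-1).

Every dataset is produced by running the same network -> simulate -> observe
chain that the estimator inverts, so noise-free generation followed by a
Scenario A fit is an exact round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import ConfidenceReport, Dataset, FitResult
from .label_transfer import (InputModel, MassIsotopomerSeries,
                             cumomers_from_mass_isotopomers, fit_input_model,
                             RUBP_CARBONS)
from .network import (FluxModeBasis, FluxParameters, NET_MODE_ORDER,
                      build_flux_mode_basis, build_reference_network,
                      flux_from_modes)
from .simulate import (ActivePoolSizes, ObservationMap, assemble_system,
                       default_observation_map, integrate, observe)

__all__ = [
    "REFERENCE_TIME_GRID",
    "REFERENCE_CONTENTS",
    "DEFAULT_INACTIVE_FRACTIONS",
    "GroundTruth",
    "SyntheticRecord",
    "make_truth",
    "simulate_rubp_labeling",
    "build_input_models",
    "make_dataset",
    "recovery_report",
]

#: sampling grid: 5 s, 10 s, 1, 3, 10, 20 and 60 min
REFERENCE_TIME_GRID = np.array([5.0, 10.0, 60.0, 180.0, 600.0, 1200.0, 3600.0])

#: measured compartmentalized contents (mean, std) in nmol C gFW^-1
REFERENCE_CONTENTS: dict[str, tuple[float, float]] = {
    "3PGA": (600.3, 135.0),
    "DHAP": (47.6, 1.8),
    "FBPpl": (37.5, 9.7),
    "F6Ppl": (176.2, 29.8),
    "G6Ppl": (176.4, 52.0),
    "G1Ppl": (5.6, 1.1),
    "ADPG": (3.3, 0.3),
    "FBPcyt": (16.1, 4.1),
    "F6Pcyt": (342.0, 57.8),
    "G6Pcyt": (861.1, 254.0),
    "G1Pcyt": (64.5, 13.3),
    "UDPG": (214.5, 34.2),
    "Suc6P": (9.8, 4.3),
    "Tre6P": (1.9, 0.5),
    "Gly": (1086.3, 118.0),
    "Ser": (12793.9, 978.0),
    "Glyc": (506.5, 195.0),
    "2PGA": (60.0, 13.5),
}

#: default true inactive fractions; Tre6P shows no plateau and is fixed at 0
DEFAULT_INACTIVE_FRACTIONS: dict[str, float] = {
    "3PGA": 0.15, "DHAP": 0.15, "FBP": 0.30, "F6P": 0.30, "G6P": 0.30,
    "G1P": 0.30, "ADPG": 0.10, "UDPG": 0.20, "Suc6P": 0.20, "Tre6P": 0.0,
    "Gly": 0.20, "Ser": 0.40, "Glyc": 0.30, "2PGA": 0.15,
}

#: default true raw exchange parameters, ordered as the reversible reactions
#: (ser_glyc, pga_dhap, g6p_g1p_pl, f6p_g6p_cyt, g6p_g1p_cyt, g1p_udpg,
#: pga_2pga): 3PGA<->DHAP and Ser<->Glyc near rapid equilibrium, the others
#: moderate
DEFAULT_EXCHANGE_RAW: dict[str, float] = {
    "ser_glyc": 0.95, "pga_dhap": 0.99, "g6p_g1p_pl": 0.90,
    "f6p_g6p_cyt": 0.27, "g6p_g1p_cyt": 0.95, "g1p_udpg": 0.40,
    "pga_2pga": 0.70,
}

#: headline net-mode weights (starch, sucrose, trehalose, photorespiration)
HEADLINE_WEIGHTS = (2.39, 6.99, 0.00059, 3.93)


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a synthetic dataset.

    RuBP labels with per-carbon unlabeled probability
    u(t) = phi_R + (1 - phi_R) exp(-lambda t): an exponential approach to a
    small residual unlabeled plateau, fast on the Calvin-Benson-cycle time
    scale (the 3-carbon cumomer u^3 halves within about a minute at the
    defaults lambda = 0.02 s^-1, phi_R = 0.05).
    """

    net_weights: tuple[float, float, float, float]
    exchange_raw: dict[str, float]
    contents: dict[str, float]
    phi: dict[str, float]
    rubp_lambda: float = 0.02
    rubp_plateau: float = 0.05
    noise_cv: float = 0.05
    seed: int = 0

    def flux_parameters(self, basis: FluxModeBasis) -> FluxParameters:
        raw = np.array([self.exchange_raw[r] for r in basis.exchange_reactions])
        return FluxParameters(np.array(self.net_weights), raw)

    def unlabeled_per_carbon(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return self.rubp_plateau + (1 - self.rubp_plateau) * np.exp(-self.rubp_lambda * t)


def make_truth(seed: int = 0, preset: str = "table1_like") -> GroundTruth:
    """A ground truth: the headline preset or a random draw within bounds."""
    if preset == "table1_like":
        return GroundTruth(
            HEADLINE_WEIGHTS, dict(DEFAULT_EXCHANGE_RAW),
            {p: m for p, (m, _) in REFERENCE_CONTENTS.items()},
            dict(DEFAULT_INACTIVE_FRACTIONS), seed=seed)
    if preset == "random":
        rng = np.random.default_rng(seed)
        w = tuple(10.0 ** rng.uniform(-3, 1.3, 4))
        raw = {r: float(rng.uniform(0.0, 0.95)) for r in DEFAULT_EXCHANGE_RAW}
        contents = {}
        for p, (m, s) in REFERENCE_CONTENTS.items():
            contents[p] = float(np.clip(rng.normal(m, s), max(1e-3, m - 2 * s),
                                        m + 2 * s))
        phi = {m: float(rng.uniform(0.0, 0.8))
               for m in DEFAULT_INACTIVE_FRACTIONS}
        phi["Tre6P"] = 0.0
        return GroundTruth(w, raw, contents, phi, seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


def simulate_rubp_labeling(truth: GroundTruth, times) -> MassIsotopomerSeries:
    """Binomial RuBP mass-isotopomer time courses.

    With label distributed independently per carbon (unlabeled probability
    u(t)), the mass-isotopomer fractions are binomial,
    x_i(t) = C(5, i) (1-u)^i u^(5-i), which realizes the uniform-within-
    mass-isotopomer assumption exactly.
    """
    times = np.asarray(times, float)
    u = truth.unlabeled_per_carbon(times)
    N = RUBP_CARBONS
    from math import comb
    x = np.stack([comb(N, i) * (1 - u) ** i * u ** (N - i)
                  for i in range(N + 1)], axis=1)
    return MassIsotopomerSeries(times, x)


def build_input_models(truth: GroundTruth, times=None,
                       sizes: tuple[int, ...] = (2, 3)) -> dict[int, InputModel]:
    """Fit two-exponential input models to the truth's RuBP cumomer series."""
    if times is None:
        times = np.concatenate([[0.0], REFERENCE_TIME_GRID])
    series = simulate_rubp_labeling(truth, times)
    models = {}
    for s in sizes:
        cum = cumomers_from_mass_isotopomers(series, s)
        models[s] = fit_input_model(cum)
    return models


@dataclass
class SyntheticRecord:
    """Everything needed to audit a synthetic dataset."""

    truth: GroundTruth
    input_models: dict[int, InputModel]
    obs_map: ObservationMap
    z_clean: np.ndarray          # noise-free predictions (T, M)
    rubp: MassIsotopomerSeries


def make_dataset(truth: GroundTruth, times=None, noise_cv: float | None = None,
                 seed: int | None = None, noise_floor: float = 0.005,
                 basis: FluxModeBasis | None = None
                 ) -> tuple[Dataset, SyntheticRecord]:
    """Generate a noisy dataset by running the forward model on the truth.

    Gaussian noise with sd = max(noise_cv * value, floor) is added to the
    unlabeled fractional contents (clipped to [0, 1]); content measurements
    are the true contents perturbed by the reference standard deviations.
    noise_cv = 0 returns the exact model prediction with floor-level
    variances.
    """
    if times is None:
        times = REFERENCE_TIME_GRID
    times = np.asarray(times, float)
    if noise_cv is None:
        noise_cv = truth.noise_cv
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    basis = basis or build_flux_mode_basis(build_reference_network())
    network = basis.network
    obs_map = default_observation_map(network, truth.phi)
    inputs = build_input_models(truth)
    params = truth.flux_parameters(basis)
    dist = flux_from_modes(params, basis)
    pools = ActivePoolSizes.from_contents(truth.contents, network, obs_map)
    system = assemble_system(network, dist, pools, inputs)
    traj = integrate(system, times)
    pred = observe(traj, pools, obs_map)

    sd = np.maximum(noise_cv * np.abs(pred.values), noise_floor)
    if noise_cv > 0:
        z_obs = np.clip(pred.values + rng.normal(0.0, sd), 0.0, 1.0)
    else:
        z_obs = pred.values.copy()
    z_var = sd ** 2

    pool_ids = tuple(p.id for p in network.simulated_pools)
    c_true = np.array([truth.contents[p] for p in pool_ids])
    c_sigma = np.array([REFERENCE_CONTENTS[p][1] for p in pool_ids])
    if noise_cv > 0:
        c_obs = np.maximum(c_true + rng.normal(0.0, c_sigma), 1e-3)
    else:
        c_obs = c_true.copy()

    dataset = Dataset(times, pred.metabolites, z_obs, z_var, pool_ids,
                      c_obs, c_sigma)
    record = SyntheticRecord(truth, inputs, obs_map, pred.values.copy(),
                             simulate_rubp_labeling(
                                 truth, np.concatenate([[0.0], times])))
    return dataset, record


def recovery_report(fit_result: FitResult, truth: GroundTruth,
                    ci: ConfidenceReport | None = None) -> pd.DataFrame:
    """Truth vs estimate per derived quantity, with CI-coverage flags.

    Quantities the scenario does not estimate (fixed contents, fixed
    inactive fractions) are flagged as not compared.
    """
    scenario = fit_result.scenario
    gross = float(np.sum(truth.net_weights))
    true_vals: dict[str, float] = {
        "gross_fixation": gross,
        "net_fixation": gross - truth.net_weights[3],
        "photorespiration_fraction": truth.net_weights[3] / gross,
    }
    for label, w in zip(NET_MODE_ORDER, truth.net_weights):
        true_vals[f"mode_{label}"] = w
        true_vals[f"fraction_{label}"] = w / gross
    for m, v in truth.phi.items():
        true_vals[f"phi_{m}"] = v
    for p, v in truth.contents.items():
        true_vals[f"content_{p}"] = v

    rows = []
    for name, est in fit_result.derived.items():
        if name not in true_vals:
            continue
        tv = true_vals[name]
        compared = True
        if name.startswith("content_"):
            compared = name.removeprefix("content_") in scenario.free_contents
        if name.startswith("phi_") and name.removeprefix("phi_") == "Tre6P":
            compared = False
        rel = (est - tv) / tv if tv != 0 else np.nan
        in_ci = None
        if ci is not None and name in ci.quantities:
            in_ci = ci.contains(name, tv)
        rows.append({"quantity": name, "truth": tv, "estimate": est,
                     "relative_error": rel, "compared": compared,
                     "in_ci": in_ci})
    df = pd.DataFrame(rows)
    df.attrs["coverage"] = (
        float(df.loc[df.in_ci.notna() & df.compared, "in_ci"].mean())
        if ci is not None else np.nan)
    return df
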