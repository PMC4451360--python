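"""Reference metabolic network and steady-state flux parameterization.

The model covers photoautotrophic central carbon metabolism of a C3 leaf:
RuBisCO carboxylation and oxygenation acting on ribulose-1,5-bisphosphate
(RuBP), a simplified photorespiratory pathway (Gly -> Ser -> glycerate ->
3PGA), and the plastidic starch and cytosolic sucrose/trehalose synthesis
chains.  Intermediates of the Calvin-Benson cycle between 3PGA/DHAP and RuBP
are not state variables; their influence enters only through the labeling
state of RuBP, which drives the system as a measured input.

All fluxes and pool sizes are carried in carbon-atom units
(nmol C gFW^-1 s^-1 and nmol C gFW^-1).  A reaction flux is the rate at
which substrate carbon is converted; per-substrate and per-product carbon
shares say how that carbon is drawn and delivered, with any remainder
released as CO2.

The steady-state flux space is spanned by 11 modes: four elementary flux
modes (net routes terminating in starch, sucrose, trehalose, or
photorespiratory CO2 release) plus seven futile exchange cycles, one per
reversible reaction.  Net-mode weights are normalized to the terminal
carbon rate, so gross carbon fixation equals the sum of the four weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pool",
    "HRule",
    "Reaction",
    "Network",
    "FluxModeBasis",
    "FluxParameters",
    "InfluxTerm",
    "FluxDistribution",
    "build_reference_network",
    "enumerate_net_modes",
    "build_flux_mode_basis",
    "exchange_transform",
    "flux_from_modes",
    "EXCHANGE_CAP_FACTOR",
]

#: capped exchange fluxes are reported as "Inf." in tabular output
EXCHANGE_CAP_FACTOR = 1.0e4


@dataclass(frozen=True)
class Pool:
    """A metabolite pool, possibly one of two compartmental twins."""

    id: str
    metabolite: str
    compartment: str  # "plastid", "cytosol" or "unassigned"
    carbons: int
    simulated: bool = True

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"pool {self.id}: carbons must be >= 1")


@dataclass(frozen=True)
class HRule:
    """Unlabeled-production probability of one reaction product.

    The probability that a newly made product molecule is fully unlabeled is
    ``coeff * prod(x[pool] for pool in pool_factors) * prod(y_s for s in
    input_sizes)`` where ``x`` are simulated unlabeled fractions and ``y_s``
    the RuBP cumomer input functions.  A product molecule that incorporates
    CO2 (unlabeled fraction identically zero after label switch-on) carries
    the zero into ``coeff``: e.g. carboxylation makes two 3PGA per event, one
    purely from the RuBP C1-C3 fragment (probability y_3) and one containing
    the fixed CO2 (probability 0), hence coeff = 1/2 with a y_3 factor.
    """

    coeff: float = 1.0
    pool_factors: tuple[str, ...] = ()
    input_sizes: tuple[int, ...] = ()


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) reaction in carbon-atom flux units.

    substrates / products are tuples of (pool_id, carbon share of the
    reaction flux).  Substrate shares sum to 1; product shares sum to
    1 - co2_release_share.  For reversible reactions (all of them 1:1
    isomerizations here) the backward direction consumes the product pool
    and produces the substrate pool with unlabeled probability equal to the
    product pool's unlabeled fraction.
    """

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    h_rules: tuple[HRule, ...]  # one per product, aligned
    reversible: bool = False
    co2_release_share: float = 0.0

    def __post_init__(self) -> None:
        sub = sum(s for _, s in self.substrates)
        prod = sum(s for _, s in self.products) + self.co2_release_share
        if abs(sub - 1.0) > 1e-12 or abs(prod - 1.0) > 1e-12:
            raise ValueError(f"reaction {self.id}: carbon shares unbalanced")
        if len(self.h_rules) != len(self.products):
            raise ValueError(f"reaction {self.id}: need one h-rule per product")


@dataclass(frozen=True)
class Network:
    pools: tuple[Pool, ...]
    reactions: tuple[Reaction, ...]

    def pool(self, pid: str) -> Pool:
        return self._pool_index[pid]

    @property
    def _pool_index(self) -> dict[str, Pool]:
        return {p.id: p for p in self.pools}

    @property
    def simulated_pools(self) -> tuple[Pool, ...]:
        return tuple(p for p in self.pools if p.simulated)

    @property
    def reversible_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.reversible)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


def build_reference_network() -> Network:
    """Construct the reference network of 18 simulated pools.

    Externals: RuBP (driving input, regenerated by the Calvin-Benson cycle
    from 3PGA), CO2 (fixed or released), and the starch, sucrose and
    trehalose sinks.
    """
    P = Pool
    pools = (
        # simulated state variables
        P("3PGA", "3PGA", "unassigned", 3),
        P("DHAP", "DHAP", "unassigned", 3),
        P("FBPpl", "FBP", "plastid", 6),
        P("F6Ppl", "F6P", "plastid", 6),
        P("G6Ppl", "G6P", "plastid", 6),
        P("G1Ppl", "G1P", "plastid", 6),
        P("ADPG", "ADPG", "plastid", 6),
        P("FBPcyt", "FBP", "cytosol", 6),
        P("F6Pcyt", "F6P", "cytosol", 6),
        P("G6Pcyt", "G6P", "cytosol", 6),
        P("G1Pcyt", "G1P", "cytosol", 6),
        P("UDPG", "UDPG", "cytosol", 6),
        P("Suc6P", "Suc6P", "cytosol", 12),
        P("Tre6P", "Tre6P", "cytosol", 12),
        P("Gly", "Gly", "unassigned", 2),
        P("Ser", "Ser", "unassigned", 3),
        P("Glyc", "Glyc", "unassigned", 3),
        P("2PGA", "2PGA", "unassigned", 3),
        # driven externals and sinks
        P("RuBP", "RuBP", "plastid", 5, simulated=False),
        P("CO2", "CO2", "unassigned", 1, simulated=False),
        P("starch", "starch", "plastid", 6, simulated=False),
        P("sucrose", "sucrose", "cytosol", 12, simulated=False),
        P("trehalose", "trehalose", "cytosol", 12, simulated=False),
    )

    R, H = Reaction, HRule
    f = 1.0
    reactions = (
        # RuBisCO carboxylation: RuBP + CO2 -> 2 x 3PGA.  Of the 6 product
        # carbons, 3 come from the RuBP C1-C3 fragment (cumomer size 3) and
        # 3 from the C4-C5 fragment plus the fixed CO2.
        R("rbc_carb", (("RuBP", 5 / 6), ("CO2", 1 / 6)),
          (("3PGA", f),), (H(0.5, (), (3,)),)),
        # RuBisCO oxygenation: RuBP -> 3PGA (C1-C3) + 2C unit -> Gly (C4-C5).
        R("rbc_oxy", (("RuBP", 1.0),),
          (("3PGA", 3 / 5), ("Gly", 2 / 5)),
          (H(1.0, (), (3,)), H(1.0, (), (2,)))),
        # 2 Gly -> Ser + CO2 (glycine decarboxylase + SHMT); an unlabeled Ser
        # requires both precursor glycines unlabeled.
        R("gly_ser", (("Gly", 1.0),), (("Ser", 3 / 4),),
          (H(1.0, ("Gly", "Gly")),), co2_release_share=1 / 4),
        R("ser_glyc", (("Ser", 1.0),), (("Glyc", 1.0),),
          (H(1.0, ("Ser",)),), reversible=True),
        R("glyc_pga", (("Glyc", 1.0),), (("3PGA", 1.0),), (H(1.0, ("Glyc",)),)),
        R("pga_dhap", (("3PGA", 1.0),), (("DHAP", 1.0),),
          (H(1.0, ("3PGA",)),), reversible=True),
        # aldolase condensations: 2 trioses -> FBP (both compartments draw
        # from the simulated DHAP pool)
        R("ald_pl", (("DHAP", 1.0),), (("FBPpl", 1.0),), (H(1.0, ("DHAP", "DHAP")),)),
        R("fbp_f6p_pl", (("FBPpl", 1.0),), (("F6Ppl", 1.0),), (H(1.0, ("FBPpl",)),)),
        R("f6p_g6p_pl", (("F6Ppl", 1.0),), (("G6Ppl", 1.0),), (H(1.0, ("F6Ppl",)),)),
        R("g6p_g1p_pl", (("G6Ppl", 1.0),), (("G1Ppl", 1.0),),
          (H(1.0, ("G6Ppl",)),), reversible=True),
        R("g1p_adpg", (("G1Ppl", 1.0),), (("ADPG", 1.0),), (H(1.0, ("G1Ppl",)),)),
        R("adpg_starch", (("ADPG", 1.0),), (("starch", 1.0),), (H(1.0, ("ADPG",)),)),
        R("ald_cyt", (("DHAP", 1.0),), (("FBPcyt", 1.0),), (H(1.0, ("DHAP", "DHAP")),)),
        R("fbp_f6p_cyt", (("FBPcyt", 1.0),), (("F6Pcyt", 1.0),), (H(1.0, ("FBPcyt",)),)),
        R("f6p_g6p_cyt", (("F6Pcyt", 1.0),), (("G6Pcyt", 1.0),),
          (H(1.0, ("F6Pcyt",)),), reversible=True),
        R("g6p_g1p_cyt", (("G6Pcyt", 1.0),), (("G1Pcyt", 1.0),),
          (H(1.0, ("G6Pcyt",)),), reversible=True),
        R("g1p_udpg", (("G1Pcyt", 1.0),), (("UDPG", 1.0),),
          (H(1.0, ("G1Pcyt",)),), reversible=True),
        # sucrose-phosphate synthase: UDPG + F6P -> Suc6P
        R("sps", (("UDPG", 0.5), ("F6Pcyt", 0.5)), (("Suc6P", 1.0),),
          (H(1.0, ("UDPG", "F6Pcyt")),)),
        R("spp", (("Suc6P", 1.0),), (("sucrose", 1.0),), (H(1.0, ("Suc6P",)),)),
        # trehalose-phosphate synthase: UDPG + G6P -> Tre6P
        R("tps", (("UDPG", 0.5), ("G6Pcyt", 0.5)), (("Tre6P", 1.0),),
          (H(1.0, ("UDPG", "G6Pcyt")),)),
        R("tpp", (("Tre6P", 1.0),), (("trehalose", 1.0),), (H(1.0, ("Tre6P",)),)),
        # dead-end exchange appendage
        R("pga_2pga", (("3PGA", 1.0),), (("2PGA", 1.0),),
          (H(1.0, ("3PGA",)),), reversible=True),
        # Calvin-Benson regeneration of RuBP from 3PGA (lumped)
        R("cbc_regen", (("3PGA", 1.0),), (("RuBP", 1.0),), (H(1.0, ("3PGA",)),)),
    )
    return Network(pools, reactions)


# ---------------------------------------------------------------------------
# elementary flux modes
# ---------------------------------------------------------------------------

def _stoichiometric_matrix(network: Network, internal: list[str],
                           reactions: list[Reaction]) -> np.ndarray:
    S = np.zeros((len(internal), len(reactions)))
    idx = {p: i for i, p in enumerate(internal)}
    for j, r in enumerate(reactions):
        for pid, share in r.substrates:
            if pid in idx:
                S[idx[pid], j] -= share
        for pid, share in r.products:
            if pid in idx:
                S[idx[pid], j] += share
    return S


def extreme_rays(S: np.ndarray, tol: float = 1e-10) -> list[np.ndarray]:
    """Extreme rays of the pointed cone {v >= 0, S v = 0} (double description).

    Starts from the nonnegative orthant (rays = unit vectors) and intersects
    with one hyperplane of S at a time, combining adjacent positive/negative
    rays.  Adjacency is decided combinatorially on the zero sets with respect
    to the orthant facets, which is exact for pointed cones of this size.
    """
    n = S.shape[1]
    rays: list[np.ndarray] = [np.eye(n)[j] for j in range(n)]
    for a in S:
        vals = [float(a @ r) for r in rays]
        pos = [r for r, v in zip(rays, vals) if v > tol]
        neg = [r for r, v in zip(rays, vals) if v < -tol]
        zero = [r for r, v in zip(rays, vals) if abs(v) <= tol]
        new = list(zero)
        for rp, rn in itertools.product(pos, neg):
            z = (rp <= tol) & (rn <= tol)
            adjacent = True
            for other in rays:
                if other is rp or other is rn:
                    continue
                if np.all(other[z] <= tol):
                    adjacent = False
                    break
            if adjacent:
                comb = float(a @ rp) * rn - float(a @ rn) * rp
                m = np.max(comb)
                if m > tol:
                    new.append(comb / m)
        rays = new
        if not rays:
            break
    # deduplicate (rays may coincide after scaling)
    out: list[np.ndarray] = []
    for r in rays:
        r = r / np.max(r)
        if not any(np.allclose(r, o, atol=1e-9) for o in out):
            out.append(r)
    return out


def enumerate_net_modes(network: Network,
                        internal: list[str] | None = None,
                        exclude_reactions: tuple[str, ...] = ("pga_2pga",),
                        normalize: bool = True) -> list[dict[str, float]]:
    """Elementary flux modes of the net (irreversible-direction) system.

    Reversible reactions are collapsed to their net forward direction and the
    pure-exchange 2PGA appendage is excluded.  RuBP is balanced (the lumped
    regeneration reaction closes the Calvin-Benson cycle), while CO2 and the
    starch/sucrose/trehalose sinks are external.

    Returns one dict {reaction id: flux} per mode.  With ``normalize`` each
    mode is scaled so its terminal carbon rate (C into starch / sucrose /
    trehalose, or C released by photorespiration) equals 1.
    """
    reactions = [r for r in network.reactions if r.id not in exclude_reactions]
    if internal is None:
        internal = [p.id for p in network.simulated_pools if p.id != "2PGA"]
        internal.append("RuBP")
    S = _stoichiometric_matrix(network, internal, reactions)
    if np.linalg.matrix_rank(S) >= len(reactions):
        raise ValueError("stoichiometric matrix admits no nonzero steady-state mode")
    rays = extreme_rays(S)
    modes = [{r.id: float(v) for r, v in zip(reactions, ray) if v > 1e-12}
             for ray in rays]
    if normalize:
        modes = [_normalize_mode(m) for m in modes]
    return modes


def _terminal_rate(mode: dict[str, float]) -> tuple[str, float]:
    """(terminus label, terminal C rate) of a reference-network mode."""
    for rid, label in (("adpg_starch", "starch"), ("spp", "sucrose"),
                       ("tpp", "trehalose")):
        if mode.get(rid, 0.0) > 1e-12:
            return label, mode[rid]
    if mode.get("gly_ser", 0.0) > 1e-12:
        net = build_reference_network()
        return "photorespiration", mode["gly_ser"] * net.reaction("gly_ser").co2_release_share
    raise ValueError("mode has no recognized terminus")


def _normalize_mode(mode: dict[str, float]) -> dict[str, float]:
    _, rate = _terminal_rate(mode)
    return {k: v / rate for k, v in mode.items()}


NET_MODE_ORDER = ("starch", "sucrose", "trehalose", "photorespiration")


@dataclass(frozen=True)
class FluxModeBasis:
    """11-mode steady-state flux parameterization of the reference network.

    ``net_matrix`` holds the four elementary flux modes as columns (reaction
    net fluxes per unit terminal carbon rate, ordered starch / sucrose /
    trehalose / photorespiration).  The seven exchange modes are futile
    cycles, one per reversible reaction in ``exchange_reactions``; they add
    equal forward and backward flux and have zero net flux on every reaction.
    """

    network: Network
    reaction_ids: tuple[str, ...]
    net_matrix: np.ndarray           # (n_reactions, 4)
    mode_labels: tuple[str, ...]     # the 4 net labels
    exchange_reactions: tuple[str, ...]  # the 7 reversible reaction ids

    @property
    def n_modes(self) -> int:
        return self.net_matrix.shape[1] + len(self.exchange_reactions)


def build_flux_mode_basis(network: Network | None = None) -> FluxModeBasis:
    network = network or build_reference_network()
    modes = enumerate_net_modes(network)
    if len(modes) != len(NET_MODE_ORDER):
        raise ValueError(f"expected {len(NET_MODE_ORDER)} net modes, got {len(modes)}")
    by_label = {}
    for m in modes:
        label, _ = _terminal_rate(m)
        by_label[label] = m
    if set(by_label) != set(NET_MODE_ORDER):
        raise ValueError(f"net-mode termini {set(by_label)} != {set(NET_MODE_ORDER)}")
    rids = tuple(r.id for r in network.reactions)
    M = np.zeros((len(rids), len(NET_MODE_ORDER)))
    for k, label in enumerate(NET_MODE_ORDER):
        for rid, v in by_label[label].items():
            M[rids.index(rid), k] = v
    exch = tuple(r.id for r in network.reversible_reactions)
    return FluxModeBasis(network, rids, M, NET_MODE_ORDER, exch)


# ---------------------------------------------------------------------------
# flux parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxParameters:
    """Net-mode weights (nmol C gFW^-1 s^-1) and raw exchange parameters.

    Raw exchange parameters live in [0, 1) and are hyperbolically transformed
    into exchange fluxes; values approaching 1 map to the finite cap that is
    reported as "Inf.".
    """

    net_weights: np.ndarray   # (4,)
    exchange_raw: np.ndarray  # (7,)

    def __post_init__(self) -> None:
        w = np.asarray(self.net_weights, float)
        x = np.asarray(self.exchange_raw, float)
        object.__setattr__(self, "net_weights", w)
        object.__setattr__(self, "exchange_raw", x)
        if w.shape != (4,) or np.any(w < 0):
            raise ValueError("net_weights must be 4 nonnegative values")
        if x.shape != (7,) or np.any(x < 0) or np.any(x >= 1):
            raise ValueError("exchange_raw must be 7 values in [0, 1)")


def exchange_transform(raw: float, scale: float,
                       cap_factor: float = EXCHANGE_CAP_FACTOR) -> float:
    """Hyperbolic transform of a raw exchange parameter to an exchange flux.

    f = scale * raw / (1 - raw), monotone on [0, 1), capped at
    ``cap_factor * scale`` (the cap stands in for an unbounded exchange and
    is printed as "Inf.").
    """
    if not 0.0 <= raw < 1.0:
        raise ValueError(f"raw exchange parameter {raw} outside [0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    cap = cap_factor * scale
    return min(scale * raw / (1.0 - raw), cap)


@dataclass(frozen=True)
class InfluxTerm:
    reaction_id: str
    flux: float      # C atoms s^-1 delivered to the target pool
    h: HRule


@dataclass
class FluxDistribution:
    """Per-reaction net/forward/backward fluxes and per-pool turnover."""

    basis: FluxModeBasis
    net: dict[str, float]
    forward: dict[str, float]
    backward: dict[str, float]
    exchange_scale: float
    exchange_capped: dict[str, bool]
    influxes: dict[str, list[InfluxTerm]] = field(default_factory=dict)
    turnover: dict[str, float] = field(default_factory=dict)  # F_n

    @property
    def gross_fixation(self) -> float:
        # CO2 uptake by carboxylation, in C atoms per unit time
        net = self.basis.network
        r = net.reaction("rbc_carb")
        co2_share = dict(r.substrates)["CO2"]
        return self.net["rbc_carb"] * co2_share

    @property
    def net_fixation(self) -> float:
        net = self.basis.network
        release = self.net["gly_ser"] * net.reaction("gly_ser").co2_release_share
        return self.gross_fixation - release

    def influx_ratios(self, pool_id: str) -> dict[str, float]:
        F = self.turnover[pool_id]
        if F <= 0:
            return {}
        return {t.reaction_id: t.flux / F for t in self.influxes[pool_id]}


def flux_from_modes(params: FluxParameters, basis: FluxModeBasis,
                    exchange_scale: float | None = None,
                    cap_factor: float = EXCHANGE_CAP_FACTOR) -> FluxDistribution:
    """Steady-state flux distribution from mode weights and exchange raws.

    Net fluxes are the linear combination of the four elementary flux modes;
    each reversible reaction additionally carries the hyperbolically
    transformed exchange flux as its backward flux (forward = net + backward).
    The exchange scale defaults to the gross fixation implied by the weights.
    """
    network = basis.network
    net_vec = basis.net_matrix @ params.net_weights
    net = dict(zip(basis.reaction_ids, net_vec))
    rev = set(basis.exchange_reactions)
    for rid, v in net.items():
        if v < -1e-12 and rid not in rev:
            raise ValueError(f"negative net flux on irreversible reaction {rid}")
    scale = exchange_scale
    if scale is None:
        gross = float(np.sum(params.net_weights))
        scale = gross if gross > 0 else 1.0
    backward, capped = {}, {}
    for rid in basis.reaction_ids:
        if rid in rev:
            raw = params.exchange_raw[basis.exchange_reactions.index(rid)]
            b = exchange_transform(raw, scale, cap_factor)
            backward[rid] = b
            capped[rid] = b >= cap_factor * scale - 1e-9
        else:
            backward[rid] = 0.0
            capped[rid] = False
    forward = {rid: net[rid] + backward[rid] for rid in basis.reaction_ids}

    dist = FluxDistribution(basis, net, forward, backward, scale, capped)
    _populate_pool_fluxes(dist)
    return dist


def _populate_pool_fluxes(dist: FluxDistribution) -> None:
    network = dist.basis.network
    influxes: dict[str, list[InfluxTerm]] = {p.id: [] for p in network.simulated_pools}
    outflux: dict[str, float] = {p.id: 0.0 for p in network.simulated_pools}
    for r in network.reactions:
        fwd, bwd = dist.forward[r.id], dist.backward[r.id]
        if fwd > 0:
            for (pid, share), h in zip(r.products, r.h_rules):
                if pid in influxes:
                    influxes[pid].append(InfluxTerm(r.id, fwd * share, h))
            for pid, share in r.substrates:
                if pid in outflux:
                    outflux[pid] += fwd * share
        if bwd > 0:  # reverse direction of a 1:1 reversible reaction
            (sub, _), (prod, _) = r.substrates[0], r.products[0]
            if sub in influxes:
                influxes[sub].append(
                    InfluxTerm(r.id + "_rev", bwd, HRule(1.0, (prod,))))
            if prod in outflux:
                outflux[prod] += bwd
    turnover = {}
    for pid in influxes:
        fin = sum(t.flux for t in influxes[pid])
        fout = outflux[pid]
        if abs(fin - fout) > 1e-9 * max(fin, fout, 1.0):
            raise AssertionError(
                f"steady-state violation at pool {pid}: in {fin} vs out {fout}")
        turnover[pid] = fin
    dist.influxes = influxes
    dist.turnover = turnover
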