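"""RuBP labeling inputs: mass isotopomers -> cumomers -> input models.

The simulated ODE layer needs, for each RuBP carbon fragment of size s, the
probability y_s(t) that the fragment is fully unlabeled (the mass-zero EMU
state variable, equal to a cumomer fraction of weight s).  Under the
assumption that label is uniformly distributed within each mass isotopomer,
y_s is a time-independent weighted sum of the measured mass-isotopomer
fractions with hypergeometric weights theta_s^i = C(N-s, i) / C(N, i).

Each y_s series is then condensed into a two-exponential "input model"
y_s(t) = A e^{-a t} + B e^{-b t} with A + B = 1, which supplies the
inhomogeneous terms of the labeling ODEs in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RUBP_CARBONS",
    "theta_weight",
    "theta_table",
    "MassIsotopomerSeries",
    "CumomerSeries",
    "cumomers_from_mass_isotopomers",
    "InputModel",
    "eval_input_model",
    "fit_input_model",
]

RUBP_CARBONS = 5


def theta_weight(N: int, s: int, i: int) -> float:
    """Contribution of mass isotopomer i to the unlabeled cumomer of size s.

    theta_s^i = C(N-s, i) / C(N, i), with C(n, k) = 0 for k > n; this is the
    probability that i labels placed uniformly on N positions all avoid a
    fixed set of s positions.
    """
    if not (1 <= s <= N):
        raise ValueError(f"cumomer size {s} outside 1..{N}")
    if not (0 <= i <= N):
        raise ValueError(f"mass state {i} outside 0..{N}")
    return comb(N - s, i) / comb(N, i)


def theta_table(N: int = RUBP_CARBONS) -> np.ndarray:
    """(N, N+1) array of theta_s^i for s = 1..N (rows) and i = 0..N."""
    return np.array([[theta_weight(N, s, i) for i in range(N + 1)]
                     for s in range(1, N + 1)])


@dataclass(frozen=True)
class MassIsotopomerSeries:
    """Fractions of the M0..MN mass isotopomers over time (rows sum to 1)."""

    times: np.ndarray       # (T,) seconds
    fractions: np.ndarray   # (T, N+1)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        x = np.asarray(self.fractions, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", x)
        if x.ndim != 2 or x.shape[0] != t.size:
            raise ValueError("fractions must be (n_times, N+1)")
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            raise ValueError("mass-isotopomer fractions outside [0, 1]")
        if np.any(np.abs(x.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("mass-isotopomer fractions must sum to 1 at each time")

    @property
    def n_carbons(self) -> int:
        return self.fractions.shape[1] - 1


@dataclass(frozen=True)
class CumomerSeries:
    size: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))


def cumomers_from_mass_isotopomers(series: MassIsotopomerSeries,
                                   s: int) -> CumomerSeries:
    """Unlabeled cumomer fraction of size s from mass-isotopomer fractions."""
    N = series.n_carbons
    w = np.array([theta_weight(N, s, i) for i in range(N + 1)])
    y = series.fractions @ w
    return CumomerSeries(s, series.times, np.clip(y, 0.0, 1.0))


@dataclass(frozen=True)
class InputModel:
    """Two-exponential model y(t) = A e^{-a t} + B e^{-b t}, A + B = 1."""

    size: int
    A: float
    a: float
    B: float
    b: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.A + self.B - 1.0) > 1e-9:
            raise ValueError("input model amplitudes must satisfy A + B = 1")
        if self.a < 0 or self.b < 0:
            raise ValueError("input model rates must be nonnegative")

    def __call__(self, t):
        return eval_input_model(self, t)


def eval_input_model(model: InputModel, t):
    t = np.asarray(t, float)
    return model.A * np.exp(-model.a * t) + model.B * np.exp(-model.b * t)


def _two_exp(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, loga, logb = params
    return A * np.exp(-np.exp(loga) * t) + (1 - A) * np.exp(-np.exp(logb) * t)


def fit_input_model(series: CumomerSeries, n_starts: int = 10) -> InputModel:
    """Constrained least-squares fit of the two-exponential input model.

    Optimizes (A, log a, log b) with B = 1 - A and A in [0, 1], multistarted
    from log-spaced rate pairs spanning the sampling window.  A flat series
    returns the degenerate constant model (a = b = 0) with a warning.
    """
    t = series.times
    y = series.values
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit an input model")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("cumomer values must lie in [0, 1]")
    if np.ptp(y) < 1e-12:
        warnings.warn("constant cumomer series: returning degenerate input model")
        return InputModel(series.size, 1.0, 0.0, 0.0, 0.0, 0.0)

    tmax = max(t.max(), 1.0)
    rates = np.geomspace(0.1 / tmax, 50.0 / max(t[t > 0].min(), 1e-6), n_starts)
    best = None
    for i, fast in enumerate(rates):
        slow = rates[max(i - 3, 0)] / 10.0
        x0 = np.array([0.7, np.log(fast), np.log(max(slow, 1e-12))])
        try:
            sol = least_squares(lambda p: _two_exp(p, t) - y, x0,
                                bounds=([0.0, -50.0, -50.0], [1.0, 10.0, 10.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("input-model fit failed from all starts")
    A, loga, logb = best.x
    a, b = np.exp(loga), np.exp(logb)
    if a < b:  # report the fast component first
        a, b, A = b, a, 1 - A
    resid = float(np.sqrt(2 * best.cost / t.size))
    # snap numerically-zero rates (log-bounded at e^-50) to exact zero
    a = 0.0 if a < 1e-18 else float(a)
    b = 0.0 if b < 1e-18 else float(b)
    return InputModel(series.size, float(A), a, float(1 - A), b, resid)
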