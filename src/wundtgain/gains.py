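"""Gain curves and optimal arousal: peaks of KLD, BS, and IG over delta.

Tabulates the recognition gain (KLD), Bayesian surprise (BS), and total
information gain (IG = KLD + BS) along a prediction-error grid and locates
the optimal prediction errors ``delta_KLD <= delta_IG <= delta_BS`` and the
corresponding optimal surprises ``S_KLD <= S_IG <= S_BS``.  The surprise
gap ``D_S = S_BS - S_KLD`` is the amplitude of the curiosity-driven
fluctuation simulated in :mod:`wundtgain.inquiry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import NumericalError, ParameterError
from .gaussian import GaussianBelief, ModelSetup
from .mixture import NoisyLikelihood, bs_mixture, kld_mixture, mixture_surprise

__all__ = [
    "GainCurve",
    "OptimumSummary",
    "default_delta_bound",
    "default_delta_grid",
    "gain_curve",
    "find_optima",
    "gain_vs_surprise",
]

#: Number of pre-scan points used to bracket each peak before local search.
PRESCAN_POINTS = 160


@dataclass(frozen=True)
class GainCurve:
    """Tabulated gains along a prediction-error grid (all values in nats)."""

    deltas: np.ndarray
    surprise: np.ndarray
    kld: np.ndarray
    bs: np.ndarray
    ig: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta": self.deltas,
                "surprise": self.surprise,
                "kld": self.kld,
                "bs": self.bs,
                "ig": self.ig,
            }
        )


@dataclass(frozen=True)
class OptimumSummary:
    """Optimal prediction errors and surprises of the three gain functions.

    ``d_delta = delta_bs - delta_kld`` and ``d_s = s_bs - s_kld`` quantify
    the exploration range and the surprise fluctuation magnitude of the
    alternating inquiry cycle.  ``warnings`` records non-interior optima.
    """

    delta_kld: float
    delta_bs: float
    delta_ig: float
    s_kld: float
    s_bs: float
    s_ig: float
    max_kld: float
    max_bs: float
    max_ig: float
    d_delta: float
    d_s: float
    warnings: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "delta_kld": self.delta_kld,
            "delta_bs": self.delta_bs,
            "delta_ig": self.delta_ig,
            "s_kld": self.s_kld,
            "s_bs": self.s_bs,
            "s_ig": self.s_ig,
            "max_kld": self.max_kld,
            "max_bs": self.max_bs,
            "max_ig": self.max_ig,
            "d_delta": self.d_delta,
            "d_s": self.d_s,
        }


def default_delta_bound(prior: GaussianBelief, noise: NoisyLikelihood) -> float:
    """Upper search bound for the optima: three switchover scales.

    The evidence kernel crosses the noise floor at
    ``delta* = sqrt(2 (sigma_p^2 + sigma_l^2) ln(1/eps))`` and the gain
    peaks sit near that switchover, so three times it safely brackets them.
    """
    total = prior.variance + noise.lik_variance
    return 3.0 * math.sqrt(2.0 * total * math.log(1.0 / noise.eps))


def default_delta_grid(
    prior: GaussianBelief, noise: NoisyLikelihood, n: int = 400
) -> np.ndarray:
    """Default curve grid: log-spaced plus linear points on [0, delta_hi]."""
    hi = default_delta_bound(prior, noise)
    n_log = n // 2
    n_lin = n - n_log
    log_pts = np.geomspace(hi * 1e-4, hi, n_log)
    lin_pts = np.linspace(0.0, hi, n_lin)
    return np.unique(np.concatenate(([0.0], log_pts, lin_pts)))


def _evaluate(
    prior: GaussianBelief, noise: NoisyLikelihood, delta: float
) -> tuple[float, float, float]:
    setup = ModelSetup(
        prior=prior, lik_variance=noise.lik_variance, prediction_error=float(delta)
    )
    s = mixture_surprise(setup, noise)
    k = kld_mixture(setup, noise)
    b = bs_mixture(setup, noise)
    return s, k, b


def gain_curve(
    prior: GaussianBelief, noise: NoisyLikelihood, delta_grid: Sequence[float]
) -> GainCurve:
    """Evaluate surprise, KLD, BS, and IG on a sorted nonnegative grid."""
    deltas = np.asarray(delta_grid, dtype=float)
    if deltas.ndim != 1 or len(deltas) == 0:
        raise ParameterError("delta_grid must be a non-empty 1-D sequence")
    if np.any(deltas < 0.0) or np.any(np.diff(deltas) < 0.0):
        raise ParameterError("delta_grid must be sorted and nonnegative")
    surprise = np.empty_like(deltas)
    kld = np.empty_like(deltas)
    bs = np.empty_like(deltas)
    for i, d in enumerate(deltas):
        try:
            surprise[i], kld[i], bs[i] = _evaluate(prior, noise, d)
        except NumericalError as err:
            raise NumericalError(f"gain evaluation failed at delta={d!r}: {err}") from err
    return GainCurve(deltas=deltas, surprise=surprise, kld=kld, bs=bs, ig=kld + bs)


def _maximize(
    f: Callable[[float], float], lo: float, hi: float, xatol: float = 1e-7
) -> tuple[float, float, list[str]]:
    """Bounded scalar maximization with a coarse unimodality pre-scan.

    A pre-scan selects the bracketing interval, then Brent-style bounded
    search (golden section plus parabolic interpolation) refines the peak.
    Ties flat to within 1e-9 resolve to the smallest delta.
    """
    warnings: list[str] = []
    grid = np.linspace(lo, hi, PRESCAN_POINTS)
    vals = np.array([f(x) for x in grid])
    best = vals.max()
    # smallest grid point within the flat-tie tolerance of the maximum
    i = int(np.argmax(vals >= best - 1e-9))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        return float(grid[i]), float(vals[i]), warnings
    res = minimize_scalar(
        lambda x: -f(x), bounds=(a, b), method="bounded", options={"xatol": xatol}
    )
    x_opt, f_opt = float(res.x), float(-res.fun)
    if f_opt < vals[i]:
        x_opt, f_opt = float(grid[i]), float(vals[i])
    if x_opt <= lo + 10 * xatol or x_opt >= hi - 10 * xatol:
        warnings.append(
            f"non-interior optimum at delta={x_opt:.6g} (bounds [{lo:.6g}, {hi:.6g}])"
        )
    return x_opt, f_opt, warnings


def find_optima(
    prior: GaussianBelief,
    noise: NoisyLikelihood,
    delta_bounds: tuple[float, float] | None = None,
) -> OptimumSummary:
    """Locate the peaks of KLD, BS, and IG over the prediction error.

    Each gain is maximized by bounded scalar optimization after a coarse
    bracketing pre-scan; optimal surprises are read off from the surprise
    function at the optimal prediction errors.
    """
    if delta_bounds is None:
        delta_bounds = (0.0, default_delta_bound(prior, noise))
    lo, hi = delta_bounds
    if not (0.0 <= lo < hi):
        raise ParameterError(f"delta_bounds must satisfy 0 <= lo < hi, got {delta_bounds!r}")

    cache: dict[float, tuple[float, float, float]] = {}

    def eval_cached(d: float) -> tuple[float, float, float]:
        if d not in cache:
            cache[d] = _evaluate(prior, noise, d)
        return cache[d]

    d_kld, max_kld, w1 = _maximize(lambda d: eval_cached(d)[1], lo, hi)
    d_bs, max_bs, w2 = _maximize(lambda d: eval_cached(d)[2], lo, hi)
    d_ig, max_ig, w3 = _maximize(
        lambda d: eval_cached(d)[1] + eval_cached(d)[2], lo, hi
    )

    s_kld = eval_cached(d_kld)[0]
    s_bs = eval_cached(d_bs)[0]
    s_ig = eval_cached(d_ig)[0]
    return OptimumSummary(
        delta_kld=d_kld,
        delta_bs=d_bs,
        delta_ig=d_ig,
        s_kld=s_kld,
        s_bs=s_bs,
        s_ig=s_ig,
        max_kld=max_kld,
        max_bs=max_bs,
        max_ig=max_ig,
        d_delta=d_bs - d_kld,
        d_s=s_bs - s_kld,
        warnings=tuple(w1 + w2 + w3),
    )


def gain_vs_surprise(curve: GainCurve) -> pd.DataFrame:
    """Reparameterize a gain curve by surprise instead of prediction error.

    A pure relabeling of the x-axis (surprise is monotone in delta under
    the kernel convention), so peak values are preserved exactly.
    """
    if np.any(np.diff(curve.surprise) < -1e-12):
        raise NumericalError("surprise is not monotone along the delta grid")
    return pd.DataFrame(
        {
            "surprise": curve.surprise,
            "kld": curve.kld,
            "bs": curve.bs,
            "ig": curve.ig,
        }
    )
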