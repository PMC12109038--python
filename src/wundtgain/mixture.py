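"""Uniform-noise-augmented likelihood and the resulting mixture posterior.

A constant floor ``eps`` is added to the kernel-height-1 Gaussian
likelihood, ``p_eps(o|s) = alpha (p(o|s) + eps)`` with ``alpha = 1/(1 +
eps)``, modeling spontaneous baseline activity far from the likelihood
mode.  The floor makes the posterior a two-component mixture of the
conjugate Gaussian posterior and the prior,

    p_eps(s|o) = w_post N_post + w_pri N_pri,
    w_post = e(delta) / (e(delta) + eps),  w_pri = eps / (e(delta) + eps),

and turns both information gains (recognition gain KLD and Bayesian
surprise BS) into inverted-U functions of the prediction error: far from
the prior the evidence kernel sinks below the floor, the posterior falls
back onto the prior, and the gains vanish.  The mixture KL divergences
have no closed form and are computed by adaptive quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

from scipy.integrate import quad

from .errors import NumericalError, ParameterError
from .gaussian import GaussianBelief, ModelSetup, evidence_kernel, posterior_params

__all__ = [
    "NoisyLikelihood",
    "MixturePosterior",
    "augmented_evidence",
    "mixture_surprise",
    "mixture_weights",
    "mixture_posterior",
    "mixture_pdf",
    "kl_numeric",
    "kld_mixture",
    "bs_mixture",
]

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-3

# Smallest positive double; floors density evaluations inside log ratios.
_TINY = 5e-324
_DENSITY_FLOOR = 1e-320


@dataclass(frozen=True)
class NoisyLikelihood:
    """Gaussian likelihood kernel variance plus a uniform noise floor.

    ``eps`` is the constant probability of the flat component and
    ``alpha = 1 / (1 + eps)`` renormalizes the augmented likelihood so that
    its peak evidence stays at 1.
    """

    lik_variance: float
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if not (self.lik_variance > 0.0) or not math.isfinite(self.lik_variance):
            raise ParameterError(
                f"lik_variance must be a positive finite number, got {self.lik_variance!r}"
            )
        if not (0.0 < self.eps < 1.0):
            raise ParameterError(f"eps must lie in (0, 1), got {self.eps!r}")

    @property
    def alpha(self) -> float:
        return 1.0 / (1.0 + self.eps)

    @property
    def surprise_ceiling(self) -> float:
        """Saturation level of the surprise, ``ln((1 + eps) / eps)``."""
        return math.log((1.0 + self.eps) / self.eps)


@dataclass(frozen=True)
class MixturePosterior:
    """Two-component posterior: conjugate Gaussian posterior plus prior."""

    w_post: float
    w_pri: float
    post: GaussianBelief
    pri: GaussianBelief

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_post <= 1.0 and 0.0 <= self.w_pri <= 1.0):
            raise ParameterError("mixture weights must lie in [0, 1]")
        if abs(self.w_post + self.w_pri - 1.0) > 1e-12:
            raise ParameterError("mixture weights must sum to 1")

    def pdf(self, s: float) -> float:
        return self.w_post * self.post.pdf(s) + self.w_pri * self.pri.pdf(s)

    def logpdf(self, s: float) -> float:
        """Log density, stable where one component underflows."""
        terms = []
        if self.w_post > 0.0:
            terms.append(math.log(self.w_post) + self.post.logpdf(s))
        if self.w_pri > 0.0:
            terms.append(math.log(self.w_pri) + self.pri.logpdf(s))
        m = max(terms)
        return m + math.log(sum(math.exp(t - m) for t in terms))


def _check_consistent(setup: ModelSetup, noise: NoisyLikelihood) -> None:
    if setup.lik_variance != noise.lik_variance:
        raise ParameterError(
            "setup.lik_variance and noise.lik_variance disagree: "
            f"{setup.lik_variance!r} != {noise.lik_variance!r}"
        )


def augmented_evidence(setup: ModelSetup, noise: NoisyLikelihood) -> float:
    """Evidence with the noise floor, ``p_eps(o) = alpha (e(delta) + eps)``.

    Bounded below by ``alpha * eps > 0``, so the surprise saturates instead
    of diverging.
    """
    _check_consistent(setup, noise)
    return noise.alpha * (evidence_kernel(setup) + noise.eps)


def mixture_surprise(setup: ModelSetup, noise: NoisyLikelihood) -> float:
    """Shannon surprise of the augmented evidence, ``-ln p_eps(o)``.

    Zero at zero prediction error, monotone nondecreasing in the prediction
    error, and saturating at ``ln((1 + eps) / eps)``.
    """
    # "+ 0.0" normalizes the IEEE negative zero at the peak
    return -math.log(augmented_evidence(setup, noise)) + 0.0


def mixture_weights(setup: ModelSetup, noise: NoisyLikelihood) -> tuple[float, float]:
    """Mixture weights ``(w_post, w_pri)`` of posterior vs prior component.

    The weights trade off the Gaussian evidence kernel against the noise
    floor and switch dominance where ``e(delta) = eps``.
    """
    _check_consistent(setup, noise)
    e = evidence_kernel(setup)
    denom = e + noise.eps
    w_post = e / denom
    return w_post, 1.0 - w_post


def mixture_posterior(setup: ModelSetup, noise: NoisyLikelihood) -> MixturePosterior:
    """Assemble the two-component posterior for one scenario."""
    w_post, w_pri = mixture_weights(setup, noise)
    post = posterior_params(setup, setup.observation)
    return MixturePosterior(w_post=w_post, w_pri=w_pri, post=post, pri=setup.prior)


def mixture_pdf(s: float, mp: MixturePosterior) -> float:
    """Mixture posterior density at ``s``."""
    return mp.pdf(s)


def kl_numeric(
    p_density: Callable[[float], float],
    q_density: Callable[[float], float],
    domain_hint: tuple[float, float],
    breakpoints: Sequence[float] | None = None,
    p_logpdf: Callable[[float], float] | None = None,
    q_logpdf: Callable[[float], float] | None = None,
) -> float:
    """KL divergence between two normalized densities by adaptive quadrature.

    Integrates ``p ln(p / q)`` over ``domain_hint`` (which must carry all
    but a negligible fraction of the mass of ``p``).  ``breakpoints`` mark
    known feature locations (component means) to help the subdivision.
    Supplying ``p_logpdf``/``q_logpdf`` keeps the log ratio exact where a
    narrow density underflows in linear space (``p ln(p/q)`` can carry
    non-negligible mass there when ``q`` is much narrower than ``p``).
    Tiny negative round-off results in ``[-1e-9, 0]`` are clamped to 0.
    """
    a, b = domain_hint

    if p_logpdf is not None and q_logpdf is not None:

        def integrand(s: float) -> float:
            lp = p_logpdf(s)
            if lp < -700.0:
                return 0.0
            return math.exp(lp) * (lp - q_logpdf(s))

    else:

        def integrand(s: float) -> float:
            ps = p_density(s)
            if ps <= _TINY:
                return 0.0
            qs = q_density(s)
            if qs < _DENSITY_FLOOR:
                qs = _DENSITY_FLOOR
            return ps * (math.log(ps) - math.log(qs))

    pts = None
    if breakpoints is not None:
        pts = sorted(x for x in breakpoints if a < x < b)
        if not pts:
            pts = None
    value, abserr = quad(
        integrand, a, b, points=pts, limit=400, epsabs=1e-12, epsrel=1e-10
    )
    if abserr > max(1e-8, 1e-6 * abs(value)):
        raise NumericalError(
            f"KL quadrature did not converge: value={value!r}, abserr={abserr!r}, "
            f"domain=({a!r}, {b!r})"
        )
    if value < 0.0:
        if value < -1e-9:
            raise NumericalError(
                f"KL quadrature returned a significantly negative value: {value!r}"
            )
        logger.debug("clamping tiny negative KL %.3e to 0", value)
        value = 0.0
    return value


def _integration_domain(setup: ModelSetup) -> tuple[tuple[float, float], list[float]]:
    """Interval covering both mixture components to below 1e-30 tail mass.

    Breakpoints at each component mean and a few standard deviations out
    force the adaptive subdivision to resolve both scales.
    """
    post = posterior_params(setup, setup.observation)
    lo_mean = min(setup.prior.mean, post.mean)
    hi_mean = max(setup.prior.mean, post.mean)
    pad = 12.0 * max(setup.prior.std, post.std)
    pts = sorted(
        m + k * sd
        for m, sd in ((setup.prior.mean, setup.prior.std), (post.mean, post.std))
        for k in (-6.0, -2.0, 0.0, 2.0, 6.0)
    )
    return (lo_mean - pad, hi_mean + pad), pts


def kld_mixture(setup: ModelSetup, noise: NoisyLikelihood) -> float:
    """Recognition gain with the noise floor: ``D_KL[prior || mixture posterior]``.

    Matches the closed-form quadratic as ``eps -> 0`` and decays to zero
    once the evidence kernel sinks far below the floor.
    """
    mp = mixture_posterior(setup, noise)
    try:
        domain, pts = _integration_domain(setup)
        return kl_numeric(
            setup.prior.pdf,
            mp.pdf,
            domain,
            breakpoints=pts,
            p_logpdf=setup.prior.logpdf,
            q_logpdf=mp.logpdf,
        )
    except NumericalError as err:
        raise NumericalError(
            f"KLD quadrature failed at delta={setup.prediction_error!r}: {err}"
        ) from err


def bs_mixture(setup: ModelSetup, noise: NoisyLikelihood) -> float:
    """Bayesian surprise with the noise floor: ``D_KL[mixture posterior || prior]``."""
    mp = mixture_posterior(setup, noise)
    try:
        domain, pts = _integration_domain(setup)
        return kl_numeric(
            mp.pdf,
            setup.prior.pdf,
            domain,
            breakpoints=pts,
            p_logpdf=mp.logpdf,
            q_logpdf=setup.prior.logpdf,
        )
    except NumericalError as err:
        raise NumericalError(
            f"BS quadrature failed at delta={setup.prediction_error!r}: {err}"
        ) from err
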