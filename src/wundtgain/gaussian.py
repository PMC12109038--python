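"""Conjugate Gaussian belief machinery and closed-form information gains.

The generative model is a one-dimensional Gaussian prior ``p(s) = N(eta,
sigma_p^2)`` observed through a Gaussian likelihood of variance
``sigma_l^2``.  Because the observation ``o`` enters every quantity only
through the prediction error ``delta = eta - o`` (the distance between the
prior mean and the likelihood peak), the model is parameterized by
``(eta, sigma_p^2, sigma_l^2, delta)``.

Two conventions coexist deliberately:

* the *kernel* convention treats the likelihood as an unnormalized Gaussian
  kernel of peak height 1, so the model evidence is ``e(delta) =
  exp(-delta^2 / (2 (sigma_p^2 + sigma_l^2)))`` and the Shannon surprise
  ``-ln e(delta)`` is exactly zero at zero prediction error;
* the *normalized* convention uses proper densities and is required
  wherever an identity involves entropies (``perceived_uncertainty`` and
  the predictive free-energy decompositions).

All information quantities are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "GaussianBelief",
    "ModelSetup",
    "GainCoefficients",
    "posterior_params",
    "evidence_kernel",
    "gaussian_surprise",
    "gain_coefficients",
    "kld_closed",
    "bs_closed",
    "kl_gaussians",
    "perceived_uncertainty",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianBelief:
    """A one-dimensional Gaussian state density.

    Plays the role of prior, posterior, or observation preference.

    Parameters
    ----------
    mean : float
        Location of the density, in state units.
    variance : float
        Strictly positive variance, in state units squared.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0.0) or not math.isfinite(self.variance):
            raise ParameterError(
                f"variance must be a positive finite number, got {self.variance!r}"
            )
        if not math.isfinite(self.mean):
            raise ParameterError(f"mean must be finite, got {self.mean!r}")

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)

    def pdf(self, s: float) -> float:
        """Normalized density at ``s``."""
        z = (s - self.mean) ** 2 / (2.0 * self.variance)
        return math.exp(-z) / math.sqrt(2.0 * math.pi * self.variance)

    def logpdf(self, s: float) -> float:
        return (
            -((s - self.mean) ** 2) / (2.0 * self.variance)
            - 0.5 * math.log(2.0 * math.pi * self.variance)
        )


@dataclass(frozen=True)
class ModelSetup:
    """Prior, likelihood variance, and prediction error of one scenario.

    ``prediction_error`` is ``delta = eta - o >= 0``; every downstream gain
    depends on ``delta`` only through ``delta^2``, so the nonnegative
    half-line loses no generality.
    """

    prior: GaussianBelief
    lik_variance: float
    prediction_error: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lik_variance > 0.0) or not math.isfinite(self.lik_variance):
            raise ParameterError(
                f"lik_variance must be a positive finite number, got {self.lik_variance!r}"
            )
        if not math.isfinite(self.prediction_error) or self.prediction_error < 0.0:
            raise ParameterError(
                f"prediction_error must be finite and >= 0, got {self.prediction_error!r}"
            )

    @property
    def total_variance(self) -> float:
        """Variance of the predictive marginal, sigma_p^2 + sigma_l^2."""
        return self.prior.variance + self.lik_variance

    @property
    def observation(self) -> float:
        """The observation implied by the prediction error: o = eta - delta."""
        return self.prior.mean - self.prediction_error


@dataclass(frozen=True)
class GainCoefficients:
    """Quadratic coefficients of the no-noise gains in the prediction error.

    ``KLD(delta) = a_kld * delta^2 + b_kld`` and
    ``BS(delta) = a_bs * delta^2 + b_bs``, all in nats.  Both slope
    coefficients are positive for any positive variances, so without a
    noise floor both gains grow without bound in the prediction error.
    """

    a_kld: float
    b_kld: float
    a_bs: float
    b_bs: float


def posterior_params(setup: ModelSetup, observation: float) -> GaussianBelief:
    """Conjugate Gaussian posterior ``p(s|o) = N(eta_post, s_post)``.

    ``s_post = sigma_p^2 sigma_l^2 / (sigma_p^2 + sigma_l^2)`` and
    ``eta_post = (sigma_p^2 o + sigma_l^2 eta) / (sigma_p^2 + sigma_l^2)``;
    the posterior variance is always below both input variances.
    """
    sp2 = setup.prior.variance
    sl2 = setup.lik_variance
    total = sp2 + sl2
    s_post = sp2 * sl2 / total
    eta_post = (sp2 * observation + sl2 * setup.prior.mean) / total
    return GaussianBelief(mean=eta_post, variance=s_post)


def evidence_kernel(setup: ModelSetup) -> float:
    """Model evidence under the kernel convention, ``e(delta)`` in (0, 1].

    ``e(delta) = exp(-delta^2 / (2 (sigma_p^2 + sigma_l^2)))``: equal to 1
    at zero prediction error and decaying to 0 as the likelihood peak moves
    away from the prior mean.
    """
    d = setup.prediction_error
    return math.exp(-(d * d) / (2.0 * setup.total_variance))


def gaussian_surprise(setup: ModelSetup) -> float:
    """Shannon surprise ``-ln e(delta) = delta^2 / (2 (sigma_p^2 + sigma_l^2))``.

    A quadratic function of the prediction error; zero iff ``delta = 0``.
    """
    d = setup.prediction_error
    return (d * d) / (2.0 * setup.total_variance)


def gain_coefficients(prior_variance: float, lik_variance: float) -> GainCoefficients:
    """Coefficients of the closed-form (no noise floor) gain quadratics.

    Derived from the Gaussian-Gaussian KL divergence between the prior
    ``N(eta, sigma_p^2)`` and the conjugate posterior:

    * ``a_kld = sigma_p^2 / (2 sigma_l^2 (sigma_p^2 + sigma_l^2))``
    * ``b_kld = ln(sigma_l^2 / (sigma_p^2 + sigma_l^2)) / 2 + sigma_p^2 / (2 sigma_l^2)``
    * ``a_bs  = sigma_p^2 / (2 (sigma_p^2 + sigma_l^2)^2)``
    * ``b_bs  = ln((sigma_p^2 + sigma_l^2) / sigma_l^2) / 2 - sigma_p^2 / (2 (sigma_p^2 + sigma_l^2))``
    """
    if not (prior_variance > 0.0):
        raise ParameterError(f"prior_variance must be > 0, got {prior_variance!r}")
    if not (lik_variance > 0.0):
        raise ParameterError(f"lik_variance must be > 0, got {lik_variance!r}")
    sp2, sl2 = prior_variance, lik_variance
    total = sp2 + sl2
    a_kld = sp2 / (2.0 * sl2 * total)
    b_kld = 0.5 * math.log(sl2 / total) + sp2 / (2.0 * sl2)
    a_bs = sp2 / (2.0 * total * total)
    b_bs = 0.5 * math.log(total / sl2) - sp2 / (2.0 * total)
    return GainCoefficients(a_kld=a_kld, b_kld=b_kld, a_bs=a_bs, b_bs=b_bs)


def kld_closed(setup: ModelSetup) -> float:
    """Recognition gain without a noise floor: ``D_KL[p(s) || p(s|o)]``.

    A strictly increasing quadratic of the prediction error,
    ``a_kld delta^2 + b_kld``.
    """
    c = gain_coefficients(setup.prior.variance, setup.lik_variance)
    d = setup.prediction_error
    return c.a_kld * d * d + c.b_kld


def bs_closed(setup: ModelSetup) -> float:
    """Bayesian surprise without a noise floor: ``D_KL[p(s|o) || p(s)]``.

    A strictly increasing quadratic of the prediction error,
    ``a_bs delta^2 + b_bs``.
    """
    c = gain_coefficients(setup.prior.variance, setup.lik_variance)
    d = setup.prediction_error
    return c.a_bs * d * d + c.b_bs


def kl_gaussians(p: GaussianBelief, q: GaussianBelief) -> float:
    """Closed-form KL divergence ``D_KL[p || q]`` between two Gaussians.

    ``ln(sigma_q / sigma_p) + (sigma_p^2 + (mu_p - mu_q)^2) / (2 sigma_q^2) - 1/2``;
    zero iff the two beliefs coincide.  Asymmetric whenever the variances
    differ.
    """
    dm = p.mean - q.mean
    return (
        0.5 * math.log(q.variance / p.variance)
        + (p.variance + dm * dm) / (2.0 * q.variance)
        - 0.5
    )


def perceived_uncertainty(setup: ModelSetup, observation: float) -> float:
    """Expected negative log-likelihood under the exact Gaussian posterior.

    ``U = -<ln p(o|s)>_{p(s|o)}`` with the *normalized* Gaussian
    likelihood density.  Together with the Bayesian surprise it recovers
    the normalized Shannon surprise: ``-ln p(o) = BS + U``, where
    ``-ln p(o) = ln(2 pi (sigma_p^2 + sigma_l^2)) / 2
    + delta^2 / (2 (sigma_p^2 + sigma_l^2))``.
    """
    sl2 = setup.lik_variance
    post = posterior_params(setup, observation)
    resid = observation - post.mean
    return 0.5 * (_LOG_2PI + math.log(sl2)) + (post.variance + resid * resid) / (
        2.0 * sl2
    )
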