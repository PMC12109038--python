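"""Predictive and expected free-energy decompositions for a Gaussian policy.

A policy is represented only through the Gaussian state prior it induces,
``q(s|pi) = N(eta_pi, sigma_p^2)``, observed through a Gaussian likelihood
of variance ``sigma_l^2``.  The predictive observation marginal is then
``q(o|pi) = N(eta_pi, sigma_p^2 + sigma_l^2)`` and every quantity below
has a closed form:

* predictive recognition gain ``pKLD = E_{q(o|pi)}[KLD(delta(o))]``,
* predictive Bayesian surprise ``pBS = I(s; o | pi)`` (mutual information),
* ambiguity = expected conditional observation entropy ``<H(o|s)>``,
* risk = ``D_KL[q(o|pi) || p(o|C)]`` against an observation preference,
* expected free energy ``G = risk + ambiguity``.

Unlike the recognition-side modules, everything here uses properly
normalized densities: mutual information and entropies are
convention-dependent, and the identities below (predictive entropy = pBS +
ambiguity) only hold in the normalized convention.  All values in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError
from .gaussian import GaussianBelief, gain_coefficients, kl_gaussians

__all__ = [
    "PolicyModel",
    "predictive_kld",
    "mutual_information",
    "ambiguity",
    "risk",
    "expected_free_energy",
    "predictive_entropy",
]

_LOG_2PI_E = math.log(2.0 * math.pi) + 1.0


@dataclass(frozen=True)
class PolicyModel:
    """Gaussian state prior induced by a policy, plus optional preference."""

    state_prior: GaussianBelief
    lik_variance: float
    preference: GaussianBelief | None = None

    def __post_init__(self) -> None:
        if not (self.lik_variance > 0.0) or not math.isfinite(self.lik_variance):
            raise ParameterError(
                f"lik_variance must be a positive finite number, got {self.lik_variance!r}"
            )

    @property
    def predictive_marginal(self) -> GaussianBelief:
        """Predicted observation distribution q(o|pi)."""
        return GaussianBelief(
            mean=self.state_prior.mean,
            variance=self.state_prior.variance + self.lik_variance,
        )


def predictive_kld(pm: PolicyModel) -> float:
    """Expected recognition gain over predicted observations.

    The no-noise recognition gain is quadratic in the prediction error,
    ``a_kld delta^2 + b_kld``, and under the predictive marginal
    ``E[delta^2] = sigma_p^2 + sigma_l^2``, so
    ``pKLD = a_kld (sigma_p^2 + sigma_l^2) + b_kld``.
    """
    sp2 = pm.state_prior.variance
    sl2 = pm.lik_variance
    c = gain_coefficients(sp2, sl2)
    return c.a_kld * (sp2 + sl2) + c.b_kld


def mutual_information(pm: PolicyModel) -> float:
    """Predictive Bayesian surprise = state-observation mutual information.

    For the Gaussian channel, ``I(s; o | pi) = ln((sigma_p^2 + sigma_l^2)
    / sigma_l^2) / 2``: zero when the prior carries no variance, growing as
    observations become relatively more precise.
    """
    return 0.5 * math.log((pm.state_prior.variance + pm.lik_variance) / pm.lik_variance)


def ambiguity(pm: PolicyModel) -> float:
    """Expected conditional observation entropy ``<H(o|s)>_{q(s|pi)}``.

    The Gaussian conditional entropy is constant in the state:
    ``ln(2 pi e sigma_l^2) / 2``.
    """
    return 0.5 * (_LOG_2PI_E + math.log(pm.lik_variance))


def predictive_entropy(pm: PolicyModel) -> float:
    """Entropy of the predictive marginal, ``H(o|pi)``.

    Decomposes exactly as mutual information plus ambiguity.
    """
    return 0.5 * (_LOG_2PI_E + math.log(pm.predictive_marginal.variance))


def risk(pm: PolicyModel) -> float:
    """Divergence of predicted observations from the preference.

    ``D_KL[q(o|pi) || p(o|C)]``; zero iff the predictive marginal equals
    the preferred observation distribution.
    """
    if pm.preference is None:
        raise ParameterError("risk requires a preference distribution")
    return kl_gaussians(pm.predictive_marginal, pm.preference)


def expected_free_energy(pm: PolicyModel) -> float:
    """Expected free energy ``G = risk + ambiguity``."""
    return risk(pm) + ambiguity(pm)
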