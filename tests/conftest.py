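import pytest

from wundtgain import GaussianBelief, NoisyLikelihood, find_optima

# The worked-example regime used throughout: wide prior, precise
# observations, default noise floor.
FIG_PRIOR_VAR = 10.0
FIG_LIK_VAR = 1.0
FIG_EPS = 1e-3


@pytest.fixture(scope="session")
def fig_prior() -> GaussianBelief:
    return GaussianBelief(mean=0.0, variance=FIG_PRIOR_VAR)


@pytest.fixture(scope="session")
def fig_noise() -> NoisyLikelihood:
    return NoisyLikelihood(lik_variance=FIG_LIK_VAR, eps=FIG_EPS)


@pytest.fixture(scope="session")
def fig_optima(fig_prior, fig_noise):
    """Gain-function peaks of the worked-example regime, computed once."""
    return find_optima(fig_prior, fig_noise)
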