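"""Alternating-curiosity inquiry cycle around the optimal arousal level.

Between the two gain peaks (``delta_KLD < delta < delta_BS``) the
recognition gain falls while the Bayesian surprise rises, so both cannot
be maximized at once.  Diversive curiosity (novelty seeking) jumps the
prediction error up to ``delta_BS``; specific curiosity (evidence seeking)
jumps it down to ``delta_KLD``.  Strict alternation produces a standing
surprise oscillation of amplitude ``D_S = S_BS - S_KLD`` straddling the
total-gain optimum ``S_IG``.  The jumps are idealized one-step moves to
each optimum — the magnitude of the fluctuation, not its transient
dynamics, is the quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .gaussian import GaussianBelief, ModelSetup
from .gains import OptimumSummary, find_optima
from .mixture import NoisyLikelihood, bs_mixture, kld_mixture, mixture_surprise

__all__ = ["CycleStep", "CycleTrace", "simulate_cycle", "DIVERSIVE", "SPECIFIC"]

DIVERSIVE = "diversive"
SPECIFIC = "specific"


@dataclass(frozen=True)
class CycleStep:
    step: int
    phase: str
    delta: float
    surprise: float
    kld: float
    bs: float
    ig: float


@dataclass(frozen=True)
class CycleTrace:
    """Deterministic trace of the alternating maximization."""

    steps: tuple[CycleStep, ...]
    optima: OptimumSummary
    start_delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "phase": s.phase,
                    "delta": s.delta,
                    "surprise": s.surprise,
                    "kld": s.kld,
                    "bs": s.bs,
                    "ig": s.ig,
                }
                for s in self.steps
            ]
        )

    @property
    def surprise_amplitude(self) -> float:
        """Peak-to-trough surprise swing of the settled oscillation."""
        vals = [s.surprise for s in self.steps]
        return max(vals) - min(vals)

    @property
    def delta_amplitude(self) -> float:
        vals = [s.delta for s in self.steps]
        return max(vals) - min(vals)


def simulate_cycle(
    prior: GaussianBelief,
    noise: NoisyLikelihood,
    n_steps: int,
    start_delta: float = 0.0,
    start_phase: str | None = None,
) -> CycleTrace:
    """Alternate diversive and specific jumps for ``n_steps`` steps.

    Each diversive step sets the prediction error to ``delta_BS``, each
    specific step to ``delta_KLD``, with all gains recomputed at the new
    point.  When ``start_phase`` is omitted it defaults to diversive if the
    starting surprise is below ``S_KLD`` (climbing the arousal curve from
    the boredom side) and specific otherwise.
    """
    if n_steps < 2:
        raise ParameterError(f"n_steps must be >= 2, got {n_steps!r}")
    if start_phase is not None and start_phase not in (DIVERSIVE, SPECIFIC):
        raise ParameterError(
            f"start_phase must be {DIVERSIVE!r} or {SPECIFIC!r}, got {start_phase!r}"
        )
    if not (start_delta >= 0.0) or not math.isfinite(start_delta):
        raise ParameterError(f"start_delta must be finite and >= 0, got {start_delta!r}")

    opt = find_optima(prior, noise)
    if start_phase is None:
        setup0 = ModelSetup(
            prior=prior, lik_variance=noise.lik_variance, prediction_error=start_delta
        )
        s0 = mixture_surprise(setup0, noise)
        start_phase = DIVERSIVE if s0 < opt.s_kld else SPECIFIC

    steps: list[CycleStep] = []
    phase = start_phase
    for i in range(1, n_steps + 1):
        delta = opt.delta_bs if phase == DIVERSIVE else opt.delta_kld
        setup = ModelSetup(
            prior=prior, lik_variance=noise.lik_variance, prediction_error=delta
        )
        s = mixture_surprise(setup, noise)
        k = kld_mixture(setup, noise)
        b = bs_mixture(setup, noise)
        steps.append(
            CycleStep(step=i, phase=phase, delta=delta, surprise=s, kld=k, bs=b, ig=k + b)
        )
        phase = SPECIFIC if phase == DIVERSIVE else DIVERSIVE

    return CycleTrace(steps=tuple(steps), optima=opt, start_delta=start_delta)
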