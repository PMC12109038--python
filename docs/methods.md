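# Methods

## Model

A single-observation Gaussian observer: latent state s with prior
p(s) = N(η, σp²), observed through a Gaussian likelihood of variance σl².
The conjugate posterior is N(η_post, s_post) with
s_post = σp²σl²/(σp²+σl²) and η_post = (σp² o + σl² η)/(σp²+σl²). All
quantities depend on the observation only through the prediction error
δ = η − o, and on δ only through δ², so the public surface exposes δ ≥ 0.

The contribution modeled here is the uniform noise floor on the
likelihood: p_ε(o|s) = α(exp(−(o−s)²/2σl²) + ε), α = 1/(1+ε). The floor
stands in for spontaneous baseline activity far from the likelihood mode,
where a pure Gaussian (Laplace-approximation) likelihood would assert
essentially zero response probability. It makes the posterior a
two-component mixture of the conjugate posterior and the prior, and turns
both information gains — the recognition gain KLD = D_KL[prior‖posterior]
and the Bayesian surprise BS = D_KL[posterior‖prior] — into single-peaked
(inverted-U) functions of the prediction error and of surprise.

## Conventions

Two normalization conventions coexist deliberately:

- **Kernel convention** (recognition-side modules `gaussian`, `mixture`,
  `gains`, `sweep`, `inquiry`): the likelihood is the unnormalized kernel
  with peak height 1, so the evidence is e(δ) = exp(−δ²/2(σp²+σl²)) with
  e(0) = 1, the surprise −ln(α(e(δ)+ε)) is exactly 0 at δ = 0 and
  saturates at ln((1+ε)/ε), and the mixture weights are
  w_post = e/(e+ε), w_pri = ε/(e+ε). This is the only convention in which
  the evidence, surprise, and weight formulas are mutually consistent, and
  it is the convention all gain curves and optima use. ε is then a
  dimensionless floor relative to the kernel peak.
- **Normalized convention** (`perceived_uncertainty` and the whole
  `predictive` module): proper densities throughout, because entropies and
  mutual information are normalization-dependent. In this convention the
  exact identities hold: −ln p(o) = BS + U (surprise = Bayesian surprise
  plus perceived uncertainty) and H(o|π) = pBS + ambiguity.

All information quantities are in nats.

## Scale invariance and the uncertainty trends

Under the kernel convention the model has an exact symmetry: scaling both
variances (and δ²) by a common factor leaves e(δ), the weights, and every
KL divergence unchanged. Consequently every optimum — max KLD/BS/IG, the
optimal surprises S_KLD/S_BS/S_IG, and D_S — is a function of the variance
ratio r = σp²/σl² alone, and the optimal prediction errors scale as
σl^… · g(r). The test suite asserts this invariance directly.

This symmetry constrains which monotone uncertainty trends can exist.
S_KLD decreases monotonically in r, so it falls with prior variance and
rises with likelihood variance; S_IG behaves the same way; max IG and D_S
increase monotonically in r. S_BS, however, is *unimodal* in r (peaking
near r ≈ 5): it first rises and then falls as the prior widens at fixed
likelihood variance, and mirror-image along the likelihood-variance axis.
A claim that S_BS rises monotonically with prior variance *and* with
likelihood variance would require opposite monotonicities of the same
one-variable function and is therefore impossible in this convention; the
trend report states the component results truthfully instead of forcing
them. (A floor added to a *normalized* density rather than to the
kernel breaks the symmetry by an entropy offset ~½ln(2π(σp²+σl²)), which
is one way monotone-looking S_BS curves can arise; that variant is not
implemented because it is inconsistent with the kernel evidence and the
zero-surprise-at-zero-error property.)

## Numerical choices

- **Mixture KL divergences** (no closed form): adaptive quadrature
  (`scipy.integrate.quad`, epsabs 1e-12, epsrel 1e-10, limit 400) of
  p·ln(p/q) over an interval covering both mixture components to ±12
  standard deviations, with breakpoints at each component mean ±{0, 2, 6}
  SD to force subdivision at both scales. The integrand is evaluated from
  *log*-densities (logsumexp for the mixture) so that the log ratio stays
  exact where a narrow component underflows in linear space — without
  this, KL against a much narrower density loses mass ~1e-2. Results in
  [−1e-9, 0] are clamped to 0 (round-off); a larger negative value or an
  unconverged quadrature raises `NumericalError`.
- **Vanishing-floor limit**: as ε → 0 the mixture gains approach the
  closed-form quadratics, but the floor caps the prior-tail contribution
  to KLD, and the gap decays like (ε/e(δ))^(σl²/σp²) (up to log factors).
  At ε = 10⁻¹² the agreement is ≤1e-6 only when the likelihood is at
  least about twice as wide as the prior; oracle tests use such combos and
  a separate test documents the slow convergence for wide priors. BS
  converges fast for all variance ratios (its outer density has the thin
  posterior tails).
- **Vanishing gains at large δ**: both gains → 0 once e(δ) ≪ ε, but BS
  lags the evidence by a log factor (BS ≈ w_post·(A_BS δ² + B_BS)), so it
  crosses 1e-6 somewhat beyond the point where e(δ) = ε·10⁻⁶; a test
  records this.
- **Peak location**: a 160-point pre-scan on [0, δ_hi] selects a
  bracketing interval, then bounded Brent search (golden section plus
  parabolic interpolation, `minimize_scalar`, xatol 1e-7) refines it.
  δ_hi = 3·√(2(σp²+σl²)ln(1/ε)) — three times the evidence/floor
  switchover scale, which the peaks never exceed. Maxima flat to within
  1e-9 resolve to the smallest δ; a peak within tolerance of a bound is
  flagged "non-interior" in the result. The pre-scan guards the
  unimodality assumption of the local search, which holds empirically but
  is not proven.
- **Unimodality checks on tabulated curves** use a peak-prominence floor
  of 1e-7: quadrature round-off creates ~1e-16-scale wiggles in the
  vanished tail that are not model structure.
- **Default grids**: gain curves use 400 mixed log/linear points on
  [0, δ_hi]; variance sweeps default to step 1.0 over [1, 50]² (2,500
  cells, minutes of compute), with finer steps (e.g. 0.1, ≈240k cells)
  available behind an explicit flag with progress logging. The audits run
  by the tests and by `scripts/acceptance.py` use 10×10 (orderings) and
  5×5 (trends) grids over the same ranges.
- **Trend monotonicity** tolerates inversions below 1e-6 absolute
  (quadrature/optimizer noise); everything larger counts as a violation.

## Parameters

| parameter | meaning | default |
|---|---|---|
| η | prior mean (state units); only δ matters | 0 |
| σp² | prior (prediction) variance | 10 (CLI) |
| σl² | likelihood (observation) variance | 1 (CLI) |
| δ | prediction error, η − o, ≥ 0 | — |
| ε | uniform likelihood floor, in (0,1) | 10⁻³ |

ε = 10⁻³ is the working default throughout; the oracle tests use 10⁻¹²
for the vanishing-floor limit. Sweep ranges default to [1, 50] for both
variances.

## Inquiry cycle

The alternating-curiosity simulator takes the model's description of
curiosity dynamics at face value: a diversive step jumps the prediction
error to δ_BS, a specific step to δ_KLD, with every gain recomputed at the
new point. The oscillation is persistent by construction (no amplitude
decay) because the quantity of interest is the standing fluctuation
magnitude D_S = S_BS − S_KLD (and D_δ = δ_BS − δ_KLD), which the trace
reproduces to optimizer tolerance; gradient-based or learning dynamics are
out of scope. The default start phase is diversive when the starting
surprise is below S_KLD (climbing from the boredom side), specific
otherwise.

## Limitations

- Univariate Gaussian state and likelihood only; no hierarchical or
  non-Gaussian generative models, no sequential multi-observation
  learning, no discrete policy search (policies enter only through the
  Gaussian prior they induce).
- The noise floor is an improper uniform: ε is treated as a constant added
  to the kernel, following the model's formal algebra; the posterior over
  s is a proper density regardless.
- The mixture KLs rely on quadrature; at extreme floors (ε ≤ 1e-30) the
  quadrature error estimate can be optimistic in the far-tail log-capped
  region. All shipped analyses operate at ε ≥ 1e-12 where this is
  irrelevant.
- The model is analytic — there is no synthetic data and no empirical
  fit; every number the package reports is a property of the equations at
  the stated parameters.
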