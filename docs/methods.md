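# Methods

## The model

`nowiw` implements a four-parameter lifetime distribution built by the
"new odd Weibull" generator over an inverse Weibull baseline, together
with an interval-valued (neutrosophic) layer for indeterminate data.

Let `H(x) = exp(-k x^-n)` be the inverse Weibull CDF (scale `k > 0`,
shape `n > 0`) and define the monotone transform

    g(x) = -H(x) log(1 - H(x)).

The NOWIW CDF with generator scale `eta > 0` and shape `zeta > 0` is

    F(x) = 1 - exp(-eta g(x)^zeta),      x > 0,

with density

    f(x) = eta zeta k n x^-(n+1) e^{-k x^-n}
           [H/(1-H) - log(1-H)] g^{zeta-1} e^{-eta g^zeta}.

The survival function is evaluated directly as `exp(-eta g^zeta)`, never
as `1 - F`, and the hazard as its closed form, so the identities
`sf + cdf = 1` and `hazard * sf = pdf` hold to near machine precision and
are enforced by tests.

**Tail behaviour.** Since `1 - H(x) ~ k x^-n` for large `x`,
`g(x) ~ n log x - log k`, so `S(x) ~ exp(-eta (n log x)^zeta)`.  The
family is therefore sub-exponential for every parameter value:

* `zeta > 1`: faster than any polynomial — all moments finite;
* `zeta = 1`: polynomial tail `x^{-eta n}` — the r-th moment exists iff
  `r < eta n`;
* `zeta < 1`: slower than any polynomial — every positive moment
  diverges.

This tail rule is the implemented moment-existence criterion (for
`zeta < 1` a dyadic tail-window growth test confirms it numerically).  A
closed-form criterion based on `Gamma((r-n)/n)` alone would ignore `eta`
and `zeta` and is not used.  Because the upper tail is sub-exponential,
`E[e^{tX}] = infinity` for every `t > 0`; a moment generating function is
deliberately not exposed, and the characteristic function is computed
numerically instead.

## Interval (neutrosophic) semantics

Indeterminate quantities are ordered intervals `[lower, upper]`;
degenerate intervals recover the classical objects bit for bit.  The
lifting is *endpoint-wise*: lower parameter slice with lower data series,
upper with upper.  This matches how interval-valued fitted tables and
curves are conventionally presented.  It is not interval arithmetic: the
two endpoint curves need not enclose curves for interior parameter
values, and the package documents rather than hides this.

After an interval fit, each parameter is reported as the interval spanned
by the two endpoint estimates, sorted so lower <= upper.  The raw
per-endpoint estimates are retained (`FitResult.endpoint_fits`) because
the sorted slices are no longer the endpoint fits whenever estimates
cross — on the battery data the inverse Weibull shape estimates do cross
(0.419 on the lower series vs 0.409 on the upper) — and all downstream
goodness-of-fit and criteria computations use the raw fits.

## Numerics

* **Safe inner transform.** With `t = k x^-n` computed in log space,
  `log(1-H)` is evaluated as `log1p(-H)` when `H < 1/2` and as
  `log(-expm1(-t))` otherwise; both tails (`H -> 0`, `H -> 1`) are then
  accurate without the catastrophic cancellation of the naive forms.  The
  density is assembled fully in log space; extreme lower-tail points where
  `x^-(n+1)` would overflow return density exactly 0 (the exponential
  factor dominates).
* **Quantile.** `F(x) = p` reduces to the scalar monotone equation
  `psi(s) = s(1 - e^-s) = A` with `A = (-log(1-p)/eta)^{1/zeta}` and
  `s = -log(1-H)`; the solver is vectorized Newton (60 iterations max,
  relative tolerance 1e-14) with a bracketed Brent fallback on any entry
  that fails its residual check.  Round-trip accuracy is ~1e-15 in
  probability.  A Lambert-W closed form sometimes quoted for this quantile is kept only as the
  quarantined diagnostic `quantile_paper`: its `W_{-1}(A e^A)` argument is
  positive for every admissible `p`, outside the real domain `[-1/e, 0)`
  of that branch, so the evaluation returns a flagged NaN status rather
  than a value; sampling and estimation never touch it.
* **Quadrature.** Moments, incomplete moments, probability-weighted
  moments, `J(c) = int f^c` and the characteristic function integrate on
  the compactified domain `x = u/(1-u)` with adaptive Gauss–Kronrod
  (`scipy.integrate.quad`, limit 200).  Divergence detection compares
  mass in successive dyadic windows `[2^j, 2^{j+1})`: a median
  window-ratio above 0.75 over the last six windows flags a divergent
  tail.
* **Entropies.** Renyi, Tsallis, Havrda–Charvat and Arimoto entropies are
  the four standard transforms of the same `J(c)`:
  `log(J)/(1-c)`, `(1-J)/(c-1)`, `(J^{1/c}-1)/(2^{1-c}-1)` and
  `c/(1-c) (J^{1/c}-1)`.

## Estimation

Three estimators for point-valued samples (sample size is written `m`
throughout; `n` is the inverse Weibull shape):

* **MLE** maximizes the closed-form log-likelihood.  The `x`-exponent
  term is `-(n+1) sum log x`, consistent with the density's `x^-(n+1)`
  factor; the identity `loglik == sum(log pdf)` is a test invariant.
* **LSE** minimizes `sum_i [F(x_(i)) - i/(m+1)]^2` over the ordered
  sample, with the standard plotting positions `i/(m+1)`.
* **WLSE** adds the reciprocal order-statistic variance weights
  `(m+1)^2 (m+2) / (i (m-i+1))`, symmetric in `i <-> m-i+1`.

Optimization is in log-parameter space (positivity is free), confined to
the admissible box `[1e-3, 1e3]` per parameter: 20 Latin-stratified
seeded starts in `[0.05, 10]`, L-BFGS-B from each, then a bounded
Nelder-Mead polish of the best point.  Ties in sorting are broken by
stable original order.  All randomness flows from the config seed; a
refit with the same seed reproduces the result exactly.

**Why the admissible box.** The four-parameter family is weakly
identified: the likelihood has long curved ridges along which very
different parameter vectors give nearly the same distribution.
Unconstrained optimization can escape to degenerate corners (observed:
`k` estimates beyond 1e100 on simulated data).  The box is wide enough to
contain every fit reported by this package by a large margin while
cutting off the degenerate escapes.

## The Monte Carlo study

`run_monte_carlo` simulates interval samples at an interval-valued truth,
fits each endpoint series, and accumulates per-parameter per-endpoint
mean, bias and RMSE.  Two protocol choices matter and are deliberate:

* **Endpoint-coupled sampling.** One uniform stream drives both parameter
  slices; observation `i` is the interval spanned by the two endpoint
  quantiles at the same `u_i`, sorted per observation.  This preserves
  within-observation ordering and makes degenerate parameter intervals
  produce exactly degenerate data.
* **Truth-started local fits.** Each replication's fit starts at the true
  parameter values (the consistent-root convention for weakly identified
  likelihoods) rather than using the global multistart.  At the default
  study truth, the ridge geometry is such that globally better likelihood
  optima exist far from the truth even at `m = 200` and even when the
  search is started at the truth with a gradient method; a global search
  would therefore measure the optimizer's ridge-hopping, not the
  estimator.  With the local protocol, RMSE decreases markedly with
  sample size for every parameter and endpoint, which is the study's
  qualitative claim.

Failed or non-finite fits are dropped and counted; a cell with more than
20% failures is flagged unreliable.  The whole summary is bit-reproducible
given the design and seed (seeds are spawned per size and replication
from one `SeedSequence`).  The reference design uses sizes 20/50/100/200
with 1000 replications; the test suite runs 100 replications at sizes 20
and 200, which already separates the RMSE cells by 1–2 orders of
magnitude.

## Series expansions (experimental)

The formal expansions of `F`, `f` and the raw moments (outer exponential
series, inner powers of `L/H = -log(1-H)/H` via the J.C.P. Miller
recursion `d_{a,j} = (1/j) sum_{m=1..j} (m(a+1)-j)/(m+1) d_{a,j-m}`,
`d_{a,0} = 1`) are implemented with explicit truncation, a remainder
estimate combining the last outer band and the extrapolated inner tails,
and a conservative status flag.  They are cross-checks only; quadrature
is authoritative.  Findings worth stating plainly:

* the CDF/PDF series converge fast for `H` not too close to 1 (agreement
  with quadrature to ~1e-12 at default truncation) and degrade as
  `H -> 1`, which the remainder estimate reports honestly;
* the term-wise moment series is valid only for `r < n` (term-wise
  integrability) and is numerically unusable in general: thin-tail
  parameter sets make the alternating outer bands grow enormously before
  factorial decay (cancellation), while heavy-tail sets put the moment
  mass exactly where the inner series converge only conditionally.  At
  particular truncations it can agree with quadrature to ~1e-4 relative
  in asymptotic-series fashion; the `diagnose` command records such a
  comparison without ever labelling it converged.

## Model comparison machinery

Information criteria (natural logs): `AIC = 2k + 2 NLL`,
`CAIC = AIC + 2k(k+1)/(m-k-1)`, `BIC = 2 NLL + k log m`,
`HQIC = 2k log(log m) + 2 NLL`.  Goodness of fit: K-S
(`max_i max(i/m - u_i, u_i - (i-1)/m)`), Cramer–von Mises
(`1/(12m) + sum (u_i - (2i-1)/(2m))^2`) and Anderson–Darling in its
standard form `-m - (1/m) sum (2i-1)[log u_i + log(1-u_{m+1-i})]`; the
small-sample modified variants (`A^2 (1 + 0.75/m + 2.25/m^2)`,
`W^2 (1 + 0.5/m)`) are emitted alongside because published tables do not
always say which was used.  K-S p-values use the exact finite-sample
Kolmogorov distribution for `m <= 100` and the asymptotic series beyond.
GoF is computed against the CDF fitted on the same data, with no
re-estimation penalty — the conventional, slightly optimistic practice;
p-values should be read comparatively.

Descriptives are endpoint-wise: sd with divisor `m-1`, 10% trimmed mean
per side, MAD scaled by 1.4826, moment-based skewness `g1` and excess
kurtosis `g2`, `se = sd/sqrt(m)`.

The six comparison models (inverse Weibull and its beta, Kumaraswamy,
exponentiated-generalized, log-gamma and Gompertz extensions) carry
analytic densities verified against numeric differentiation of their
CDFs.  Two competitor CDFs are often quoted in forms that are not valid
distribution functions; the package uses the standard family forms instead (Gompertz-G
with `eta/zeta` in the exponent; log-gamma-G as the increasing
`P(eta, -zeta log(1-G))`), which is recorded in the comparison caveats.

## What the synthetic generator does and does not emulate

The generator draws exactly from the model at stated interval parameters
with endpoint coupling.  Real interval data (like the battery lifetimes)
need not satisfy either assumption: observed interval widths embody
measurement indeterminacy, not a parametric coupling, and the data need
not follow the model at all.  Passing simulation tests therefore
demonstrate correctness of the sampling/fitting loop and finite-sample
estimator behaviour under the model, not adequacy of the model for any
real dataset — that is what the goodness-of-fit machinery is for.

## Known limitations

* Weak identifiability is intrinsic to the family; reported parameter
  estimates should be read as one representative of a near-equivalence
  ridge.  Likelihood values, criteria and GoF statistics are stable
  across the ridge; individual parameters are not.
* Endpoint-wise interval semantics carry no enclosure guarantee for
  interior parameter values.
* No censoring support, no standard errors or confidence intervals, no
  Bayesian estimation.
* GoF p-values are not bootstrap-calibrated for parameter estimation.
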