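"""Experimental series representations of the NOWIW CDF, PDF and moments.

The distribution admits formal double/triple series obtained by expanding
``exp(-eta g^zeta)`` as a power series and the powers of
``L(H) = -log(1-H) = H * sum_{m>=0} H^m/(m+1)`` by the J.C.P. Miller
power-of-a-series recursion

    d_{a,0} = 1,
    d_{a,j} = (1/j) * sum_{m=1..j} (m(a+1) - j)/(m+1) * d_{a,j-m},

so that ``(L/H)^a = sum_j d_{a,j} H^j``.  The resulting expansions are

    F(x) = 1 - sum_{i,j} (-1)^i eta^i/i! d_{i zeta, j} H^{2 i zeta + j}

    f(x) = zeta k n x^-(n+1) sum_{i,j,p} (-1)^i eta^{i+1}/i!
               d_{i zeta + zeta - 1, j} c_p H^{2(i+1) zeta + j + p - 1}

with ``H = exp(-k x^-n)`` and ``c_p = 1 + 1/p`` (p >= 1) collecting the two
positive pieces of the bracket H/(1-H) - log(1-H) (geometric and log
series).  These series converge only where the inner H-expansions do; this
module therefore truncates explicitly, tracks a Cauchy-style remainder
(the magnitude of the last included index band), and reports a status
instead of trusting the partial sum.  The quadrature implementations in
:mod:`nowiw.distribution` are authoritative everywhere; nothing outside the
diagnostics path calls this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy import special

from .distribution import NOWIWParams

__all__ = ["SeriesCoefficients", "d_coefficients", "cdf_series", "pdf_series",
           "moment_series"]


def d_coefficients(alpha: float, j_max: int) -> np.ndarray:
    """d_{alpha, 0..j_max} for (L/H)^alpha per the power-of-a-series recursion."""
    d = np.zeros(j_max + 1)
    d[0] = 1.0  # base case of the recursion
    for j in range(1, j_max + 1):
        m = np.arange(1, j + 1)
        d[j] = np.sum((m * (alpha + 1.0) - j) / (m + 1.0) * d[j - m]) / j
    return d


@dataclass
class SeriesCoefficients:
    """Truncation orders and cached coefficient tables for the expansions."""

    i_max: int = 20
    j_max: int = 20
    p_max: int = 20
    z_max: int = 20
    band_tol: float = 1e-12
    d_table: dict = field(default_factory=dict)

    def d(self, alpha: float) -> np.ndarray:
        key = round(float(alpha), 12)
        if key not in self.d_table:
            self.d_table[key] = d_coefficients(alpha, self.j_max)
        return self.d_table[key]


def _band_sum_cdf(i: int, coeffs: SeriesCoefficients, x: float,
                  params: NOWIWParams):
    """(band value, inner-truncation remainder) of outer index i for the CDF."""
    eta, zeta, k, n = params.eta, params.zeta, params.k, params.n
    logH = -k * x ** (-n)
    H = np.exp(logH)
    d = coeffs.d(i * zeta)
    j = np.arange(coeffs.j_max + 1)
    terms = d * np.exp((2.0 * i * zeta + j) * logH)
    coef = np.exp(i * np.log(eta) - lgamma(i + 1)) if i > 0 else 1.0
    # geometric-style bound on the dropped j-tail (d_j is slowly varying)
    inner_rem = coef * abs(terms[-1]) * H / max(1.0 - H, 1e-12)
    return (-1.0) ** i * coef * np.sum(terms), inner_rem


def cdf_series(x: float, params: NOWIWParams,
               coeffs: SeriesCoefficients | None = None) -> dict:
    """Truncated series CDF with remainder estimate and convergence status."""
    coeffs = coeffs or SeriesCoefficients()
    if x <= 0:
        raise ValueError("x must be positive")
    bands = [_band_sum_cdf(i, coeffs, x, params) for i in range(coeffs.i_max + 1)]
    return _assemble(bands, lambda s: 1.0 - s, coeffs)


def _assemble(bands, finalize, coeffs: SeriesCoefficients,
              rel_tol: float | None = None) -> dict:
    """Partial-sum (band, inner_rem) pairs with early stopping and growth detection.

    The reported remainder estimate is the magnitude of the last included
    outer band plus the inner-truncation bound accumulated over the bands
    actually used; "converged" requires both pieces to be small — in
    absolute terms (1e-6) by default, or relative to the value when
    ``rel_tol`` is given (the moment path, whose inner sums decay only
    polynomially).
    """
    total = 0.0
    inner_total = 0.0
    mags = []
    overflow = False
    for b, inner in bands:
        if not np.isfinite(b):
            overflow = True
            break
        total += b
        inner_total += inner  # may legitimately be inf (inner sums unconverged)
        mags.append(abs(b))
        if abs(b) < coeffs.band_tol and len(mags) >= 2:
            break
    used = len(mags)
    # alternating bands may legitimately grow before factorial decay sets in;
    # "diverged" means they are still growing when the terms run out
    growing = (used >= 3 and mags[-1] > mags[-2] > mags[-3]
               and mags[-1] > coeffs.band_tol)
    if overflow or used == 0 or growing:
        return {"value": float("nan"), "remainder_estimate": float("inf"),
                "status": "diverged", "bands_used": used}
    value = float(finalize(total))
    # last outer band + inner truncation + cancellation loss at the band peak
    remainder = float(mags[-1] + inner_total + max(mags) * 1e-15)
    threshold = 1e-6 if rel_tol is None else rel_tol * max(abs(value), 1e-12)
    status = "converged" if remainder <= threshold else "not-converged"
    return {"value": value, "remainder_estimate": remainder,
            "status": status, "bands_used": used}


def _pdf_band(i: int, coeffs: SeriesCoefficients, x: float,
              params: NOWIWParams):
    eta, zeta, k, n = params.eta, params.zeta, params.k, params.n
    logH = -k * x ** (-n)
    H = np.exp(logH)
    alpha = i * zeta + zeta - 1.0
    d = coeffs.d(alpha)
    j = np.arange(coeffs.j_max + 1)
    p = np.arange(1, coeffs.p_max + 1)
    cp = 1.0 + 1.0 / p  # geometric + log-series bracket weights
    grid = (d[:, None] * cp[None, :]
            * np.exp((2.0 * (i + 1) * zeta + j[:, None] + p[None, :] - 1.0) * logH))
    lead = zeta * k * n * x ** (-(n + 1.0))
    coef = lead * np.exp((i + 1) * np.log(eta) - lgamma(i + 1))
    geom = H / max(1.0 - H, 1e-12)
    inner_rem = coef * (np.abs(grid[-1, :]).sum() + np.abs(grid[:, -1]).sum()) * geom
    return (-1.0) ** i * coef * np.sum(grid), inner_rem


def pdf_series(x: float, params: NOWIWParams,
               coeffs: SeriesCoefficients | None = None) -> dict:
    """Truncated series PDF; same contract as :func:`cdf_series`."""
    coeffs = coeffs or SeriesCoefficients()
    if x <= 0:
        raise ValueError("x must be positive")
    bands = [_pdf_band(i, coeffs, x, params) for i in range(coeffs.i_max + 1)]
    return _assemble(bands, lambda s: s, coeffs)


def moment_series(r: int, params: NOWIWParams,
                  coeffs: SeriesCoefficients | None = None) -> dict:
    """Series r-th raw moment via term-wise integration.

    Each series term integrates to (1/n)(c k)^((r-n)/n) Gamma((n-r)/n) with
    c the term's H-exponent; term-wise integration requires r < n (each
    term is integrable at infinity only then) and Gamma((n-r)/n) must avoid
    poles.  Outside that region the status says so and no value is
    asserted.  Compared against the quadrature moment in diagnostics, never
    trusted on its own.
    """
    coeffs = coeffs or SeriesCoefficients()
    if r < 1:
        raise ValueError("r must be >= 1")
    eta, zeta, k, n = params.eta, params.zeta, params.k, params.n
    gamma_arg = (n - r) / n
    if r > n:
        return {"value": float("nan"), "status": "outside-termwise-validity"}
    if r == n or (gamma_arg <= 0 and float(gamma_arg).is_integer()):
        return {"value": float("nan"), "status": "undefined-by-formula"}
    gam = special.gamma(gamma_arg)
    power = (r - n) / n

    def _poly_tail(slices: np.ndarray, J: int) -> float:
        """Extrapolated tail of a ~ j^-sigma slice sequence beyond index J."""
        a_last, a_half = abs(slices[-1]), abs(slices[len(slices) // 2])
        if a_last <= 0:
            return 0.0
        if a_half <= a_last:  # not decaying
            return float("inf")
        sigma = np.log(a_half / a_last) / np.log(J / (J // 2))
        if sigma <= 1.05:
            return float("inf")
        return a_last * J / (sigma - 1.0)

    def band(i):
        alpha = i * zeta + zeta - 1.0
        d = coeffs.d(alpha)
        j = np.arange(coeffs.j_max + 1)
        p = np.arange(1, coeffs.p_max + 1)
        cp = 1.0 + 1.0 / p
        c = 2.0 * (i + 1) * zeta + j[:, None] + p[None, :] - 1.0
        with np.errstate(over="ignore", invalid="ignore"):
            grid = d[:, None] * cp[None, :] * np.power(c * k, power)
        coef = zeta * k * np.exp((i + 1) * np.log(eta) - lgamma(i + 1))
        # individual terms far larger than the O(1) result mean the
        # alternating d-sums cancel below machine precision: cut off there
        scale = coef * abs(gam) * np.max(np.abs(grid))
        if not np.isfinite(scale) or scale > 1e8:
            return None
        inner_rem = coef * abs(gam) * (
            _poly_tail(np.abs(grid).sum(axis=1), coeffs.j_max)
            + _poly_tail(np.abs(grid).sum(axis=0), coeffs.p_max))
        return (-1.0) ** i * coef * np.sum(grid) * gam, inner_rem

    bands = []
    for i in range(coeffs.i_max + 1):
        b = band(i)
        if b is None:  # d-sum cancellation limit reached; truncate outer sum
            break
        bands.append(b)
    out = _assemble(bands, lambda s: s, coeffs, rel_tol=5e-3)
    return {"value": out["value"], "status": out["status"],
            "remainder_estimate": out["remainder_estimate"]}
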