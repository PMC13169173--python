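"""Comparison models from the inverse Weibull family.

Six lifetime models used to benchmark the NOWIW fit, all built on the
inverse Weibull CDF ``G(x) = exp(-k x^(-n))``:

====== ======================================================== ========
name   CDF                                                      params
====== ======================================================== ========
niw    G                                                        k, n
beiw   I_G(eta, zeta)  (regularized incomplete beta at G)       eta, zeta, k, n
kuiw   1 - (1 - G^eta)^zeta  (Kumaraswamy-G)                    eta, zeta, k, n
egiw   (1 - (1-G)^eta)^zeta  (exponentiated generalized-G)      eta, zeta, k, n
lgamiw P(eta, -zeta log(1-G))  (log-gamma-G)                    eta, zeta, k, n
goiw   1 - exp{(eta/zeta)[1 - (1-G)^(-zeta)]}  (Gompertz-G)     eta, zeta, k, n
====== ======================================================== ========

Densities are analytic chain-rule derivatives of the CDFs (verified against
numeric differentiation in the test suite).  Fitting reuses the multistart
MLE engine from :mod:`nowiw.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .estimation import FitConfig, FitResult, _check_data, multistart_minimize

__all__ = ["CompetitorSpec", "REGISTRY", "competitor_cdf", "competitor_logpdf",
           "competitor_fit"]


def _iw_parts(x, k, n):
    """(G, 1-G, log G, log g_iw) for the inverse Weibull baseline."""
    x = np.asarray(x, dtype=float)
    t = k * x ** (-n)
    G = np.exp(-t)
    one_m_G = -np.expm1(-t)
    log_g = np.log(k) + np.log(n) - (n + 1.0) * np.log(x) - t
    return G, one_m_G, -t, log_g


def _cdf_niw(x, th):
    k, n = th
    return np.exp(-k * np.asarray(x, float) ** (-n))


def _logpdf_niw(x, th):
    k, n = th
    x = np.asarray(x, float)
    with np.errstate(over="ignore"):
        return np.log(k) + np.log(n) - (n + 1.0) * np.log(x) - k * x ** (-n)


def _cdf_beiw(x, th):
    eta, zeta, k, n = th
    G, _, _, _ = _iw_parts(x, k, n)
    return special.betainc(eta, zeta, G)


def _logpdf_beiw(x, th):
    eta, zeta, k, n = th
    G, omG, logG, log_g = _iw_parts(x, k, n)
    with np.errstate(divide="ignore"):
        return (log_g + (eta - 1.0) * logG + (zeta - 1.0) * np.log(omG)
                - special.betaln(eta, zeta))


def _cdf_kuiw(x, th):
    eta, zeta, k, n = th
    G, _, logG, _ = _iw_parts(x, k, n)
    return -np.expm1(zeta * np.log1p(-np.exp(eta * logG)))


def _logpdf_kuiw(x, th):
    eta, zeta, k, n = th
    G, _, logG, log_g = _iw_parts(x, k, n)
    with np.errstate(divide="ignore"):
        return (np.log(eta) + np.log(zeta) + log_g + (eta - 1.0) * logG
                + (zeta - 1.0) * np.log1p(-np.exp(eta * logG)))


def _cdf_egiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, _ = _iw_parts(x, k, n)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return np.exp(zeta * np.log1p(-omG ** eta))


def _logpdf_egiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, log_g = _iw_parts(x, k, n)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        return (np.log(eta) + np.log(zeta) + log_g + (eta - 1.0) * np.log(omG)
                + (zeta - 1.0) * np.log1p(-omG ** eta))


def _cdf_lgamiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, _ = _iw_parts(x, k, n)
    with np.errstate(divide="ignore"):
        u = -zeta * np.log(omG)
    return special.gammainc(eta, u)


def _logpdf_lgamiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, log_g = _iw_parts(x, k, n)
    with np.errstate(divide="ignore"):
        u = -zeta * np.log(omG)
        return ((eta - 1.0) * np.log(u) - u - special.gammaln(eta)
                + np.log(zeta) + log_g - np.log(omG))


def _cdf_goiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, _ = _iw_parts(x, k, n)
    with np.errstate(over="ignore"):
        return -np.expm1(eta / zeta * -np.expm1(-zeta * np.log(omG)))


def _logpdf_goiw(x, th):
    eta, zeta, k, n = th
    _, omG, _, log_g = _iw_parts(x, k, n)
    with np.errstate(divide="ignore", over="ignore"):
        return (np.log(eta) + log_g - (zeta + 1.0) * np.log(omG)
                + eta / zeta * -np.expm1(-zeta * np.log(omG)))


@dataclass(frozen=True)
class CompetitorSpec:
    """A named comparison model: CDF, log-density, parameter labels."""

    name: str
    n_params: int
    param_names: tuple
    cdf: callable
    logpdf: callable


REGISTRY = {
    "niw": CompetitorSpec("niw", 2, ("k", "n"), _cdf_niw, _logpdf_niw),
    "beiw": CompetitorSpec("beiw", 4, ("eta", "zeta", "k", "n"), _cdf_beiw, _logpdf_beiw),
    "kuiw": CompetitorSpec("kuiw", 4, ("eta", "zeta", "k", "n"), _cdf_kuiw, _logpdf_kuiw),
    "egiw": CompetitorSpec("egiw", 4, ("eta", "zeta", "k", "n"), _cdf_egiw, _logpdf_egiw),
    "lgamiw": CompetitorSpec("lgamiw", 4, ("eta", "zeta", "k", "n"), _cdf_lgamiw, _logpdf_lgamiw),
    "goiw": CompetitorSpec("goiw", 4, ("eta", "zeta", "k", "n"), _cdf_goiw, _logpdf_goiw),
}


def _get_spec(name: str) -> CompetitorSpec:
    try:
        return REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(f"unknown competitor {name!r}; choose from {sorted(REGISTRY)}")


def competitor_cdf(name: str, x, params):
    """CDF of a registered comparison model."""
    spec = _get_spec(name)
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(f"{spec.name} takes {spec.n_params} parameters, got {params.size}")
    if np.any(params <= 0):
        raise ValueError("all parameters must be strictly positive")
    return spec.cdf(x, tuple(params))


def competitor_logpdf(name: str, x, params):
    """Log-density of a registered comparison model."""
    spec = _get_spec(name)
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(f"{spec.name} takes {spec.n_params} parameters, got {params.size}")
    if np.any(params <= 0):
        raise ValueError("all parameters must be strictly positive")
    return spec.logpdf(x, tuple(params))


def competitor_fit(name: str, data, config: FitConfig | None = None) -> FitResult:
    """MLE fit of a comparison model with the shared multistart engine."""
    spec = _get_spec(name)
    config = config or FitConfig()
    data = _check_data(data)
    if data.size < spec.n_params + 1:
        raise ValueError(f"need at least {spec.n_params + 1} observations for {spec.name}")

    def neg(th):
        lp = spec.logpdf(data, tuple(np.exp(th)))
        lp = np.asarray(lp)
        if not np.all(np.isfinite(lp)):
            return np.inf
        return -float(np.sum(lp))

    x, fval, tried, ok = multistart_minimize(neg, spec.n_params, config)
    if not ok:
        return FitResult(method="mle", params_hat=None, objective=float("nan"),
                         converged=False, n_obs=data.size, starts_tried=tried,
                         seed=config.seed, message=f"{spec.name}: all starts failed")
    return FitResult(method="mle", params_hat=dict(zip(spec.param_names, np.exp(x))),
                     objective=-fval, converged=True, n_obs=data.size,
                     starts_tried=tried, seed=config.seed, message=spec.name)
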