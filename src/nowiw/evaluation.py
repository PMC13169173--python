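"""Model assessment: information criteria, goodness of fit, descriptives.

Everything here operates endpoint-wise on intervals: a statistic of an
interval sample is the pair (statistic of the lower-endpoint series,
statistic of the upper-endpoint series).

Conventions
-----------
* Information criteria use natural logs: AIC = 2k + 2*negloglik,
  CAIC = AIC + 2k(k+1)/(m-k-1), BIC = 2*negloglik + k log m,
  HQIC = 2k log(log m) + 2*negloglik.
* The Anderson-Darling statistic is computed in its standard form
  A^2 = -m - (1/m) sum (2i-1)[log u_i + log(1 - u_(m+1-i))]; the
  small-sample modified variants A^2 (1 + 0.75/m + 2.25/m^2) and
  W^2 (1 + 0.5/m) are reported alongside because published tables do not
  always say which was used.
* GoF statistics are computed against the CDF fitted on the same data
  (no re-estimation penalty); the K-S p-value is therefore approximate in
  the usual way and should be read comparatively.
* Descriptive skewness/kurtosis are the moment-based g1 and excess g2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .competitors import REGISTRY, competitor_fit
from .estimation import FitConfig, fit_neutrosophic
from .intervals import Interval, IntervalSample, split_sample

__all__ = [
    "FitAssessment",
    "DescriptiveStats",
    "information_criteria",
    "gof_statistics",
    "ks_pvalue",
    "describe",
    "compare_models",
]


@dataclass
class FitAssessment:
    """Per-model criteria and GoF block, interval-valued."""

    neg_loglik: Interval
    aic: Interval
    caic: Interval
    bic: Interval
    hqic: Interval
    k: int
    m: int
    ks: Interval = None
    ks_pvalue: Interval = None
    ad: Interval = None
    ad_modified: Interval = None
    cvm: Interval = None
    cvm_modified: Interval = None

    def to_dict(self) -> dict:
        out = {}
        for name, v in self.__dict__.items():
            out[name] = list(v.as_tuple()) if isinstance(v, Interval) else v
        return out


def _endpointwise(fn, nll: Interval) -> Interval:
    return Interval.from_sorted(fn(nll.lower), fn(nll.upper))


def information_criteria(neg_loglik, k: int, m: int) -> FitAssessment:
    """AIC/CAIC/BIC/HQIC from a (possibly interval-valued) negative loglik."""
    if m <= k + 1:
        raise ValueError("CAIC undefined: need m > k + 1")
    if not isinstance(neg_loglik, Interval):
        neg_loglik = Interval(neg_loglik, neg_loglik)
    aic = _endpointwise(lambda v: 2.0 * k + 2.0 * v, neg_loglik)
    caic = _endpointwise(lambda v: 2.0 * k + 2.0 * v + 2.0 * k * (k + 1) / (m - k - 1), neg_loglik)
    bic = _endpointwise(lambda v: 2.0 * v + k * np.log(m), neg_loglik)
    hqic = _endpointwise(lambda v: 2.0 * k * np.log(np.log(m)) + 2.0 * v, neg_loglik)
    return FitAssessment(neg_loglik=neg_loglik, aic=aic, caic=caic, bic=bic,
                         hqic=hqic, k=k, m=m)


def gof_statistics(data, fitted_cdf) -> dict:
    """K-S, Anderson-Darling and Cramer-von Mises against a fitted CDF.

    ``data`` must be sorted ascending.  Probability transforms exactly at 0
    or 1 are clamped to the nearest representable neighbourhood (with a
    warning) so the AD log terms stay finite.
    """
    x = np.asarray(data, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("data must be sorted ascending")
    m = x.size
    u = np.asarray(fitted_cdf(x), dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        warnings.warn("fitted cdf hit 0 or 1 at an observation; clamping", RuntimeWarning)
        tiny = np.finfo(float).tiny
        u = np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)
    i = np.arange(1, m + 1)
    ks = float(max((i / m - u).max(), (u - (i - 1) / m).max()))
    cvm = float(1.0 / (12.0 * m) + np.sum((u - (2 * i - 1) / (2.0 * m)) ** 2))
    ad = float(-m - np.sum((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))) / m)
    return {
        "ks": ks,
        "ad": ad,
        "ad_modified": ad * (1.0 + 0.75 / m + 2.25 / m ** 2),
        "cvm": cvm,
        "cvm_modified": cvm * (1.0 + 0.5 / m),
    }


def ks_pvalue(ks: float, m: int) -> float:
    """P(D_m >= ks) under the Kolmogorov null.

    Exact finite-sample distribution (matrix method) for m <= 100, the
    asymptotic Kolmogorov series beyond.
    """
    if not (0.0 <= ks <= 1.0):
        raise ValueError("ks must lie in [0, 1]")
    if ks == 0.0:
        return 1.0
    if ks == 1.0:
        return 0.0
    if m <= 100:
        return float(stats.kstwo.sf(ks, m))
    return float(stats.kstwobign.sf(np.sqrt(m) * ks))


@dataclass
class DescriptiveStats:
    """Endpoint-wise descriptive statistics of an interval sample."""

    m: int
    mean: Interval
    sd: Interval
    median: Interval
    trimmed_mean: Interval
    mad: Interval
    min: Interval
    max: Interval
    range: Interval
    skewness: Interval
    kurtosis: Interval
    se: Interval

    def to_dict(self) -> dict:
        return {k: (list(v.as_tuple()) if isinstance(v, Interval) else v)
                for k, v in self.__dict__.items()}


def describe(sample: IntervalSample) -> DescriptiveStats:
    """Table of descriptive statistics, one value per interval endpoint.

    sd uses divisor m-1; trimmed mean drops 10% per side; MAD is scaled by
    1.4826 (consistent for the normal); skewness is the biased g1 and
    kurtosis the excess g2.
    """
    lower, upper = split_sample(sample)
    m = lower.size

    def stats_of(v):
        constant = np.ptp(v) == 0.0
        return dict(
            mean=np.mean(v),
            sd=np.std(v, ddof=1),
            median=np.median(v),
            trimmed_mean=stats.trim_mean(v, 0.1),
            mad=stats.median_abs_deviation(v, scale="normal"),
            min=np.min(v),
            max=np.max(v),
            range=np.ptp(v),
            skewness=0.0 if constant else stats.skew(v, bias=True),
            kurtosis=0.0 if constant else stats.kurtosis(v, fisher=True, bias=True),
            se=np.std(v, ddof=1) / np.sqrt(m),
        )

    lo, up = stats_of(lower), stats_of(upper)
    pairs = {k: Interval.from_sorted(lo[k], up[k]) for k in lo}
    return DescriptiveStats(m=m, **pairs)


def _assess_endpointwise(series_pair, cdf_pair, nll: Interval, k: int, m: int) -> FitAssessment:
    out = information_criteria(nll, k, m)
    blocks = []
    for series, fitted in zip(series_pair, cdf_pair):
        x = np.sort(series, kind="stable")
        g = gof_statistics(x, fitted)
        g["ks_pvalue"] = ks_pvalue(g["ks"], m)
        blocks.append(g)
    for key in ("ks", "ks_pvalue", "ad", "ad_modified", "cvm", "cvm_modified"):
        setattr(out, key, Interval.from_sorted(blocks[0][key], blocks[1][key]))
    return out


def compare_models(sample: IntervalSample, model_names, config: FitConfig | None = None) -> dict:
    """Fit several models per endpoint and rank them by lower-endpoint AIC.

    ``model_names`` may include "nowiw" (the four-parameter model of this
    package) and any key of the competitor registry.  Per-model failures
    are recorded and the comparison proceeds with the survivors.
    """
    names = [n.lower() for n in model_names]
    if len(names) < 2:
        raise ValueError("model comparison needs at least 2 models")
    config = config or FitConfig()
    lower, upper = split_sample(sample)
    m = len(sample)
    report = {"models": {}, "failures": {}, "m": m,
              "config": {"starts": config.starts, "seed": config.seed,
                         "tol": config.tol, "max_iter": config.max_iter}}
    for name in names:
        try:
            if name == "nowiw":
                fit = fit_neutrosophic(sample, "mle", config)
                if not all(fit.converged):
                    raise RuntimeError("endpoint fit failed")
                k = 4
                nll = Interval.from_sorted(-fit.objective.lower, -fit.objective.upper)
                from .distribution import cdf as _cdf
                p_lo, p_up = fit.endpoint_fits
                cdf_pair = (lambda x, pp=p_lo: _cdf(x, pp),
                            lambda x, pp=p_up: _cdf(x, pp))
                params_out = {f: list(getattr(fit.params_hat, f).as_tuple())
                              for f in ("eta", "zeta", "k", "n")}
            elif name in REGISTRY:
                spec = REGISTRY[name]
                f_lo = competitor_fit(name, lower, config)
                f_up = competitor_fit(name, upper, config)
                if not (f_lo.converged and f_up.converged):
                    raise RuntimeError("endpoint fit failed")
                k = spec.n_params
                nll = Interval.from_sorted(-f_lo.objective, -f_up.objective)
                th_lo = tuple(f_lo.params_hat[pn] for pn in spec.param_names)
                th_up = tuple(f_up.params_hat[pn] for pn in spec.param_names)
                cdf_pair = (lambda x, th=th_lo, s=spec: s.cdf(x, th),
                            lambda x, th=th_up, s=spec: s.cdf(x, th))
                params_out = {pn: sorted([f_lo.params_hat[pn], f_up.params_hat[pn]])
                              for pn in spec.param_names}
            else:
                raise ValueError(f"unknown model {name!r}")
            assessment = _assess_endpointwise((lower, upper), cdf_pair, nll, k, m)
            entry = assessment.to_dict()
            entry["params"] = params_out
            report["models"][name] = entry
        except Exception as exc:  # failures recorded, comparison proceeds
            report["failures"][name] = str(exc)
    ranked = sorted(report["models"], key=lambda n: report["models"][n]["aic"][0])
    report["ranking"] = ranked
    return report
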