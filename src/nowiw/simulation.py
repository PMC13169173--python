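"""Random variate generation and the Monte Carlo estimator study.

Sampling is by inverse transform through the numeric quantile.  Interval
samples are endpoint-coupled: one uniform stream drives both parameter
slices, so observation i is the interval spanned by
``quantile(u_i; lower slice)`` and ``quantile(u_i; upper slice)`` (sorted
per observation).  Coupling preserves within-observation ordering and makes
degenerate parameter intervals produce exactly degenerate data.

``run_monte_carlo`` replays the estimator study design: for each sample
size and replication, simulate an interval sample at the truth, fit with
each requested method, and accumulate per-parameter per-endpoint mean,
bias and RMSE.  Failed fits are dropped and counted; a cell with more than
20% failures is flagged unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import NOWIWParams, quantile
from .estimation import FitConfig, fit_lse, fit_mle, fit_wlse
from .intervals import Interval, IntervalSample, NeutroParams

__all__ = ["MonteCarloDesign", "MonteCarloSummary", "rvs", "rvs_neutrosophic",
           "run_monte_carlo"]

_FITTERS = {"mle": fit_mle, "lse": fit_lse, "wlse": fit_wlse}
_PARAM_FIELDS = ("eta", "zeta", "k", "n")


def rvs(params: NOWIWParams, m: int, seed) -> np.ndarray:
    """m inverse-transform draws from the NOWIW distribution, reproducible per seed."""
    if m < 0:
        raise ValueError("m must be nonnegative")
    rng = np.random.default_rng(seed)
    if m == 0:
        return np.empty(0)
    u = rng.random(m)
    return np.asarray(quantile(u, params))


def rvs_neutrosophic(params: NeutroParams, m: int, seed) -> IntervalSample:
    """Endpoint-coupled interval sample: one uniform stream, two parameter slices."""
    if m < 0:
        raise ValueError("m must be nonnegative")
    rng = np.random.default_rng(seed)
    if m == 0:
        return IntervalSample(observations=())
    u = rng.random(m)
    lo = np.asarray(quantile(u, params.lower()))
    up = np.asarray(quantile(u, params.upper()))
    obs = tuple(Interval(min(a, b), max(a, b)) for a, b in zip(lo, up))
    return IntervalSample(observations=obs, label=f"simulated(m={m})")


@dataclass(frozen=True)
class MonteCarloDesign:
    """Truth, sample sizes, replication count, methods and master seed."""

    truth: NeutroParams
    sample_sizes: tuple = (20, 50, 100, 200)
    replications: int = 1000
    methods: tuple = ("mle",)
    seed: int = 0
    # each fit is started at the data-generating truth: the study measures
    # the local estimator around the truth (the consistent-root convention
    # for weakly identified likelihoods); extra starts would chase distant
    # ridge optima and measure the optimizer, not the estimator
    fit_starts: int = 1

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.sample_sizes)
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if any(s <= 0 for s in sizes) or any(np.diff(sizes) <= 0):
            raise ValueError("sample sizes must be positive and increasing")
        bad = set(m.lower() for m in self.methods) - set(_FITTERS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        object.__setattr__(self, "sample_sizes", sizes)
        object.__setattr__(self, "methods", tuple(m.lower() for m in self.methods))


@dataclass
class MonteCarloSummary:
    """Tidy per-cell summary (size, method, parameter, endpoint -> mean/bias/rmse)."""

    table: pd.DataFrame
    failed: dict = field(default_factory=dict)
    design_seed: int = 0

    def cell(self, size: int, method: str, parameter: str, endpoint: str) -> dict:
        t = self.table
        row = t[(t["size"] == size) & (t["method"] == method)
                & (t["parameter"] == parameter) & (t["endpoint"] == endpoint)]
        return row.iloc[0].to_dict()


def run_monte_carlo(design: MonteCarloDesign) -> MonteCarloSummary:
    """Execute the design; deterministic given (design, seed)."""
    truth = design.truth
    truth_vals = {
        "lower": truth.lower().as_array(),
        "upper": truth.upper().as_array(),
    }
    rows = []
    failed = {}
    seeds = np.random.SeedSequence(design.seed).spawn(len(design.sample_sizes))
    for size_seed, m in zip(seeds, design.sample_sizes):
        rep_seeds = size_seed.spawn(design.replications)
        samples = [rvs_neutrosophic(truth, m, s) for s in rep_seeds]
        for method in design.methods:
            fitter = _FITTERS[method]
            ests = {ep: [] for ep in ("lower", "upper")}
            n_fail = 0
            for rep, sample in enumerate(samples):
                ok = True
                got = {}
                for ep, series in zip(("lower", "upper"),
                                      (np.array([o.lower for o in sample]),
                                       np.array([o.upper for o in sample]))):
                    cfg = FitConfig(starts=design.fit_starts, seed=design.seed + rep,
                                    init=tuple(truth_vals[ep]))
                    fit = fitter(series, cfg)
                    if not fit.converged or fit.params_hat is None:
                        ok = False
                        break
                    got[ep] = fit.params_hat.as_array()
                if ok:
                    for ep in ("lower", "upper"):
                        ests[ep].append(got[ep])
                else:
                    n_fail += 1
            failed[(m, method)] = n_fail
            unreliable = n_fail > 0.2 * design.replications
            for ep in ("lower", "upper"):
                est = np.array(ests[ep])
                for j, pname in enumerate(_PARAM_FIELDS):
                    th0 = truth_vals[ep][j]
                    if est.size == 0:
                        mean = bias = rmse = float("nan")
                    else:
                        mean = float(np.mean(est[:, j]))
                        bias = mean - th0
                        rmse = float(np.sqrt(np.mean((est[:, j] - th0) ** 2)))
                    rows.append(dict(size=m, method=method, parameter=pname,
                                     endpoint=ep, mean=mean, bias=bias,
                                     rmse=rmse, n_failed=n_fail,
                                     unreliable=unreliable))
    return MonteCarloSummary(table=pd.DataFrame(rows), failed=failed,
                             design_seed=design.seed)
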