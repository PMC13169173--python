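"""Interval semantics for neutrosophic quantities.

A neutrosophic quantity carries an explicit indeterminacy component and is
encoded here as an ordered interval ``[lower, upper]``; a degenerate
interval (``lower == upper``) recovers the classical, point-valued object.
Parameters and observations are lifted endpoint-wise: the lower-endpoint
slice of the parameters pairs with the lower-endpoint series of the data,
and likewise for the upper endpoints.  This is the convention the model's
tables and fitted curves follow; it is *not* interval arithmetic, and the
endpoint curves need not bound the curves of interior parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distribution import NOWIWParams, cdf, hazard, pdf, sf

__all__ = [
    "Interval",
    "NeutroParams",
    "IntervalSample",
    "endpoint_slices",
    "neutro_curve",
    "split_sample",
]


@dataclass(frozen=True)
class Interval:
    """Ordered pair [lower, upper] with both endpoints finite."""

    lower: float
    upper: float

    def __post_init__(self):
        lo, up = float(self.lower), float(self.upper)
        if not (np.isfinite(lo) and np.isfinite(up)):
            raise ValueError("interval endpoints must be finite")
        if lo > up:
            raise ValueError(f"interval lower {lo} exceeds upper {up}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def degenerate(self) -> bool:
        return self.lower == self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def as_tuple(self):
        return (self.lower, self.upper)

    @classmethod
    def from_sorted(cls, a: float, b: float) -> "Interval":
        """Build an interval from two values in either order."""
        return cls(min(a, b), max(a, b))

    def __format__(self, spec: str) -> str:
        spec = spec or ".5f"
        return f"[{self.lower:{spec}}, {self.upper:{spec}}]"

    def __str__(self) -> str:
        return format(self, ".5f")


@dataclass(frozen=True)
class NeutroParams:
    """Interval-valued NOWIW parameters; endpoint slices are valid NOWIWParams."""

    eta: Interval
    zeta: Interval
    k: Interval
    n: Interval

    def __post_init__(self):
        for name in ("eta", "zeta", "k", "n"):
            iv = getattr(self, name)
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
                object.__setattr__(self, name, iv)
            if iv.lower <= 0:
                raise ValueError(f"NeutroParams.{name} lower endpoint must be > 0")

    @property
    def degenerate(self) -> bool:
        return all(getattr(self, f).degenerate for f in ("eta", "zeta", "k", "n"))

    def lower(self) -> NOWIWParams:
        return NOWIWParams(self.eta.lower, self.zeta.lower, self.k.lower, self.n.lower)

    def upper(self) -> NOWIWParams:
        return NOWIWParams(self.eta.upper, self.zeta.upper, self.k.upper, self.n.upper)

    @classmethod
    def from_point(cls, p: NOWIWParams) -> "NeutroParams":
        return cls(Interval(p.eta, p.eta), Interval(p.zeta, p.zeta),
                   Interval(p.k, p.k), Interval(p.n, p.n))


@dataclass(frozen=True)
class IntervalSample:
    """Ordered collection of interval observations (the neutrosophic dataset)."""

    observations: tuple
    label: str = ""

    def __post_init__(self):
        obs = tuple(o if isinstance(o, Interval) else Interval(*o)
                    for o in self.observations)
        for i, o in enumerate(obs):
            if o.lower <= 0:
                raise ValueError(f"observation {i} has non-positive lower endpoint")
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)


def endpoint_slices(p: NeutroParams):
    """(lower-slice, upper-slice) of interval parameters; equal when degenerate."""
    return p.lower(), p.upper()


_CURVES = {"cdf": cdf, "pdf": pdf, "sf": sf, "hazard": hazard}


def neutro_curve(fn: str, x_grid, p: NeutroParams) -> dict:
    """Evaluate a distribution function at both parameter slices over a grid.

    Returns the lower-slice curve, upper-slice curve and the pointwise
    min/max envelope.  The envelope is of the two endpoint curves only; no
    enclosure is claimed for interior parameter values.
    """
    if fn not in _CURVES:
        raise ValueError(f"fn must be one of {sorted(_CURVES)}")
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be positive and strictly increasing")
    f = _CURVES[fn]
    lo_curve = np.asarray(f(x, p.lower()))
    up_curve = np.asarray(f(x, p.upper()))
    return {
        "x": x,
        "lower_params_curve": lo_curve,
        "upper_params_curve": up_curve,
        "band_min": np.minimum(lo_curve, up_curve),
        "band_max": np.maximum(lo_curve, up_curve),
    }


def split_sample(s: IntervalSample):
    """Project an interval sample onto its (lower, upper) endpoint series.

    Pure projection: observation order is preserved, nothing is sorted or
    deduplicated.
    """
    if len(s) == 0:
        raise ValueError("sample is empty")
    lower = np.array([o.lower for o in s.observations])
    upper = np.array([o.upper for o in s.observations])
    return lower, upper
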