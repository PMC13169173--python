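"""Reading and writing interval samples.

CSV dialect: header ``lower,upper``, one observation per row, decimal
point, UTF-8.  A single-column file is accepted and promoted to degenerate
intervals (classical data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalSample

__all__ = ["read_interval_csv", "write_interval_csv"]


def read_interval_csv(path) -> IntervalSample:
    """Parse a one- or two-column CSV into an IntervalSample, preserving row order."""
    df = pd.read_csv(path)
    if df.shape[1] not in (1, 2):
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric value in table: {exc}") from exc
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values))[0][0])
        raise ValueError(f"{path}: missing value in row {bad + 1}")
    obs = []
    for idx, row in enumerate(values):
        lo = float(row[0])
        up = float(row[-1])
        if lo > up:
            raise ValueError(f"{path}: row {idx + 1} has lower {lo} > upper {up}")
        try:
            obs.append(Interval(lo, up))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 1}: {exc}") from exc
    sample = IntervalSample(observations=tuple(obs), label=str(path))
    return sample


def write_interval_csv(sample: IntervalSample, path) -> None:
    """Write a sample back to the two-column dialect (round-trips exactly)."""
    df = pd.DataFrame(
        {"lower": [o.lower for o in sample], "upper": [o.upper for o in sample]}
    )
    df.to_csv(path, index=False)
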