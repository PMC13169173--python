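"""Bundled interval-valued datasets."""

from __future__ import annotations

from .intervals import Interval, IntervalSample

__all__ = ["BATTERY_INTERVALS", "battery_lifetimes"]

# Lifetimes of 23 batteries, in units of 100 hours, recorded as
# [lower, upper] intervals reflecting measurement indeterminacy.
BATTERY_INTERVALS = (
    (2.9, 3.99), (5.24, 7.2), (6.56, 9.02), (7.14, 9.82), (11.6, 15.96),
    (12.14, 16.69), (12.65, 17.4), (13.24, 18.21), (13.67, 18.79),
    (13.88, 19.09), (15.64, 21.51), (17.05, 23.45), (17.4, 23.93),
    (17.8, 24.48), (19.01, 26.14), (19.34, 26.59), (23.13, 31.81),
    (23.34, 32.09), (26.07, 35.84), (30.29, 41.65), (43.97, 60.46),
    (48.09, 66.13), (73.48, 98.04),
)


def battery_lifetimes() -> IntervalSample:
    """The 23 battery-lifetime intervals (unit: 100 hours)."""
    return IntervalSample(
        observations=tuple(Interval(a, b) for a, b in BATTERY_INTERVALS),
        label="battery lifetimes (100 h), 23 intervals",
    )
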