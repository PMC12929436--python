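"""Thermal-time accumulation and small experimental-design arithmetic.

Thermal time (growing degree-days, °Cd) is accumulated as the sum over
calendar days of ``max(0, daily mean temperature - base)``, with base 0 °C
by default.  Partial first/last days inside the requested window use the
mean of the readings that fall within the window.  A per-reading
integration alternative (each reading weighted by its cadence as a fraction
of a day) is available via ``method="per_reading"``; it is exactly additive
over arbitrary window splits, whereas the daily-mean convention is additive
only across midnight-aligned boundaries.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .types import TemperatureLog, ValidationError

__all__ = [
    "accumulate_thermal_time",
    "planting_density",
    "ThermalGapWarning",
]


class ThermalGapWarning(UserWarning):
    """A gap exceeding twice the expected cadence was found in the log."""


def accumulate_thermal_time(
    log: TemperatureLog,
    start,
    end,
    base_temp: float = 0.0,
    method: str = "daily_mean",
) -> float:
    """Accumulated thermal time (°Cd) above ``base_temp`` over [start, end).

    Parameters
    ----------
    log : TemperatureLog
        Temperature readings; the window must lie within the log span.
    start, end : timestamp-like
        Half-open accumulation window; ``start < end``.
    base_temp : float
        Base temperature in °C (default 0).
    method : {"daily_mean", "per_reading"}
        Daily-mean-above-base (default, the conventional °Cd definition) or
        per-reading integration weighted by cadence.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if start >= end:
        raise ValidationError("start must precede end")
    if start < log.start or end > log.end + log.cadence:
        raise ValidationError(
            f"window [{start}, {end}) outside log span "
            f"[{log.start}, {log.end}]"
        )

    window = log.series[(log.series.index >= start) & (log.series.index < end)]
    if len(window) == 0:
        raise ValidationError("no readings fall within the window")

    gaps = window.index.to_series().diff().dropna()
    if (gaps > 2 * log.cadence).any():
        worst = gaps.max()
        warnings.warn(
            f"temperature log has a gap of {worst} (cadence {log.cadence}); "
            "linear coverage assumed across the gap",
            ThermalGapWarning,
            stacklevel=2,
        )

    if method == "per_reading":
        frac_day = log.cadence / pd.Timedelta(days=1)
        return float(
            np.maximum(0.0, window.to_numpy() - base_temp).sum() * frac_day
        )
    if method != "daily_mean":
        raise ValueError(f"unknown method {method!r}")

    daily_means = window.groupby(window.index.normalize()).mean()
    return float(np.maximum(0.0, daily_means.to_numpy() - base_temp).sum())


def planting_density(pots: int, area_m2: float) -> int:
    """Plants per m², rounded half-up to the nearest integer.

    The reference tent holds 35 pots on 0.64 m², i.e. 55 plants/m².
    """
    if area_m2 <= 0:
        raise ValidationError("area_m2 must be > 0")
    if pots < 0:
        raise ValidationError("pots must be >= 0")
    density = Decimal(pots) / Decimal(str(area_m2))
    return int(density.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
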