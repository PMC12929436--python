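"""Speed-breeding lighting energy and cost ledger.

Shortening the daily photoperiod from the conventional 22 h speed-breeding
standard to a genotype-tailored value cuts LED lighting demand in direct
proportion.  The reference fixture is a 0.65 kW LED unit covering 8 sq ft;
run 3,000 h/yr over a 15-year service life it consumes 29,250 kWh (the
lifetime bookkeeping convention).  Annual per-fixture savings instead use a
365-day operating year, the convention under which a one-hour daily cut
saves 0.65 x 365 = 237.25 kWh; the two conventions are deliberately kept
side by side and never mixed.

Rounding is fixed per quantity so printed figures are bit-reproducible:
per-hour percentage truncated (not rounded) to 2 decimals, percentage
reductions rounded half-up to integers, kWh reported half-up to the
nearest unit, facility costs reported to the nearest 1,000 currency units.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from typing import Optional

from .types import ValidationError

__all__ = [
    "EnergyScenario",
    "lifetime_consumption",
    "hourly_fraction_saving",
    "fractional_saving",
    "annual_fixture_saving",
    "facility_cost_saving",
    "energy_report",
]


@dataclass(frozen=True)
class EnergyScenario:
    """Lighting scenario: fixture, photoperiods, tariff, facility geometry."""

    reduced_photoperiod_h: float
    baseline_photoperiod_h: float = 22.0
    fixture_power_kw: float = 0.65
    fixture_area_sqft: float = 8.0
    days_per_year: int = 365
    tariff_per_kwh: float = 0.22
    facility_area_sqft: Optional[float] = None
    annual_operating_hours: float = 3000.0
    lifetime_years: int = 15
    currency: str = "£"

    def __post_init__(self) -> None:
        if not (0.0 <= self.reduced_photoperiod_h
                < self.baseline_photoperiod_h <= 24.0):
            raise ValidationError(
                "photoperiods must satisfy 0 <= reduced < baseline <= 24"
            )
        for name in ("fixture_power_kw", "fixture_area_sqft", "days_per_year",
                     "tariff_per_kwh", "annual_operating_hours",
                     "lifetime_years"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.facility_area_sqft is not None and self.facility_area_sqft < 0:
            raise ValidationError("facility_area_sqft must be non-negative")

    @property
    def delta_h(self) -> float:
        return self.baseline_photoperiod_h - self.reduced_photoperiod_h


def lifetime_consumption(power_kw: float, hours_per_year: float,
                         years: float) -> float:
    """Total kWh over a fixture's service life."""
    if min(power_kw, hours_per_year, years) < 0:
        raise ValidationError("all inputs must be >= 0")
    return power_kw * hours_per_year * years


def hourly_fraction_saving(baseline_h: float = 22.0) -> float:
    """Percent of daily lighting energy saved per hour of photoperiod cut,
    truncated to two decimals (100/22 -> 4.54)."""
    if baseline_h <= 0:
        raise ValidationError("baseline_h must be > 0")
    pct = Decimal(100) / Decimal(str(baseline_h))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def fractional_saving(scenario: EnergyScenario) -> int:
    """Percent reduction in daily lighting, rounded half-up to an integer."""
    pct = (Decimal(100)
           * Decimal(str(scenario.delta_h))
           / Decimal(str(scenario.baseline_photoperiod_h)))
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def annual_fixture_saving(scenario: EnergyScenario) -> float:
    """kWh saved per fixture per year (unrounded).

    fixture_power_kw x (baseline - reduced) x days_per_year; the reporting
    helper rounds half-up to the nearest kWh.
    """
    return (scenario.fixture_power_kw * scenario.delta_h
            * scenario.days_per_year)


def facility_cost_saving(scenario: EnergyScenario) -> float:
    """Annual cost saving for a whole facility (currency units, unrounded).

    Fixture count is the exact (possibly non-integer) ratio of facility
    area to per-fixture coverage.
    """
    if scenario.facility_area_sqft is None:
        raise ValidationError("facility_area_sqft must be set")
    n_fixtures = scenario.facility_area_sqft / scenario.fixture_area_sqft
    return n_fixtures * annual_fixture_saving(scenario) * scenario.tariff_per_kwh


def _round_half_up(x: float, quantum: str) -> float:
    return float(Decimal(str(x)).quantize(Decimal(quantum),
                                          rounding=ROUND_HALF_UP))


def energy_report(scenario: EnergyScenario) -> dict:
    """Raw and reporting-rounded figures for one scenario, side by side."""
    annual = annual_fixture_saving(scenario)
    report = {
        "scenario": {
            "baseline_photoperiod_h": scenario.baseline_photoperiod_h,
            "reduced_photoperiod_h": scenario.reduced_photoperiod_h,
            "delta_h": scenario.delta_h,
            "fixture_power_kw": scenario.fixture_power_kw,
            "fixture_area_sqft": scenario.fixture_area_sqft,
            "tariff_per_kwh": scenario.tariff_per_kwh,
            "currency": scenario.currency,
        },
        "lifetime_consumption_kwh": lifetime_consumption(
            scenario.fixture_power_kw, scenario.annual_operating_hours,
            scenario.lifetime_years,
        ),
        "hourly_fraction_saving_pct": hourly_fraction_saving(
            scenario.baseline_photoperiod_h
        ),
        "fractional_saving_pct": fractional_saving(scenario),
        "annual_fixture_saving_kwh": annual,
        "annual_fixture_saving_kwh_reported": _round_half_up(annual, "1"),
    }
    if scenario.facility_area_sqft is not None:
        cost = facility_cost_saving(scenario)
        report["facility_cost_saving"] = cost
        report["facility_cost_saving_reported_nearest_1000"] = _round_half_up(
            cost / 1000.0, "1") * 1000.0
        report["facility_cost_note"] = (
            "facility figures derive from exact fixture-count division; "
            "reported value rounds to the nearest 1,000 currency units"
        )
    return report
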