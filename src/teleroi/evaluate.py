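"""Scenario evaluation: net benefit, ROI, multi-year totals, breakeven.

For every (care model, site, year) the runner fills a cost cell (staffing
plus any travel-subsidy burden) and an income cell (activity-based funding),
each in whole dollars.  Multi-year totals are sums of the rounded yearly
cells, net benefit is total income minus total cost, and

    ROI (%) = 100 x (total income - total cost) / total cost.

Breakeven is the smallest whole number of attended appointments per clinic
whose income covers the per-clinic cost; a site with positive cost and no
income stream can never break even and is reported as unreachable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from ._money import round_cents, round_dollars, to_decimal
from .costs import annual_staff_cost, site_clinic_cost, travel_subsidy_cost
from .domain import ActivityYear, CareModel, DiscountSchedule, ScenarioBundle
from .funding import StreamsLike, annual_income, site_rate


class _Unreachable:
    """Sentinel: the site cannot recoup its costs at any attendance level."""

    _instance: Optional["_Unreachable"] = None

    def __new__(cls) -> "_Unreachable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "unreachable"

    __str__ = __repr__


UNREACHABLE = _Unreachable()


def roi_percent(total_cost, total_income) -> Optional[float]:
    """Return on investment, ``100 x (income - cost) / cost``, in percent.

    Zero cost has no defined ROI and returns ``None`` (never 0); negative
    cost is rejected.
    """
    cost = to_decimal(total_cost)
    income = to_decimal(total_income)
    if cost < 0:
        raise ValueError("total_cost must be non-negative")
    if cost == 0:
        return None
    return float(100 * (income - cost) / cost)


def format_roi(roi: Optional[float]) -> str:
    """Render ROI the way finance tables print it: one decimal, with the
    trailing ``.0`` dropped for whole percentages (``-12.5%`` but ``32%``)."""
    if roi is None:
        return "N/A"
    rounded = round(roi, 1)
    if rounded == int(rounded):
        return f"{int(rounded)}%"
    return f"{rounded}%"


def breakeven_appointments(
    clinic_cost, income_per_attended
) -> Union[int, _Unreachable]:
    """Smallest integer ``b`` with ``b x income_per_attended >= clinic_cost``.

    Returns :data:`UNREACHABLE` when the cost is positive but each attended
    appointment earns nothing.
    """
    cost = to_decimal(clinic_cost)
    rate = to_decimal(income_per_attended)
    if cost < 0 or rate < 0:
        raise ValueError("clinic_cost and income_per_attended must be >= 0")
    if cost == 0:
        return 0
    if rate == 0:
        return UNREACHABLE
    return int(math.ceil(cost / rate))


@dataclass(frozen=True)
class YearCell:
    """One (model, site, year) slot of the results table."""

    cost: int
    income: int
    income_fta_low: int   # income at the low FTA-rate bound (more attendance)
    income_fta_high: int  # income at the high FTA-rate bound


@dataclass(frozen=True)
class SiteSummary:
    """Multi-year position of one site under one care model."""

    cost: int
    income: int
    income_fta_low: int
    income_fta_high: int
    net_benefit: int
    roi: Optional[float]
    earns_income: bool


@dataclass
class ScenarioResult:
    """Filled evaluation grid plus per-site multi-year summaries."""

    years: list[str]
    fta_bounds: tuple[float, float]
    cells: dict[tuple[str, str, str], YearCell] = field(default_factory=dict)
    summaries: dict[tuple[str, str], SiteSummary] = field(default_factory=dict)

    def cell(self, model_id: str, site_id: str, year: str) -> YearCell:
        return self.cells[(model_id, site_id, year)]

    def summary(self, model_id: str, site_id: str) -> SiteSummary:
        return self.summaries[(model_id, site_id)]

    def to_frame(self) -> pd.DataFrame:
        """Wide, report-shaped table: one row per (model, site)."""
        low, high = self.fta_bounds
        rows = []
        for (model_id, site_id), s in self.summaries.items():
            row: dict[str, object] = {"model": model_id, "site": site_id}
            for year in self.years:
                c = self.cells[(model_id, site_id, year)]
                row[f"{year} cost (A$)"] = c.cost
                row[f"{year} income (A$)"] = c.income if s.earns_income else None
                row[f"{year} income FTA {low:.0%} (A$)"] = (
                    c.income_fta_low if s.earns_income else None
                )
                row[f"{year} income FTA {high:.0%} (A$)"] = (
                    c.income_fta_high if s.earns_income else None
                )
            row["total cost (A$)"] = s.cost
            row["total income (A$)"] = s.income if s.earns_income else None
            row["net benefit (A$)"] = s.net_benefit
            row["ROI (%)"] = None if s.roi is None else round(s.roi, 1)
            row["ROI (printed)"] = format_roi(s.roi)
            rows.append(row)
        return pd.DataFrame(rows)


def run_scenario(
    models: Sequence[CareModel],
    activity: Sequence[ActivityYear],
    streams: StreamsLike,
    schedules: Mapping[str, DiscountSchedule],
    *,
    fta_bounds: tuple[float, float] = (0.10, 0.35),
) -> ScenarioResult:
    """Evaluate every care model over every activity year.

    ``schedules`` maps schedule names to :class:`DiscountSchedule`; each
    model names its staffing schedule, and a travel policy may name its own.
    ``fta_bounds`` are the failure-to-attend rates used for the income
    sensitivity columns.
    """
    low, high = fta_bounds
    result = ScenarioResult(years=[a.year_label for a in activity], fta_bounds=fta_bounds)
    for model in models:
        staff_schedule = schedules[model.staff_discount_schedule]
        for site_id in model.site_ids:
            earns = bool(model.claims_for(site_id))
            totals = {"cost": 0, "income": 0, "low": 0, "high": 0}
            for year in activity:
                cost = annual_staff_cost(model, site_id, year, staff_schedule)
                policy = model.travel_policy
                if policy is not None and policy.site_id == site_id:
                    travel_schedule = schedules[
                        policy.discount_schedule or model.staff_discount_schedule
                    ]
                    cost += travel_subsidy_cost(year, policy, travel_schedule)
                income = annual_income(model, site_id, year, streams)
                income_low = annual_income(model, site_id, year, streams, low)
                income_high = annual_income(model, site_id, year, streams, high)
                cell = YearCell(
                    cost=cost,
                    income=income,
                    income_fta_low=income_low,
                    income_fta_high=income_high,
                )
                result.cells[(model.model_id, site_id, year.year_label)] = cell
                totals["cost"] += cost
                totals["income"] += income
                totals["low"] += income_low
                totals["high"] += income_high
            result.summaries[(model.model_id, site_id)] = SiteSummary(
                cost=totals["cost"],
                income=totals["income"],
                income_fta_low=totals["low"],
                income_fta_high=totals["high"],
                net_benefit=totals["income"] - totals["cost"],
                roi=roi_percent(totals["cost"], totals["income"]),
                earns_income=earns,
            )
    return result


def run_bundle(bundle: ScenarioBundle, **kwargs) -> ScenarioResult:
    """Convenience wrapper: evaluate a loaded scenario bundle."""
    return run_scenario(
        bundle.care_models,
        bundle.activity,
        bundle.streams_by_id,
        bundle.discount_schedules,
        **kwargs,
    )


def breakeven_table(
    models: Sequence[CareModel],
    streams: StreamsLike,
    reference_year: str,
    activity: Optional[Sequence[ActivityYear]] = None,
) -> pd.DataFrame:
    """Breakeven attendance per (model, site) at a reference year's rates.

    The per-clinic cost is the site's staffing total plus, for a site that
    bears a travel-subsidy policy, the reference year's subsidy spread over
    its clinics (undiscounted: the reference year is taken at base prices).
    The income per attended appointment is the summed rate of the site's
    claimed streams for the reference year.
    """
    by_label = {a.year_label: a for a in activity} if activity else {}
    rows = []
    for model in models:
        for site_id in model.site_ids:
            cost = site_clinic_cost(model, site_id).total
            policy = model.travel_policy
            if policy is not None and policy.site_id == site_id and by_label:
                ref = by_label[reference_year]
                if ref.clinics_held:
                    base = (
                        ref.total_bookings
                        if policy.base_population == "all_bookings"
                        else ref.attended
                    )
                    cost += (
                        Decimal(base)
                        * policy.uptake_fraction
                        * policy.average_cost_per_claimant
                        / ref.clinics_held
                    )
            rate = site_rate(model, site_id, streams, reference_year)
            b = breakeven_appointments(cost, rate)
            rows.append(
                {
                    "model": model.model_id,
                    "site": site_id,
                    "clinic cost (A$)": float(round_cents(cost)),
                    "income per attended appointment (A$)": float(round_cents(rate)),
                    "breakeven (appointments)": None
                    if b is UNREACHABLE
                    else int(b),
                    "breakeven (printed)": str(b),
                }
            )
    return pd.DataFrame(rows)
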