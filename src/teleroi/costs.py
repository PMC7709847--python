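"""Cost engine: per-clinic staffing costs, discounted annual costs, and
travel-subsidy costs.

Per-clinic line cost
    ``hourly_rate x (1 + on_cost_fraction) x hours_per_clinic``, rounded
    half-up to cents.  A line may instead carry a ``reported_cost`` pinned to
    a published wage table (within a documented A$0.03 tolerance of the
    formula); the reported figure then takes precedence so that printed site
    totals are reproduced exactly.

Annual cost
    per-clinic site total x clinics held x discount factor, where the factor
    rescales base-year prices to an earlier year's price level (divisive
    form, ``1/(1+r)**k``).  Annual cells are reported in whole dollars,
    half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Union

from ._money import round_cents, round_dollars
from .domain import (
    ActivityYear,
    CareModel,
    DiscountSchedule,
    StaffLine,
    TravelSubsidyPolicy,
)
from .errors import MissingYearError, UnknownSiteError


@dataclass(frozen=True)
class ClinicCostBreakdown:
    """Per-clinic cost of one site under one care model, line by line."""

    site_id: str
    line_costs: tuple[tuple[str, Decimal], ...]  # (role_name, cost)

    @property
    def total(self) -> Decimal:
        return sum((cost for _, cost in self.line_costs), Decimal(0))


def formula_line_cost(line: StaffLine) -> Decimal:
    """Wage-formula per-clinic cost, ignoring any reported override."""
    return round_cents(
        line.hourly_rate * (1 + line.on_cost_fraction) * line.hours_per_clinic
    )


def staff_line_cost(line: StaffLine) -> Decimal:
    """Per-clinic cost of one staffing line, in A$ (2 decimals).

    Uses the pinned ``reported_cost`` when present, the wage formula
    otherwise.
    """
    if line.reported_cost is not None:
        return round_cents(line.reported_cost)
    return formula_line_cost(line)


def site_clinic_cost(model: CareModel, site_id: str) -> ClinicCostBreakdown:
    """Per-clinic staffing cost of ``site_id`` under ``model``.

    The site total is the exact sum of the (rounded) line costs; a site with
    no staffing lines costs 0.00 per clinic.
    """
    if site_id not in model.site_ids:
        raise UnknownSiteError(
            f"site {site_id!r} does not participate in model {model.model_id!r}"
        )
    lines = tuple(
        (line.role_name, staff_line_cost(line)) for line in model.lines_for(site_id)
    )
    return ClinicCostBreakdown(site_id=site_id, line_costs=lines)


def discount_factor(schedule: DiscountSchedule, year_label: str) -> Decimal:
    """Multiplicative price factor for ``year_label`` (base year -> 1)."""
    try:
        return Decimal(schedule.factor_by_year[year_label])
    except KeyError:
        raise MissingYearError(
            f"discount schedule (base {schedule.base_year!r}) has no factor "
            f"for {year_label!r}"
        ) from None


def annual_staff_cost(
    model: CareModel,
    site_id: str,
    activity: ActivityYear,
    schedule: DiscountSchedule,
    *,
    exact: bool = False,
) -> Union[int, Decimal]:
    """Annual staffing cost of a site: per-clinic total x clinics x factor.

    Reported in whole dollars (half-up) unless ``exact=True``, which returns
    the unrounded :class:`~decimal.Decimal` for property checks and
    downstream aggregation.
    """
    total = site_clinic_cost(model, site_id).total
    value = total * activity.clinics_held * discount_factor(schedule, activity.year_label)
    return value if exact else round_dollars(value)


def travel_subsidy_cost(
    activity: ActivityYear,
    policy: TravelSubsidyPolicy,
    schedule: DiscountSchedule,
    *,
    uptake_override: Union[Decimal, float, None] = None,
    exact: bool = False,
) -> Union[int, Decimal]:
    """Annual travel-subsidy expenditure for one financial year.

    ``base population x uptake x average claim cost x discount factor``.
    The base population is all bookings or attended bookings only, per
    ``policy.base_population``.
    """
    from ._money import to_decimal  # local import to avoid cycle noise

    base = (
        activity.total_bookings
        if policy.base_population == "all_bookings"
        else activity.attended
    )
    uptake = (
        policy.uptake_fraction
        if uptake_override is None
        else to_decimal(uptake_override)
    )
    if not 0 <= uptake <= 1:
        raise ValueError(f"uptake {uptake} outside [0, 1]")
    value = (
        Decimal(base)
        * uptake
        * policy.average_cost_per_claimant
        * discount_factor(schedule, activity.year_label)
    )
    return value if exact else round_dollars(value)


def cost_breakdown_frame(model: CareModel):
    """All staffing lines of a model as a wage-table-shaped DataFrame
    (role, hourly rate, on-cost, hours, per-clinic cost)."""
    import pandas as pd

    rows = []
    for site_id in model.site_ids:
        for line in model.lines_for(site_id):
            rows.append(
                {
                    "model": model.model_id,
                    "site": site_id,
                    "role": line.role_name,
                    "hourly_rate_aud": float(line.hourly_rate),
                    "on_cost": float(line.on_cost_fraction),
                    "hours_per_clinic": float(line.hours_per_clinic),
                    "cost_aud": float(staff_line_cost(line)),
                }
            )
        if model.lines_for(site_id):
            rows.append(
                {
                    "model": model.model_id,
                    "site": site_id,
                    "role": "Total",
                    "hourly_rate_aud": None,
                    "on_cost": None,
                    "hours_per_clinic": None,
                    "cost_aud": float(site_clinic_cost(model, site_id).total),
                }
            )
    return pd.DataFrame(rows)
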