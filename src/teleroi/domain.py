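"""Domain types and scenario-document IO.

A *scenario document* is a single YAML (or JSON) file describing everything a
care-model evaluation needs: the care models with their staffing lines and
funding claims, the per-year clinic activity, the per-appointment funding
rates, and the wage/travel discount schedules.  The schema is versioned
(``schema_version: 1``) and documented in ``docs/scenario_schema.md``.

Money fields are validated into exact :class:`~decimal.Decimal` values; see
:mod:`teleroi._money`.
"""

from __future__ import annotations

import warnings
from decimal import Decimal
from pathlib import Path
from typing import Annotated, Literal, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from ._money import round_dollars, to_decimal
from .errors import ScenarioValidationError

SCHEMA_VERSION = 1

#: On-cost fractions used in Queensland Health workplace agreements:
#: 23% for medical officers, 29% for all other staff.
STANDARD_ON_COSTS = (Decimal("0.23"), Decimal("0.29"))

#: Largest tolerated gap between a reported (printed) per-clinic line cost
#: and the rate*(1+on-cost)*hours formula; wage tables in source reports
#: occasionally embed upstream rounding of this size.
REPORTED_COST_TOLERANCE = Decimal("0.03")

Money = Annotated[Decimal, BeforeValidator(to_decimal)]


class StaffLine(BaseModel):
    """One staffing resource on one site, costed per clinic session.

    ``reported_cost`` optionally pins the per-clinic cost to the figure a
    published wage table prints when that figure embeds upstream rounding;
    it must lie within :data:`REPORTED_COST_TOLERANCE` of the formula value.
    """

    model_config = ConfigDict(frozen=True)

    role_name: str
    hourly_rate: Money = Field(ge=0)
    on_cost_fraction: Money = Field(ge=0)
    hours_per_clinic: Money = Field(ge=0)
    site_id: str
    reported_cost: Optional[Money] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "StaffLine":
        if self.on_cost_fraction not in STANDARD_ON_COSTS:
            warnings.warn(
                f"staff line {self.role_name!r}: on-cost fraction "
                f"{self.on_cost_fraction} is outside the standard workplace-"
                f"agreement values {tuple(map(str, STANDARD_ON_COSTS))}",
                stacklevel=2,
            )
        if self.reported_cost is not None:
            formula = (
                self.hourly_rate * (1 + self.on_cost_fraction) * self.hours_per_clinic
            )
            if abs(self.reported_cost - formula) > REPORTED_COST_TOLERANCE:
                raise ValueError(
                    f"reported_cost {self.reported_cost} deviates from the "
                    f"wage formula value {formula} by more than "
                    f"A${REPORTED_COST_TOLERANCE}"
                )
        return self


class TravelSubsidyPolicy(BaseModel):
    """Patient travel-subsidy scheme: uptake fraction x average claim cost.

    ``base_population`` selects whether uptake applies to all bookings or to
    attended (non-FTA) bookings only.
    """

    model_config = ConfigDict(frozen=True)

    uptake_fraction: Money = Field(ge=0, le=1)
    average_cost_per_claimant: Money = Field(ge=0)
    base_population: Literal["all_bookings", "attended_only"] = "all_bookings"


class TravelSubsidyAssignment(TravelSubsidyPolicy):
    """A travel-subsidy policy borne by a specific site, optionally with its
    own discount schedule."""

    site_id: str
    discount_schedule: Optional[str] = None


class FundingStream(BaseModel):
    """Activity-based funding stream: A$ paid per attended appointment,
    per financial year."""

    model_config = ConfigDict(frozen=True)

    stream_id: str
    label: str = ""
    rate_by_year: Mapping[str, Money]

    @model_validator(mode="after")
    def _check(self) -> "FundingStream":
        for year, rate in self.rate_by_year.items():
            if rate < 0:
                raise ValueError(f"rate for {year} is negative")
        return self


class ActivityYear(BaseModel):
    """Aggregate outpatient-clinic activity for one financial year."""

    model_config = ConfigDict(frozen=True)

    year_label: str
    total_bookings: int = Field(ge=0)
    clinics_held: int = Field(ge=0)
    new_bookings: int = Field(ge=0)
    review_bookings: int = Field(ge=0)
    adult_bookings: int = Field(ge=0)
    pediatric_bookings: int = Field(ge=0)
    fta_count: int = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ActivityYear":
        if self.new_bookings + self.review_bookings != self.total_bookings:
            raise ValueError("new_bookings + review_bookings != total_bookings")
        if self.adult_bookings + self.pediatric_bookings != self.total_bookings:
            raise ValueError("adult_bookings + pediatric_bookings != total_bookings")
        if self.fta_count > self.total_bookings:
            raise ValueError("fta_count exceeds total_bookings")
        return self

    @property
    def attended(self) -> int:
        return self.total_bookings - self.fta_count


class DiscountSchedule(BaseModel):
    """Multiplicative price factors per financial year, base year = 1.

    Factors are typically divisive from base-year prices:
    ``factor = 1 / (1 + rate) ** years_back`` (see :meth:`from_rate`).
    """

    model_config = ConfigDict(frozen=True)

    base_year: str
    factor_by_year: Mapping[str, Money]

    @model_validator(mode="after")
    def _check(self) -> "DiscountSchedule":
        base = self.factor_by_year.get(self.base_year)
        if base != 1:
            raise ValueError(f"factor for base year {self.base_year} must be 1")
        for year, factor in self.factor_by_year.items():
            if factor <= 0:
                raise ValueError(f"factor for {year} must be positive")
        return self

    @classmethod
    def from_rate(
        cls,
        base_year: str,
        annual_rate: Union[str, float, Decimal],
        years_back: Mapping[str, int],
    ) -> "DiscountSchedule":
        """Build divisive factors ``1/(1+rate)**k`` from per-year exponents."""
        rate = to_decimal(annual_rate)
        factors = {
            year: Decimal(1) / (Decimal(1) + rate) ** k
            for year, k in years_back.items()
        }
        return cls(base_year=base_year, factor_by_year=factors)


class SiteRef(BaseModel):
    model_config = ConfigDict(frozen=True)

    site_id: str
    role: Literal["referral", "provider"]


class CareModel(BaseModel):
    """A named service-delivery configuration.

    Declares the participating sites, which site bears which staffing lines,
    which funding streams each site claims (a site absent from
    ``income_claims`` earns nothing), and an optional travel-subsidy burden.
    """

    model_config = ConfigDict(frozen=True)

    model_id: str
    sites: Sequence[SiteRef]
    staff_lines: Sequence[StaffLine] = ()
    income_claims: Mapping[str, Sequence[str]] = Field(default_factory=dict)
    travel_policy: Optional[TravelSubsidyAssignment] = None
    staff_discount_schedule: str = "staffing"

    @model_validator(mode="after")
    def _check(self) -> "CareModel":
        declared = self.site_ids
        if len(declared) != len(set(declared)):
            raise ValueError("duplicate site_id")
        for line in self.staff_lines:
            if line.site_id not in declared:
                raise ValueError(
                    f"staff line {line.role_name!r} references undeclared "
                    f"site {line.site_id!r}"
                )
        for site_id in self.income_claims:
            if site_id not in declared:
                raise ValueError(f"income_claims references undeclared site {site_id!r}")
        if self.travel_policy and self.travel_policy.site_id not in declared:
            raise ValueError(
                f"travel_policy references undeclared site "
                f"{self.travel_policy.site_id!r}"
            )
        return self

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def claims_for(self, site_id: str) -> list[str]:
        return list(self.income_claims.get(site_id, []))

    def lines_for(self, site_id: str) -> list[StaffLine]:
        return [l for l in self.staff_lines if l.site_id == site_id]


class ScenarioBundle(BaseModel):
    """Everything one evaluation needs, as loaded from a scenario document."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = SCHEMA_VERSION
    care_models: Sequence[CareModel]
    activity: Sequence[ActivityYear]
    funding_streams: Sequence[FundingStream]
    discount_schedules: Mapping[str, DiscountSchedule]

    @model_validator(mode="after")
    def _check(self) -> "ScenarioBundle":
        years = [a.year_label for a in self.activity]
        if len(years) != len(set(years)):
            raise ValueError("duplicate activity year_label")
        streams = self.streams_by_id
        for model in self.care_models:
            for site_id, claims in model.income_claims.items():
                for stream_id in claims:
                    if stream_id not in streams:
                        raise ValueError(
                            f"model {model.model_id!r} site {site_id!r} claims "
                            f"unknown funding stream {stream_id!r}"
                        )
                    stream = streams[stream_id]
                    for year in years:
                        if year not in stream.rate_by_year:
                            raise ValueError(
                                f"funding stream {stream_id!r} has no rate for "
                                f"financial year {year!r}"
                            )
            for name in self._schedule_names(model):
                if name not in self.discount_schedules:
                    raise ValueError(
                        f"model {model.model_id!r} references unknown discount "
                        f"schedule {name!r}"
                    )
                schedule = self.discount_schedules[name]
                for year in years:
                    if year not in schedule.factor_by_year:
                        raise ValueError(
                            f"discount schedule {name!r} has no factor for "
                            f"financial year {year!r}"
                        )
        return self

    @staticmethod
    def _schedule_names(model: CareModel) -> list[str]:
        names = [model.staff_discount_schedule]
        if model.travel_policy and model.travel_policy.discount_schedule:
            names.append(model.travel_policy.discount_schedule)
        return names

    @property
    def streams_by_id(self) -> dict[str, FundingStream]:
        return {s.stream_id: s for s in self.funding_streams}

    @property
    def years(self) -> list[str]:
        """Financial years in activity-list order (labels are opaque)."""
        return [a.year_label for a in self.activity]

    def model(self, model_id: str) -> CareModel:
        for m in self.care_models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def activity_year(self, year_label: str) -> ActivityYear:
        for a in self.activity:
            if a.year_label == year_label:
                return a
        raise KeyError(year_label)

    def staff_schedule(self, model: CareModel) -> DiscountSchedule:
        return self.discount_schedules[model.staff_discount_schedule]

    def travel_schedule(self, model: CareModel) -> DiscountSchedule:
        policy = model.travel_policy
        name = (
            policy.discount_schedule
            if policy and policy.discount_schedule
            else model.staff_discount_schedule
        )
        return self.discount_schedules[name]


# ---------------------------------------------------------------------------
# Scenario document IO


def _parse_activity_entry(entry: dict) -> dict:
    """Accept FTA as a count, a rate, or both (the count wins).

    A rate is converted to a count by half-up rounding of
    ``rate * total_bookings``.
    """
    entry = dict(entry)
    if "fta_count" not in entry and "fta_rate" in entry:
        rate = to_decimal(entry["fta_rate"])
        if not 0 <= rate <= 1:
            raise ScenarioValidationError("fta_rate outside [0, 1]")
        entry["fta_count"] = round_dollars(rate * entry.get("total_bookings", 0))
    entry.pop("fta_rate", None)
    return entry


def _parse_rates(raw: Mapping) -> dict[str, Decimal]:
    """A rate entry is either a number or a ``{income, attended}`` pair.

    The pair form records a rate calibrated from a printed annual income
    divided by the attended count, keeping its origin auditable; the division
    is carried out exactly here.
    """
    rates: dict[str, Decimal] = {}
    for year, value in raw.items():
        if isinstance(value, Mapping):
            attended = to_decimal(value["attended"])
            income = to_decimal(value["income"])
            if attended == 0:
                if income != 0:
                    raise ScenarioValidationError(
                        f"rates[{year!r}]: nonzero income with zero attendance"
                    )
                rates[year] = Decimal(0)
            else:
                rates[year] = income / attended
        else:
            rates[year] = to_decimal(value)
    return rates


def _parse_schedule(raw: Mapping) -> DiscountSchedule:
    if "factor_by_year" in raw or "factors" in raw:
        factors = raw.get("factor_by_year", raw.get("factors"))
        return DiscountSchedule(base_year=raw["base_year"], factor_by_year=factors)
    return DiscountSchedule.from_rate(
        base_year=raw["base_year"],
        annual_rate=raw.get("annual_rate", "0.025"),
        years_back=raw["years_back"],
    )


def load_scenario(source: Union[str, Path, Mapping]) -> ScenarioBundle:
    """Load and validate a scenario document.

    ``source`` may be a path to a YAML/JSON file or an already-parsed
    mapping.  All cross-references (sites, streams, schedules, years) are
    resolved; violations raise :class:`ScenarioValidationError` with a path
    into the document.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            document = yaml.safe_load(handle)
    else:
        document = dict(source)
    if not isinstance(document, Mapping):
        raise ScenarioValidationError("document is not a mapping")

    version = document.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ScenarioValidationError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})",
            path="schema_version",
        )

    try:
        activity = [
            ActivityYear(**_parse_activity_entry(entry))
            for entry in document.get("activity", [])
        ]
        streams = [
            FundingStream(
                stream_id=raw["stream_id"],
                label=raw.get("label", ""),
                rate_by_year=_parse_rates(raw.get("rates", raw.get("rate_by_year", {}))),
            )
            for raw in document.get("funding_streams", [])
        ]
        schedules = {
            name: _parse_schedule(raw)
            for name, raw in document.get("discount_schedules", {}).items()
        }
        models = [CareModel(**raw) for raw in document.get("care_models", [])]
        return ScenarioBundle(
            schema_version=version,
            care_models=models,
            activity=activity,
            funding_streams=streams,
            discount_schedules=schedules,
        )
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ScenarioValidationError(first["msg"], path=loc or None) from exc
    except (KeyError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(str(exc)) from exc


def save_scenario(bundle: ScenarioBundle, destination: Union[str, Path]) -> None:
    """Write a bundle back to a YAML scenario document (round-trips through
    :func:`load_scenario`)."""

    def _plain(value):
        if isinstance(value, Decimal):
            return float(value) if value != value.to_integral_value() else int(value)
        return value

    document = {
        "schema_version": bundle.schema_version,
        "discount_schedules": {
            name: {
                "base_year": s.base_year,
                "factors": {y: float(f) for y, f in s.factor_by_year.items()},
            }
            for name, s in bundle.discount_schedules.items()
        },
        "activity": [
            {k: _plain(v) for k, v in a.model_dump().items()} for a in bundle.activity
        ],
        "funding_streams": [
            {
                "stream_id": s.stream_id,
                "label": s.label,
                "rates": {y: float(r) for y, r in s.rate_by_year.items()},
            }
            for s in bundle.funding_streams
        ],
        "care_models": [
            _prune_nones(
                {
                    k: _dump_money(v)
                    for k, v in m.model_dump(exclude_none=True).items()
                }
            )
            for m in bundle.care_models
        ],
    }
    with open(destination, "w", encoding="utf-8") as handle:
        yaml.safe_dump(document, handle, sort_keys=False)


def _dump_money(value):
    if isinstance(value, Decimal):
        return float(value)
    if isinstance(value, dict):
        return {k: _dump_money(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_dump_money(v) for v in value]
    return value


def _prune_nones(value):
    if isinstance(value, dict):
        return {k: _prune_nones(v) for k, v in value.items() if v is not None}
    return value


# ---------------------------------------------------------------------------
# Activity-table IO (CSV mirroring the published activity-report headings)

ACTIVITY_COLUMNS = {
    "year_label": "Financial year",
    "total_bookings": "Total patients, n",
    "clinics_held": "Clinics, n",
    "new_bookings": "New patient bookings, n",
    "review_bookings": "Review patient bookings, n",
    "adult_bookings": "Adult patient bookings, n",
    "pediatric_bookings": "Pediatric patient bookings, n",
    "fta_count": "Failed to attend, n",
}


def activity_to_frame(activity: Sequence[ActivityYear]) -> pd.DataFrame:
    rows = [{col: getattr(a, field) for field, col in ACTIVITY_COLUMNS.items()}
            for a in activity]
    return pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS.values()))


def write_activity_table(
    activity: Sequence[ActivityYear], destination: Union[str, Path]
) -> None:
    """Write activity years to CSV; round-trips through
    :func:`read_activity_table`."""
    if not activity:
        raise ValueError("activity list is empty")
    activity_to_frame(activity).to_csv(destination, index=False)


def read_activity_table(source: Union[str, Path]) -> list[ActivityYear]:
    frame = pd.read_csv(source)
    reverse = {col: field for field, col in ACTIVITY_COLUMNS.items()}
    missing = set(reverse) - set(frame.columns)
    if missing:
        raise ScenarioValidationError(f"missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        fields = {reverse[col]: row[col] for col in reverse}
        fields = {
            k: (str(v) if k == "year_label" else int(v)) for k, v in fields.items()
        }
        out.append(ActivityYear(**fields))
    return out
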