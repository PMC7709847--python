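"""Synthetic activity data and the bundled worked scenario.

The generator emulates the statistical shape of an aggregate outpatient
activity report: yearly clinic counts around a mean (Poisson, zero-clinic
years rejected), bookings accumulating per clinic (Poisson), and binomial
splits for failure-to-attend, new-vs-review, and adult-vs-pediatric mixes.
One integer seed drives a single pseudo-random stream, so identical
configurations are bit-reproducible.

Defaults mirror the bundled three-year tele-orthopedic fracture-clinic
scenario: 65 clinics/year and ~13.8 bookings/clinic on average, a 26%
failure-to-attend probability, 55% new patients, 27% pediatric patients.

:func:`fracture_clinic_fixture` loads that worked scenario — a Queensland
tele-orthopedic fracture clinic evaluated over financial years 2014-2015 to
2016-2017 under three care models — with calibrated funding rates and
discount schedules, ready for :func:`teleroi.evaluate.run_bundle`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .domain import (
    ActivityYear,
    DiscountSchedule,
    FundingStream,
    ScenarioBundle,
    load_scenario,
)

FIXTURE_RESOURCE = "fracture_clinic.yaml"


class ActivityGeneratorConfig(BaseModel):
    """Parameters of the synthetic activity generator."""

    model_config = ConfigDict(frozen=True)

    n_years: int = Field(default=3, ge=1)
    clinics_per_year_mean: float = Field(default=65.0, gt=0)
    bookings_per_clinic_mean: float = Field(default=13.8, gt=0)
    fta_probability: float = Field(default=0.26, ge=0, le=1)
    new_fraction: float = Field(default=0.55, ge=0, le=1)
    pediatric_fraction: float = Field(default=0.27, ge=0, le=1)
    start_year: int = Field(default=2014)
    seed: int = 0


def year_labels(start_year: int, n_years: int) -> list[str]:
    """July-June financial-year labels: ``2014-2015``, ``2015-2016``, ..."""
    return [f"{start_year + i}-{start_year + i + 1}" for i in range(n_years)]


def generate_activity(config: ActivityGeneratorConfig) -> list[ActivityYear]:
    """Draw a list of activity years satisfying every domain invariant."""
    rng = np.random.default_rng(config.seed)
    out = []
    for label in year_labels(config.start_year, config.n_years):
        clinics = 0
        while clinics == 0:
            clinics = int(rng.poisson(config.clinics_per_year_mean))
        bookings = int(rng.poisson(clinics * config.bookings_per_clinic_mean))
        fta = int(rng.binomial(bookings, config.fta_probability))
        new = int(rng.binomial(bookings, config.new_fraction))
        pediatric = int(rng.binomial(bookings, config.pediatric_fraction))
        out.append(
            ActivityYear(
                year_label=label,
                total_bookings=bookings,
                clinics_held=clinics,
                new_bookings=new,
                review_bookings=bookings - new,
                adult_bookings=bookings - pediatric,
                pediatric_bookings=pediatric,
                fta_count=fta,
            )
        )
    return out


def fracture_clinic_fixture() -> ScenarioBundle:
    """The bundled worked scenario (three care models, three years,
    calibrated funding rates and discount schedules)."""
    path = resources.files("teleroi.data").joinpath(FIXTURE_RESOURCE)
    with resources.as_file(path) as fixture_path:
        return load_scenario(fixture_path)


def generate_scenario(config: ActivityGeneratorConfig) -> ScenarioBundle:
    """A ready-to-run bundle: the fixture's care models and funding rates
    over a synthetic activity table.

    Generated years reuse the fixture's base-year (last fixture year)
    funding rates, and the discount schedule is rebuilt divisively at 2.5%
    per year back from the last generated year.
    """
    fixture = fracture_clinic_fixture()
    activity = generate_activity(config)
    labels = [a.year_label for a in activity]
    base_rate_year = fixture.years[-1]
    streams = [
        FundingStream(
            stream_id=s.stream_id,
            label=s.label,
            rate_by_year={y: s.rate_by_year[base_rate_year] for y in labels},
        )
        for s in fixture.funding_streams
    ]
    schedule = DiscountSchedule.from_rate(
        base_year=labels[-1],
        annual_rate="0.025",
        years_back={y: len(labels) - 1 - i for i, y in enumerate(labels)},
    )
    names = {
        name
        for m in fixture.care_models
        for name in (
            m.staff_discount_schedule,
            m.travel_policy.discount_schedule if m.travel_policy else None,
        )
        if name
    }
    return ScenarioBundle(
        schema_version=fixture.schema_version,
        care_models=fixture.care_models,
        activity=activity,
        funding_streams=streams,
        discount_schedules={name: schedule for name in names},
    )
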