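"""Funding engine: activity-based-funding income with failure-to-attend
adjustment, and rate calibration from printed income tables.

Income model: every attended appointment earns the sum of the per-appointment
rates of the funding streams the site claims; failed-to-attend (FTA)
appointments earn nothing.  Under an FTA-rate override the attended count is
kept fractional (``bookings x (1 - rate)``) before multiplying by the rate,
so income is exactly linear in the attendance fraction.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

from ._money import round_dollars, to_decimal
from .domain import ActivityYear, CareModel, FundingStream
from .errors import MissingRateError, UnknownSiteError

StreamsLike = Union[Mapping[str, FundingStream], Iterable[FundingStream]]


def _as_stream_map(streams: StreamsLike) -> Mapping[str, FundingStream]:
    if isinstance(streams, Mapping):
        return streams
    return {s.stream_id: s for s in streams}


def attended_count(
    activity: ActivityYear,
    fta_override: Union[Decimal, float, None] = None,
) -> Union[int, Decimal]:
    """Appointments that earned income in one year.

    With no override this is the recorded ``bookings - FTA`` count.  With an
    FTA-rate override it is the fractional ``bookings x (1 - rate)``, kept
    unrounded for income arithmetic.
    """
    if fta_override is None:
        return activity.attended
    rate = to_decimal(fta_override)
    if not 0 <= rate <= 1:
        raise ValueError(f"FTA override {rate} outside [0, 1]")
    return activity.total_bookings * (1 - rate)


def site_rate(
    model: CareModel, site_id: str, streams: StreamsLike, year_label: str
) -> Decimal:
    """Summed per-attended-appointment rate of every stream the site claims."""
    if site_id not in model.site_ids:
        raise UnknownSiteError(
            f"site {site_id!r} does not participate in model {model.model_id!r}"
        )
    stream_map = _as_stream_map(streams)
    total = Decimal(0)
    for stream_id in model.claims_for(site_id):
        stream = stream_map[stream_id]
        if year_label not in stream.rate_by_year:
            raise MissingRateError(
                f"stream {stream_id!r} has no rate for {year_label!r}"
            )
        total += stream.rate_by_year[year_label]
    return total


def annual_income(
    model: CareModel,
    site_id: str,
    activity: ActivityYear,
    streams: StreamsLike,
    fta_override: Union[Decimal, float, None] = None,
    *,
    exact: bool = False,
) -> Union[int, Decimal]:
    """Activity-based-funding income of a site for one year, whole dollars.

    A site with no funding claims earns 0.
    """
    if not model.claims_for(site_id):
        if site_id not in model.site_ids:
            raise UnknownSiteError(
                f"site {site_id!r} does not participate in model {model.model_id!r}"
            )
        return Decimal(0) if exact else 0
    rate = site_rate(model, site_id, streams, activity.year_label)
    value = attended_count(activity, fta_override) * rate
    return value if exact else round_dollars(value)


def calibrate_funding_rates(
    income_by_year: Mapping[str, Union[int, float, Decimal]],
    activity: Sequence[ActivityYear],
    *,
    stream_id: str = "calibrated",
    label: str = "",
) -> FundingStream:
    """Solve the inverse problem: per-year rate = printed income / attended.

    Feeding the returned stream back through :func:`annual_income`
    reproduces the calibration incomes to within A$1 of rounding.
    """
    by_label = {a.year_label: a for a in activity}
    rates: dict[str, Decimal] = {}
    for year, income in income_by_year.items():
        attended = by_label[year].attended
        income_d = to_decimal(income)
        if attended == 0:
            if income_d != 0:
                raise ValueError(
                    f"{year}: nonzero income {income_d} with zero attendance"
                )
            rates[year] = Decimal(0)
        else:
            rates[year] = income_d / attended
    return FundingStream(stream_id=stream_id, label=label, rate_by_year=rates)
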