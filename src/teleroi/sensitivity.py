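"""One-way sensitivity sweeps.

Two deterministic one-way analyses generalise the base case:

* failure-to-attend (FTA) rate — income is recomputed at each rate while
  costs stay fixed (clinic counts, and by default the travel-subsidy spend,
  are held at their base values);
* travel-subsidy uptake — the subsidy spend is recomputed at each uptake
  fraction.

Both quantities are exactly linear in their parameter (income in
``1 - FTA rate``, subsidy in uptake), so a sweep over any grid is cheap and
the default grids match the usual reporting points.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .costs import travel_subsidy_cost
from .domain import ActivityYear, CareModel, DiscountSchedule, TravelSubsidyPolicy
from .funding import StreamsLike, annual_income

#: Default FTA-rate grid: the customary low/high reporting bounds.
DEFAULT_FTA_RATES = (0.10, 0.35)
#: Default subsidy-uptake grid: observed uptake and a hypothetical increase.
DEFAULT_UPTAKES = (0.17, 0.25)


def fta_sweep(
    models: Sequence[CareModel],
    activity: Sequence[ActivityYear],
    streams: StreamsLike,
    rates: Sequence[float] = DEFAULT_FTA_RATES,
) -> pd.DataFrame:
    """Income per (model, income-earning site, year) at each FTA rate.

    Long format: model, site, year, parameter, value, quantity, amount (A$).
    """
    for rate in rates:
        if not 0 <= rate <= 1:
            raise ValueError(f"FTA rate {rate} outside [0, 1]")
    rows = []
    for model in models:
        for site_id in model.site_ids:
            if not model.claims_for(site_id):
                continue
            for year in activity:
                for rate in rates:
                    rows.append(
                        {
                            "model": model.model_id,
                            "site": site_id,
                            "year": year.year_label,
                            "parameter": "fta_rate",
                            "value": float(rate),
                            "quantity": "income",
                            "amount_aud": annual_income(
                                model, site_id, year, streams, rate
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def uptake_sweep(
    activity: Sequence[ActivityYear],
    policy: TravelSubsidyPolicy,
    uptakes: Sequence[float] = DEFAULT_UPTAKES,
    schedule: Optional[DiscountSchedule] = None,
) -> pd.DataFrame:
    """Travel-subsidy spend per year at each uptake fraction, plus totals.

    Long format like :func:`fta_sweep`; the multi-year total appears as a
    row with ``year == "total"`` (the sum of the rounded yearly cells).
    """
    if schedule is None:
        raise ValueError("a discount schedule is required")
    rows = []
    for uptake in uptakes:
        total = 0
        for year in activity:
            amount = travel_subsidy_cost(
                year, policy, schedule, uptake_override=uptake
            )
            total += amount
            rows.append(
                {
                    "year": year.year_label,
                    "parameter": "uptake_fraction",
                    "value": float(uptake),
                    "quantity": "travel_subsidy_cost",
                    "amount_aud": amount,
                }
            )
        rows.append(
            {
                "year": "total",
                "parameter": "uptake_fraction",
                "value": float(uptake),
                "quantity": "travel_subsidy_cost",
                "amount_aud": total,
            }
        )
    return pd.DataFrame(rows)
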