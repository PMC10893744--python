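"""Supply side: specialist headcount trends and demand/supply gap reports.

Headcounts are registered practitioners at their primary registration
location (not FTE), so the gap metric is deliberately descriptive: expected
cases per registered specialist, by profession, remoteness band and year.
A band with zero registered supply but positive demand is flagged as a
shortage — patients or clinicians must travel — rather than given an
infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .types import CaseTable, RemotenessBand, WorkforceSeries


@dataclass(frozen=True)
class SupplyTrend:
    """Log-linear headcount trend for one profession."""

    profession: str
    base_year: int
    base_headcount: float
    annual_growth: float

    def __post_init__(self):
        if self.annual_growth <= 0:
            raise ValidationError("annual growth factor must be positive")

    def expected(self, year: int) -> float:
        return self.base_headcount * self.annual_growth ** (year - self.base_year)


def fit_supply_trend(series: WorkforceSeries, profession: str) -> SupplyTrend:
    """OLS fit of log headcount on year for one profession (state-wide)."""
    df = series.data[series.data["profession"] == profession]
    if series.is_stratified:
        df = df.groupby("year", observed=True, as_index=False)["headcount"].sum()
    if len(df) < 3:
        raise InsufficientDataError(
            f"supply trend for {profession!r} needs >= 3 years, got {len(df)}"
        )
    years = df["year"].to_numpy(dtype=float)
    counts = df["headcount"].to_numpy(dtype=float)
    offset = 0.5 if (counts == 0).any() else 0.0
    ref = float(years.max())
    slope, intercept = np.polyfit(years - ref, np.log(counts + offset), 1)
    return SupplyTrend(
        profession=profession,
        base_year=int(ref),
        base_headcount=float(np.exp(intercept) - offset),
        annual_growth=float(np.exp(slope)),
    )


def project_supply(trend: SupplyTrend, horizon: Iterable[int]) -> WorkforceSeries:
    """Geometric headcount projection; real-valued, rounded only at display."""
    years = sorted(int(y) for y in horizon)
    if not years:
        raise ValidationError("empty projection horizon")
    if years[0] <= trend.base_year:
        raise ValidationError(
            f"horizon starts {years[0]}, not after base year {trend.base_year}"
        )
    rows = [
        {"profession": trend.profession, "year": y, "headcount": trend.expected(y)}
        for y in years
    ]
    return WorkforceSeries(pd.DataFrame(rows))


@dataclass(frozen=True)
class GapReport:
    """Cases-per-specialist ratios and shortage flags.

    ``table`` columns: profession, band, year, demand, supply,
    cases_per_specialist (NaN when supply is zero), shortage (True iff
    supply is zero while demand is positive). ``travel_necessity`` lists
    the (profession, band) pairs with any shortage year.
    """

    table: pd.DataFrame

    @property
    def travel_necessity(self) -> list[tuple[str, RemotenessBand]]:
        short = self.table[self.table["shortage"]]
        pairs = short[["profession", "band"]].drop_duplicates()
        return [
            (str(p), RemotenessBand(b))
            for p, b in zip(pairs["profession"], pairs["band"])
        ]


def compute_gap(
    demand: CaseTable,
    supply: WorkforceSeries,
    professions: Sequence[str],
) -> GapReport:
    """Compare band-stratified demand against band-stratified supply.

    ``demand`` is whatever case table the question concerns (total cases,
    or additional early-stage cases under a scenario); its per-(year, band)
    cell sum is the demand figure. Supply snapshots covering a single year
    are carried forward to every demand year.
    """
    if not demand.is_stratified:
        raise ValidationError("gap analysis needs band-stratified demand")
    if not supply.is_stratified:
        raise ValidationError("gap analysis needs band-stratified supply")
    for prof in professions:
        if prof not in supply.professions:
            raise ValidationError(f"profession {prof!r} absent from supply series")

    demand_by = (
        demand.cells.groupby(["year", "band"], observed=True)["cases"]
        .sum()
        .sort_index()
    )
    rows = []
    for (year, band), d in demand_by.items():
        band = RemotenessBand(band)
        for prof in professions:
            s = supply.headcount(prof, year=int(year), band=band)
            ratio = d / s if s > 0 else float("nan")
            rows.append(
                {
                    "profession": prof,
                    "band": band,
                    "year": int(year),
                    "demand": float(d),
                    "supply": s,
                    "cases_per_specialist": ratio,
                    "shortage": bool(s == 0 and d > 0),
                }
            )
    return GapReport(table=pd.DataFrame(rows))
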