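"""Demand side: incidence trend fitting, projection, and decomposition of
annual totals by diagnostic stage and remoteness band.

The projection model is a log-linear (constant multiplicative growth) trend:
``log N_y = a + b (y - y_ref)``, fitted by ordinary least squares on the log
counts. That choice matches the 2.2-3.7 %/yr growth of registry incidence in
a growing, ageing population, and folds population growth, all-cause
mortality and migration into a single empirical trend — no age-period-cohort
structure is attempted. Stage and remoteness decompositions are proportional
allocations, so they conserve year totals by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InsufficientDataError, ValidationError
from .types import (
    BANDS,
    STAGES,
    CaseTable,
    RemotenessShares,
    StageDistribution,
)


@dataclass(frozen=True)
class IncidenceHistory:
    """Observed annual new-case counts for one region.

    ``counts`` maps consecutive calendar years to non-negative counts.
    """

    counts: Mapping[int, float]
    region: str = "Victoria"

    def __post_init__(self):
        years = np.array(sorted(self.counts), dtype=int)
        if len(years) and not np.array_equal(np.diff(years), np.ones(len(years) - 1, int)):
            raise ValidationError(f"history years must be consecutive: {years.tolist()}")
        vals = np.array([self.counts[y] for y in years], dtype=float)
        if (vals < 0).any():
            raise ValidationError("history counts must be non-negative")
        object.__setattr__(self, "counts", {int(y): float(self.counts[y]) for y in years})

    @property
    def years(self) -> list[int]:
        return sorted(self.counts)

    @property
    def last_year(self) -> int:
        return max(self.counts)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="cases").sort_index()


@dataclass(frozen=True)
class TrendModel:
    """Fitted log-linear incidence trend.

    ``intercept`` is the log expected count at ``reference_year`` (the last
    observed year), ``slope`` the log annual growth; ``annual_growth`` is
    ``exp(slope)``. ``slope_se`` and ``residual_variance`` come from the OLS
    fit and feed the growth-factor confidence interval.
    """

    intercept: float
    slope: float
    reference_year: int
    residual_variance: float = 0.0
    slope_se: float = float("nan")
    n_obs: int = 0
    offset: float = 0.0

    @property
    def annual_growth(self) -> float:
        return float(np.exp(self.slope))

    def growth_interval(self, z: float = 1.96) -> tuple[float, float]:
        """Normal-approximation confidence interval for the growth factor."""
        if not np.isfinite(self.slope_se):
            return (self.annual_growth, self.annual_growth)
        lo, hi = self.slope - z * self.slope_se, self.slope + z * self.slope_se
        return float(np.exp(lo)), float(np.exp(hi))

    def expected(self, year: int) -> float:
        """Expected count at ``year`` on the original (count) scale."""
        return float(np.exp(self.intercept + self.slope * (year - self.reference_year))
                     - self.offset)


def fit_incidence_trend(
    history: IncidenceHistory, *, offset: float | None = None
) -> TrendModel:
    """OLS fit of log counts on calendar year.

    ``offset`` is added inside the log to guard zero counts; by default it
    is 0.5 when the history contains zeros and 0 otherwise, so noise-free
    geometric series are recovered exactly.
    """
    series = history.as_series()
    if len(series) < 3:
        raise InsufficientDataError(
            f"trend fit needs >= 3 years, got {len(series)}"
        )
    if (series <= 0).all():
        raise DegenerateFitError("all-zero history: growth is unidentified")
    if offset is None:
        offset = 0.5 if (series == 0).any() else 0.0

    years = series.index.to_numpy(dtype=float)
    ref = float(history.last_year)
    x = years - ref
    y = np.log(series.to_numpy(dtype=float) + offset)
    coef, resid = np.polyfit(x, y, 1, full=True)[:2]
    slope, intercept = float(coef[0]), float(coef[1])
    n = len(x)
    dof = n - 2
    ss_res = float(resid[0]) if len(resid) else 0.0
    resid_var = ss_res / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = float(np.sqrt(resid_var / sxx)) if sxx > 0 and dof > 0 else float("nan")
    return TrendModel(
        intercept=intercept,
        slope=slope,
        reference_year=int(ref),
        residual_variance=resid_var,
        slope_se=slope_se,
        n_obs=n,
        offset=offset,
    )


def project_incidence(trend: TrendModel, horizon: Iterable[int]) -> CaseTable:
    """Project annual totals over ``horizon`` (must start after the data)."""
    years = sorted(int(y) for y in horizon)
    if not years:
        raise ValidationError("empty projection horizon")
    if years[0] <= trend.reference_year:
        raise ValidationError(
            f"horizon starts {years[0]}, inside the fitted data "
            f"(last observed {trend.reference_year})"
        )
    totals = {y: trend.expected(y) for y in years}
    return CaseTable.from_totals(
        totals, explicit=True, name="projected",
        metadata={"annual_growth": trend.annual_growth},
    )


def apply_stage_distribution(
    totals: CaseTable, shares: StageDistribution
) -> CaseTable:
    """Decompose year totals into stage cells: ``C_{y,k} = N_y * s_k``.

    Per-year stage sums equal N_y exactly (shares sum to 1), so the result
    carries consistent totals.
    """
    if not totals.is_empty:
        raise ValidationError("table already has stage cells")
    rows = []
    for y in totals.years:
        n = totals.total(y)
        for stage in STAGES:
            rows.append({"year": y, "stage": stage, "cases": n * shares[stage]})
    return CaseTable.from_cells(
        pd.DataFrame(rows),
        totals={y: totals.total(y) for y in totals.years},
        name=totals.name,
        metadata=dict(totals.metadata),
    )


def allocate_by_remoteness(
    table: CaseTable, shares: RemotenessShares
) -> CaseTable:
    """Split every stage cell (and total) across remoteness bands:
    ``C_{y,k,m} = w_m * C_{y,k}``. Band sums reproduce the input exactly."""
    if table.is_stratified:
        raise ValidationError("table is already band-stratified")
    if table.is_empty:
        raise ValidationError("allocate after stage decomposition, not on totals")
    rows = []
    for _, r in table.cells.iterrows():
        for band in BANDS:
            rows.append(
                {
                    "year": int(r["year"]),
                    "stage": r["stage"],
                    "band": band,
                    "cases": float(r["cases"]) * shares[band],
                }
            )
    tot_rows = []
    for y in table.years:
        for band in BANDS:
            tot_rows.append(
                {"year": y, "band": band, "total": table.total(y) * shares[band]}
            )
    return CaseTable(
        cells=pd.DataFrame(rows),
        totals=pd.DataFrame(tot_rows),
        explicit_totals=table.explicit_totals,
        name=table.name,
        metadata=dict(table.metadata),
    )
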