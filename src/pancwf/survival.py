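"""Survival side: expected 5-year survivor counts from stage-resolved cases.

Survival enters the model as a fixed 5-year relative-survival point
probability per stage (localized 41.6%, regional 14.4%, distant 3.0% in the
bundled inputs; stages I-II map to localized, III to regional, IV to
distant). Expected survivors are the linear functional

    S_y = sum_k C_{y,k} * v_k

with no interim mortality timing, competing risks, or lead-time bias
correction. Because the functional is linear, band-stratified survivor
counts sum exactly to the unstratified count, and survivors grow strictly
with the shifted fraction r whenever early-stage survival exceeds
late-stage survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .rounding import display_int, display_round
from .types import STAGES, CaseTable, RemotenessBand, Stage, SurvivalRates


def expected_survivors(cells: dict[Stage, float], rates: SurvivalRates) -> float:
    """Expected persons alive 5 years post-diagnosis for one year's cells."""
    missing = [k for k in cells if k not in rates.rates]
    if missing:
        raise ValidationError(f"missing survival rate for stage(s) {missing}")
    return float(sum(cells[k] * rates[k] for k in cells))


@dataclass(frozen=True)
class SurvivorTable:
    """Expected 5-year survivors per year (and band) for one scenario.

    ``survivors`` has columns ``year``, optional ``band``, ``survivors``
    (real-valued) and ``proportion`` (survivors / year total).
    """

    survivors: pd.DataFrame
    scenario: str = "current"

    @property
    def is_stratified(self) -> bool:
        return "band" in self.survivors.columns

    @property
    def years(self) -> list[int]:
        return sorted(self.survivors["year"].unique().tolist())

    def value(self, year: int, band: RemotenessBand | None = None) -> float:
        df = self.survivors
        mask = df["year"] == year
        if band is not None:
            if not self.is_stratified:
                raise ValidationError("survivor table is not band-stratified")
            mask &= df["band"] == band
            sub = df.loc[mask, "survivors"]
            if len(sub) != 1:
                raise KeyError(f"no unique survivors for {year}, {band}")
            return float(sub.iloc[0])
        return float(df.loc[mask, "survivors"].sum())

    def per_year(self) -> pd.Series:
        """Year-indexed survivors, summed over bands if stratified."""
        return (
            self.survivors.groupby("year", observed=True)["survivors"]
            .sum()
            .sort_index()
        )

    def display(self, year: int, band: RemotenessBand | None = None) -> int:
        return display_int(self.value(year, band))


def survivor_table(table: CaseTable, rates: SurvivalRates) -> SurvivorTable:
    """Expected survivors for every year (and band) of a case table."""
    if table.is_empty:
        raise ValidationError("stage cells required to compute survivors")
    rows = []
    if table.is_stratified:
        for y in table.years:
            for band in table.cells["band"].unique():
                band = RemotenessBand(band)
                s = expected_survivors(table.stage_cells(y, band), rates)
                n = table.total(y, band)
                rows.append(
                    {"year": y, "band": band, "survivors": s,
                     "proportion": s / n if n > 0 else float("nan")}
                )
    else:
        for y in table.years:
            s = expected_survivors(table.stage_cells(y), rates)
            n = table.total(y)
            rows.append(
                {"year": y, "survivors": s,
                 "proportion": s / n if n > 0 else float("nan")}
            )
    return SurvivorTable(survivors=pd.DataFrame(rows), scenario=table.name)


@dataclass(frozen=True)
class SurvivalGain:
    """Survivor-count gain of a proposed scenario over the current one."""

    per_year: pd.Series       # year -> S'_y - S_y (real)
    cumulative: float
    percent_per_year: pd.Series  # year -> integer percent increase

    @property
    def cumulative_display(self) -> int:
        return display_int(self.cumulative)


def survival_gain(proposed: SurvivorTable, current: SurvivorTable) -> SurvivalGain:
    """Per-year gain, cumulative gain and integer percent increase."""
    if proposed.years != current.years:
        raise ValidationError(
            f"year ranges differ: {proposed.years} vs {current.years}"
        )
    s_new = proposed.per_year()
    s_cur = current.per_year()
    gain = (s_new - s_cur).rename("survivor_gain")
    percent = pd.Series(
        {
            y: display_int(100.0 * gain[y] / s_cur[y]) if s_cur[y] > 0 else 0
            for y in gain.index
        },
        name="percent_increase",
    )
    return SurvivalGain(
        per_year=gain, cumulative=float(gain.sum()), percent_per_year=percent
    )


def overall_survival_rate(survivors: SurvivorTable, totals: CaseTable) -> pd.Series:
    """Integer-percent 5-year survival proportion per year.

    Years with a zero total are reported as missing (NA), not zero.
    """
    if survivors.years != totals.years:
        raise ValidationError("survivor and case tables cover different years")
    s = survivors.per_year()
    out = {}
    for y in s.index:
        n = totals.total(y)
        out[y] = display_int(100.0 * s[y] / n) if n > 0 else pd.NA
    return pd.Series(out, name="survival_percent")
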