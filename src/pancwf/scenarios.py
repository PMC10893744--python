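"""Stage-shift scenario engine.

An earlier-diagnosis scenario moves a fraction ``r`` of current stage-IV
diagnoses and a fraction ``1 - q`` of current stage-III diagnoses into
stages I-II, holding the year's total incidence fixed (the conservative
assumption that screening changes stage at diagnosis, not the number of
cases). Per year:

    C'_IV   = (1 - r) * C_IV
    C'_III  = q * C_III
    C'_I-II = N_y - C'_III - C'_IV

Stage I-II is obtained by subtraction from the conserved total rather than
by adding shifted cases to the early-stage cell, because published input
rows round each cell independently: the totals are self-consistent, the
rounded cells are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InfeasibleScenarioError, ValidationError
from .rounding import display_round
from .types import CaseTable, RemotenessBand, Stage, StageShiftScenario

_NEG_TOL = 1e-9


def apply_stage_shift(
    cells: dict[Stage, float], total: float, scenario: StageShiftScenario
) -> dict[Stage, float]:
    """Shift one year's stage cells; conserves ``total`` exactly.

    The identity scenario (r=0, q=1) returns the input unchanged, bit for
    bit — including any cell-sum/total discrepancy an explicit published
    total may carry.
    """
    if scenario.is_identity:
        return dict(cells)
    new_iv = (1.0 - scenario.stage_iv_shift) * cells[Stage.IV]
    new_iii = scenario.stage_iii_retained * cells[Stage.III]
    new_early = total - new_iii - new_iv
    if new_early < -_NEG_TOL:
        raise InfeasibleScenarioError(
            f"scenario {scenario.name!r}: retained stage III ({new_iii:.2f}) "
            f"plus residual stage IV ({new_iv:.2f}) exceed the year total {total:.2f}"
        )
    return {Stage.I_II: max(new_early, 0.0), Stage.III: new_iii, Stage.IV: new_iv}


def build_scenario_table(
    status_quo: CaseTable, scenario: StageShiftScenario
) -> CaseTable:
    """Apply the stage shift to every year (and band) of a case table."""
    if status_quo.is_empty:
        if len(status_quo.totals) == 0:
            return status_quo.rename(scenario.name, scenario=scenario.name)
        raise ValidationError("stage cells required before applying a scenario")
    rows = []
    if status_quo.is_stratified:
        for y in status_quo.years:
            for band in status_quo.cells["band"].unique():
                band = RemotenessBand(band)
                shifted = apply_stage_shift(
                    status_quo.stage_cells(y, band), status_quo.total(y, band), scenario
                )
                rows += [
                    {"year": y, "stage": k, "band": band, "cases": v}
                    for k, v in shifted.items()
                ]
    else:
        for y in status_quo.years:
            shifted = apply_stage_shift(
                status_quo.stage_cells(y), status_quo.total(y), scenario
            )
            rows += [{"year": y, "stage": k, "cases": v} for k, v in shifted.items()]
    return CaseTable(
        cells=pd.DataFrame(rows),
        totals=status_quo.totals.copy(),
        explicit_totals=status_quo.explicit_totals,
        name=scenario.name,
        metadata={**status_quo.metadata, "scenario": scenario.name,
                  "stage_iv_shift": scenario.stage_iv_shift,
                  "stage_iii_retained": scenario.stage_iii_retained},
    )


@dataclass(frozen=True)
class EarlyCasesGain:
    """Per-year and cumulative additional stage I-II cases under a scenario."""

    per_year: pd.Series          # year -> additional early-stage cases (real)
    cumulative: float
    by_band: pd.DataFrame | None = None  # year, band, delta (when stratified)

    @property
    def per_year_display(self) -> pd.Series:
        return pd.Series(
            display_round(self.per_year.to_numpy()).astype(int),
            index=self.per_year.index, name=self.per_year.name,
        )

    @property
    def cumulative_display(self) -> int:
        return int(display_round(self.cumulative))


def additional_early_cases(
    proposed: CaseTable, current: CaseTable
) -> EarlyCasesGain:
    """Stage I-II differences (proposed minus current), per year and cumulative."""
    if proposed.years != current.years:
        raise ValidationError(
            f"year ranges differ: {proposed.years} vs {current.years}"
        )
    if proposed.is_stratified != current.is_stratified:
        raise ValidationError("tables differ in band stratification")
    deltas = {}
    for y in current.years:
        deltas[y] = proposed.value(y, Stage.I_II) - current.value(y, Stage.I_II)
    per_year = pd.Series(deltas, name="additional_early_cases").sort_index()
    by_band = None
    if current.is_stratified:
        rows = []
        for y in current.years:
            for band in RemotenessBand:
                rows.append(
                    {
                        "year": y,
                        "band": band,
                        "delta": proposed.value(y, Stage.I_II, band)
                        - current.value(y, Stage.I_II, band),
                    }
                )
        by_band = pd.DataFrame(rows)
    return EarlyCasesGain(
        per_year=per_year, cumulative=float(per_year.sum()), by_band=by_band
    )


def apply_lead_time(
    status_quo: CaseTable, scenario: StageShiftScenario
) -> CaseTable:
    """Earlier-by-L-years variant (experimental).

    With lead time L <= 1 this is exactly :func:`build_scenario_table`: the
    shift happens within the diagnosis year. For L > 1 the interpretation
    implemented (one defensible reading of "diagnosed L years earlier") is
    that the first horizon year additionally absorbs the scenario's
    early-stage gains of the following L-1 horizon years, so its stage I-II
    cell and its year total grow by that pulled-forward sum. The output is
    flagged ``experimental`` in metadata and nothing downstream relies on it.
    """
    L = int(scenario.lead_time_years)
    shifted = build_scenario_table(status_quo, scenario)
    if L <= 1:
        return shifted
    years = status_quo.years
    first = years[0]
    needed = [first + k for k in range(1, L)]
    missing = [y for y in needed if y not in years]
    if missing:
        raise ValidationError(
            f"lead time {L} needs projections for {missing}, beyond the horizon"
        )
    gains = additional_early_cases(shifted, status_quo)
    if status_quo.is_stratified:
        extra_by_band = {
            band: float(
                gains.by_band.query("year in @needed and band == @band")["delta"].sum()
            )
            for band in RemotenessBand
        }
        cells = shifted.cells.copy()
        totals = shifted.totals.copy()
        for band, extra in extra_by_band.items():
            sel = (
                (cells["year"] == first)
                & (cells["stage"] == Stage.I_II)
                & (cells["band"] == band)
            )
            cells.loc[sel, "cases"] += extra
            tsel = (totals["year"] == first) & (totals["band"] == band)
            totals.loc[tsel, "total"] += extra
    else:
        extra = float(gains.per_year.loc[needed].sum())
        cells = shifted.cells.copy()
        totals = shifted.totals.copy()
        sel = (cells["year"] == first) & (cells["stage"] == Stage.I_II)
        cells.loc[sel, "cases"] += extra
        totals.loc[totals["year"] == first, "total"] += extra
    return CaseTable(
        cells=cells,
        totals=totals,
        explicit_totals=shifted.explicit_totals,
        name=scenario.name,
        metadata={**shifted.metadata, "experimental": True,
                  "lead_time_years": L},
    )
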