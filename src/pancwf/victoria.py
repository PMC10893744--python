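"""Published Victorian model inputs (2023-2027), bundled as an in-code fixture.

These are the publicly reported inputs for pancreatic-cancer workforce
planning in Victoria, Australia: status-quo projected new cases by year and
stage, the current stage distribution at diagnosis (Cancer Council NSW), US
SEER 5-year relative survival by stage (localized / regional / distant,
mapped to stages I-II / III / IV), population shares by Modified Monash
remoteness band, and registered specialist headcounts from the national
Health Workforce Data tool.

Cells are carried verbatim as printed; printed rows round each cell
independently, so cell sums may miss the printed year total by 1 (e.g.
198 + 297 + 495 = 990 under a total of 991). The year totals are
authoritative for scenario arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import (
    BANDS,
    CaseTable,
    RemotenessBand,
    RemotenessShares,
    Stage,
    StageDistribution,
    StageShiftScenario,
    SurvivalRates,
    WorkforceSeries,
)

#: Status-quo new cases by year: {year: (stages I-II, III, IV, total)}.
STATUS_QUO_CASES: dict[int, tuple[int, int, int, int]] = {
    2023: (198, 297, 495, 991),
    2024: (206, 308, 514, 1028),
    2025: (210, 315, 526, 1051),
    2026: (215, 323, 538, 1075),
    2027: (220, 330, 550, 1100),
}

#: Current stage distribution at diagnosis (I-II, III, IV).
STAGE_SHARES: tuple[float, float, float] = (0.20, 0.30, 0.50)

#: 5-year relative survival by stage: localized 41.6%, regional 14.4%,
#: distant 3.0% (US SEER; no Australian stage-specific figures exist).
SURVIVAL_RATES: tuple[float, float, float] = (0.416, 0.144, 0.030)

#: Population/demand shares by remoteness band (MM1, MM2, MM3, MM4-7),
#: back-calculated from the published band allocation of 400 additional
#: early-stage cases: 324/400, 23/400, 24/400, 29/400.
REMOTENESS_SHARES: tuple[float, float, float, float] = (0.81, 0.0575, 0.06, 0.0725)

#: Retained fraction of current stage-III cases under every published
#: scenario, back-calculated as 244 / 297 from the 2023 scenario rows.
STAGE_III_RETAINED: float = 0.8216

#: The three published earlier-diagnosis scenarios (stage-IV reduction r).
SCENARIO_SHIFTS: tuple[float, float, float] = (0.20, 0.50, 0.70)

_PROFESSIONS = (
    "endocrinology",
    "gastroenterology_hepatology",
    "palliative_medicine",
    "pain_medicine",
    "general_surgery",
    "radiation_oncology",
    "medical_oncology",
)

#: Projected state-wide registered headcounts per profession, 2023-2027.
WORKFORCE_SUPPLY: dict[int, tuple[int, ...]] = {
    2023: (1862, 2274, 601, 310, 4135, 914, 2104),
    2024: (1986, 2379, 646, 336, 4248, 946, 2241),
    2025: (2091, 2488, 695, 364, 4364, 979, 2388),
    2026: (2202, 2603, 747, 395, 4483, 1013, 2544),
    2027: (2318, 2723, 803, 429, 4605, 1048, 2711),
}

#: Current (snapshot-year 2023) headcounts by remoteness band. The
#: metropolitan row is unambiguous; the published non-metropolitan rows are
#: run-on digit strings and the tokenization below is a best-effort parse —
#: flagged uncertain, and nothing downstream asserts those cells.
WORKFORCE_BY_BAND: dict[RemotenessBand, tuple[int, ...]] = {
    RemotenessBand.METROPOLITAN: (1635, 1992, 463, 236, 3174, 734, 1588),
    RemotenessBand.REGIONAL_CENTRES: (55, 49, 53, 30, 274, 87, 166),
    RemotenessBand.LARGE_RURAL: (7, 19, 11, 0, 296, 28, 96),
    RemotenessBand.MEDIUM_SMALL_RURAL_PLUS: (7, 15, 3, 0, 176, 0, 3),
}

#: Which WORKFORCE_BY_BAND rows carry tokenization uncertainty.
WORKFORCE_BY_BAND_UNCERTAIN: dict[RemotenessBand, bool] = {
    RemotenessBand.METROPOLITAN: False,
    RemotenessBand.REGIONAL_CENTRES: True,
    RemotenessBand.LARGE_RURAL: True,
    RemotenessBand.MEDIUM_SMALL_RURAL_PLUS: True,
}


@dataclass(frozen=True)
class VictoriaFixture:
    """The bundled published inputs, ready for the pipeline."""

    case_table: CaseTable
    stage_shares: StageDistribution
    survival_rates: SurvivalRates
    remoteness_shares: RemotenessShares
    supply: WorkforceSeries           # state-wide, by year
    supply_by_band: WorkforceSeries   # 2023 snapshot, by band (partly uncertain)
    scenarios: tuple[StageShiftScenario, ...]

    @property
    def professions(self) -> tuple[str, ...]:
        return _PROFESSIONS


def victoria_fixture() -> VictoriaFixture:
    """Return the published Victorian inputs as validated model objects."""
    rows = []
    totals = {}
    for year, (i_ii, iii, iv, total) in STATUS_QUO_CASES.items():
        rows += [
            {"year": year, "stage": Stage.I_II, "cases": i_ii},
            {"year": year, "stage": Stage.III, "cases": iii},
            {"year": year, "stage": Stage.IV, "cases": iv},
        ]
        totals[year] = float(total)
    case_table = CaseTable.from_cells(
        pd.DataFrame(rows), totals=totals, name="status_quo",
        metadata={"source": "published Victorian projection, 2023-2027"},
    )

    supply_rows = [
        {"profession": prof, "year": year, "headcount": head}
        for year, heads in WORKFORCE_SUPPLY.items()
        for prof, head in zip(_PROFESSIONS, heads)
    ]
    supply = WorkforceSeries(pd.DataFrame(supply_rows))

    band_rows = [
        {"profession": prof, "year": 2023, "band": band, "headcount": head}
        for band, heads in WORKFORCE_BY_BAND.items()
        for prof, head in zip(_PROFESSIONS, heads)
    ]
    supply_by_band = WorkforceSeries(pd.DataFrame(band_rows))
    supply_by_band.data.attrs["uncertain_bands"] = [
        str(b) for b, flag in WORKFORCE_BY_BAND_UNCERTAIN.items() if flag
    ]

    scenarios = tuple(
        StageShiftScenario(
            name=f"shift{int(round(r * 100))}",
            stage_iv_shift=r,
            stage_iii_retained=STAGE_III_RETAINED,
        )
        for r in SCENARIO_SHIFTS
    )

    return VictoriaFixture(
        case_table=case_table,
        stage_shares=StageDistribution.from_sequence(STAGE_SHARES),
        survival_rates=SurvivalRates.from_sequence(SURVIVAL_RATES),
        remoteness_shares=RemotenessShares.from_sequence(REMOTENESS_SHARES),
        supply=supply,
        supply_by_band=supply_by_band,
        scenarios=scenarios,
    )
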