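#!/usr/bin/env python
"""Geography: survivors by remoteness band and the workforce gap report.

Allocates demand across the four Modified Monash bands
(81% / 5.75% / 6% / 7.25%), recomputes survivors per band for the current
and base-case (70% shift) scenarios, and compares each band's additional
early-stage cases against its registered specialist headcounts. Writes
results/survivors_by_band.csv and results/gap_report.csv.
"""

from pathlib import Path

import pandas as pd

from pancwf import (
    additional_early_cases,
    allocate_by_remoteness,
    build_scenario_table,
    compute_gap,
    survivor_table,
    victoria_fixture,
)
from pancwf.types import BANDS, CaseTable, Stage

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    fx = victoria_fixture()
    status_quo = fx.case_table
    base_case = next(s for s in fx.scenarios if s.stage_iv_shift == 0.70)

    cur_band = allocate_by_remoteness(status_quo, fx.remoteness_shares)
    prop_band = allocate_by_remoteness(
        build_scenario_table(status_quo, base_case), fx.remoteness_shares
    )
    rows = []
    print("5-year survivors by remoteness band (2023):")
    for name, table in (("current", cur_band), (base_case.name, prop_band)):
        surv = survivor_table(table, fx.survival_rates)
        for y in surv.years:
            for band in BANDS:
                rows.append({"scenario": name, "year": y, "band": str(band),
                             "survivors": surv.value(y, band),
                             "survivors_display": surv.display(y, band)})
        print(f"  {name}: " + ", ".join(
            f"{band.value}={surv.display(2023, band)}" for band in BANDS))
    pd.DataFrame(rows).to_csv(OUT / "survivors_by_band.csv", index=False)

    gains = additional_early_cases(prop_band, cur_band)
    demand = CaseTable.from_cells(
        gains.by_band.assign(stage=Stage.I_II).rename(columns={"delta": "cases"})[
            ["year", "stage", "band", "cases"]
        ],
        name="additional_early_cases",
    )
    gap = compute_gap(demand, fx.supply_by_band, fx.supply_by_band.professions)
    gap.table.to_csv(OUT / "gap_report.csv", index=False)
    shortages = gap.travel_necessity
    g2023 = gains.by_band[gains.by_band["year"] == 2023].set_index("band")["delta"]
    print("\nBase-case additional stage I-II cases, 2023: " + ", ".join(
        f"{b.value}={int(round(float(g2023.loc[b])))}" for b in BANDS))
    print(f"Shortage cells (zero registered supply, positive demand): "
          f"{int(gap.table['shortage'].sum())}")
    print("Profession/band pairs requiring patient or clinician travel:")
    for prof, band in shortages:
        print(f"  {prof} in {band.value}")
    print(f"\nWrote {OUT / 'survivors_by_band.csv'} and {OUT / 'gap_report.csv'}")


if __name__ == "__main__":
    main()
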