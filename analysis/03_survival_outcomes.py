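#!/usr/bin/env python
"""Survival outcomes: expected 5-year survivors under each scenario.

Applies the stage-specific 5-year relative survival probabilities
(41.6% / 14.4% / 3.0%) to the status-quo and scenario case tables;
reports per-year survivors, percent gains, overall survival proportions
and cumulative survivor gains. Writes results/survivors.csv.
"""

from pathlib import Path

import pandas as pd

from pancwf import (
    build_scenario_table,
    overall_survival_rate,
    survival_gain,
    survivor_table,
    victoria_fixture,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    fx = victoria_fixture()
    status_quo = fx.case_table
    current = survivor_table(status_quo, fx.survival_rates)
    rows = [
        {"scenario": "current", "year": y,
         "survivors": current.value(y),
         "survivors_display": current.display(y),
         "percent_increase": 0}
        for y in current.years
    ]
    print("Expected patients alive 5 years post-diagnosis:")
    print("  current:", [current.display(y) for y in current.years],
          "| overall rate:",
          f"{int(overall_survival_rate(current, status_quo)[2023])}%")
    for sc in fx.scenarios:
        table = build_scenario_table(status_quo, sc)
        surv = survivor_table(table, fx.survival_rates)
        gain = survival_gain(surv, current)
        rate = overall_survival_rate(surv, table)
        rows += [
            {"scenario": sc.name, "year": y,
             "survivors": surv.value(y),
             "survivors_display": surv.display(y),
             "percent_increase": int(gain.percent_per_year[y])}
            for y in surv.years
        ]
        print(f"  {sc.name}:", [surv.display(y) for y in surv.years],
              f"| overall rate: {int(rate[2023])}%",
              f"| cumulative extra survivors: {gain.cumulative_display}")
    pd.DataFrame(rows).to_csv(OUT / "survivors.csv", index=False)
    print(f"\nWrote {OUT / 'survivors.csv'}")


if __name__ == "__main__":
    main()
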