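#!/usr/bin/env python
"""Validation: parameter recovery on synthetic registry histories.

Generates 500 seeded 12-year Poisson incidence histories around a 2.5 %/yr
log-linear trend (~900 cases/yr at baseline), refits the trend on each, and
summarises bias and interval coverage. Writes results/synthetic_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pancwf import SynthParams, fit_incidence_trend, generate_incidence_history

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TRUE_GROWTH = 1.025
N_REPLICATES = 500


def main() -> None:
    rows = []
    for seed in range(N_REPLICATES):
        hist = generate_incidence_history(SynthParams(seed=seed))
        trend = fit_incidence_trend(hist)
        lo, hi = trend.growth_interval()
        rows.append({"seed": seed, "growth": trend.annual_growth,
                     "ci_lo": lo, "ci_hi": hi,
                     "covered": lo <= TRUE_GROWTH <= hi})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "synthetic_recovery.csv", index=False)
    mean = df["growth"].mean()
    print(f"True annual growth: {TRUE_GROWTH}")
    print(f"Mean fitted growth over {N_REPLICATES} replicates: {mean:.4f} "
          f"(bias {mean - TRUE_GROWTH:+.4f}, SD {df['growth'].std():.4f})")
    print(f"95% interval coverage: {df['covered'].mean():.1%}")
    print(f"Monte-Carlo SE of the mean: "
          f"{df['growth'].std() / np.sqrt(N_REPLICATES):.5f}")
    print(f"\nWrote {OUT / 'synthetic_recovery.csv'}")


if __name__ == "__main__":
    main()
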