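"""Synthetic registry-style data generator.

Generates inputs with the statistical structure the pipeline assumes — a
registry incidence history with log-linear growth and (optionally) Poisson
count noise, and near-linear specialist headcount growth per profession —
so every stage of the analysis is exercisable without any external data.
The scenario model itself is deterministic; noise exists solely to exercise
the trend-fitting operations.

Defaults mirror the published Victorian conditions: a 12-year history
(2010-2021) growing ~2.5 %/yr from ~900 cases, reaching ~991 by 2023, and
2023 headcount bases with per-profession growth factors matching the
published supply series.

One global seed drives everything; each output stream draws from its own
derived substream (``default_rng([seed, stream_id])``), so regenerating one
stream never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import victoria
from .errors import ValidationError
from .io import write_case_table, write_shares, write_workforce
from .types import (
    BANDS,
    CaseTable,
    RemotenessShares,
    StageDistribution,
    WorkforceSeries,
)
from .demand import IncidenceHistory

_STREAM_INCIDENCE = 1
_STREAM_WORKFORCE = 2

#: Published 2023 headcount bases and fitted annual growth per profession.
_DEFAULT_WORKFORCE: dict[str, tuple[float, float]] = {
    "endocrinology": (1862, 1.0563),
    "gastroenterology_hepatology": (2274, 1.0460),
    "palliative_medicine": (601, 1.0750),
    "pain_medicine": (310, 1.0846),
    "general_surgery": (4135, 1.0273),
    "radiation_oncology": (914, 1.0273),
    "medical_oncology": (2104, 1.0654),
}


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults are the study conditions."""

    base_incidence: float = 900.0
    incidence_growth: float = 1.025
    n_history_years: int = 12
    history_start_year: int = 2010
    noise_model: str = "poisson"          # none | poisson
    stage_shares: StageDistribution = field(
        default_factory=lambda: StageDistribution.from_sequence(victoria.STAGE_SHARES)
    )
    band_shares: RemotenessShares = field(
        default_factory=lambda: RemotenessShares.from_sequence(
            victoria.REMOTENESS_SHARES
        )
    )
    workforce: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WORKFORCE)
    )  # profession -> (base headcount, annual growth)
    workforce_start_year: int = 2023
    n_workforce_years: int = 5
    seed: int | None = None
    region: str = "synthetic"
    #: Optional pre-projected horizon totals; when set, the emitted bundle
    #: runs the pipeline in fixture mode on exactly these totals.
    pre_projected_totals: Mapping[int, float] | None = None

    def __post_init__(self):
        if self.noise_model not in {"none", "poisson"}:
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.seed is None:
            raise ValidationError("a seed is mandatory when noise_model != 'none'")
        if self.incidence_growth <= 0 or self.base_incidence < 0:
            raise ValidationError("incidence growth must be > 0 and base >= 0")
        if self.n_history_years < 3:
            raise ValidationError("need at least 3 history years to fit a trend")
        for prof, (base, growth) in self.workforce.items():
            if base < 0 or growth <= 0:
                raise ValidationError(f"invalid workforce params for {prof!r}")


def _rng(params: SynthParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed or 0), stream])


def geometric_means(base: float, growth: float, n: int) -> np.ndarray:
    """Noise-free geometric series ``base * growth**k`` for k = 0..n-1."""
    return base * growth ** np.arange(n, dtype=float)


def generate_incidence_history(params: SynthParams) -> IncidenceHistory:
    """Draw an annual incidence history; Poisson noise around the trend."""
    years = [params.history_start_year + k for k in range(params.n_history_years)]
    means = geometric_means(
        params.base_incidence, params.incidence_growth, params.n_history_years
    )
    if params.noise_model == "poisson":
        counts = _rng(params, _STREAM_INCIDENCE).poisson(means).astype(float)
    else:
        counts = means
    return IncidenceHistory(counts=dict(zip(years, counts)), region=params.region)


def generate_workforce_series(params: SynthParams) -> WorkforceSeries:
    """Per-profession geometric headcount growth, split across bands.

    Band splitting uses the configured band shares; headcounts are rounded
    to whole persons (registered practitioners are integers). With Poisson
    noise the state-wide count for each year is drawn around the geometric
    mean before splitting.
    """
    rng = _rng(params, _STREAM_WORKFORCE)
    years = [params.workforce_start_year + k for k in range(params.n_workforce_years)]
    rows = []
    for prof in sorted(params.workforce):
        base, growth = params.workforce[prof]
        means = geometric_means(base, growth, params.n_workforce_years)
        if params.noise_model == "poisson":
            totals = rng.poisson(means).astype(float)
        else:
            totals = means
        for year, total in zip(years, totals):
            for band in BANDS:
                rows.append(
                    {
                        "profession": prof,
                        "year": year,
                        "band": band,
                        "headcount": float(np.round(total * params.band_shares[band])),
                    }
                )
    return WorkforceSeries(pd.DataFrame(rows))


def generate_full_bundle(params: SynthParams, out_dir) -> dict[str, Path]:
    """Write a complete, loadable input bundle (CSV + config) to ``out_dir``.

    Emits ``cases.csv`` (the incidence history, stage-free), ``workforce.csv``,
    ``shares.csv`` and ``config.yaml``; the config points the pipeline at the
    generated files. Identical params and seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    history = generate_incidence_history(params)
    if params.pre_projected_totals is not None:
        cases = CaseTable.from_totals(
            {int(y): float(v) for y, v in params.pre_projected_totals.items()},
            explicit=True, name="cases",
        )
        demand_mode = "cases"
    else:
        cases = CaseTable.from_totals(history.counts, explicit=True, name="cases")
        demand_mode = "fit"
    cases_path = write_case_table(cases, out / "cases.csv", rounding="none")

    workforce = generate_workforce_series(params)
    workforce_path = write_workforce(workforce, out / "workforce.csv")

    shares = {f"stage_share.{k}": v for k, v in params.stage_shares.shares.items()}
    shares |= {f"band_share.{b}": v for b, v in params.band_shares.shares.items()}
    shares_path = write_shares(shares, out / "shares.csv")

    horizon_start = (
        min(params.pre_projected_totals)
        if params.pre_projected_totals
        else history.last_year + 2
    )
    horizon_end = (
        max(params.pre_projected_totals)
        if params.pre_projected_totals
        else horizon_start + 4
    )
    config = {
        "years": {"start": int(horizon_start), "end": int(horizon_end)},
        "stages": {"shares": {str(k): v for k, v in params.stage_shares.shares.items()}},
        "remoteness": {
            "shares": {str(b): v for b, v in params.band_shares.shares.items()}
        },
        "demand": {"mode": demand_mode},
        "io": {"cases": "cases.csv", "workforce": "workforce.csv"},
        "seed": int(params.seed or 0),
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))

    return {
        "cases": cases_path,
        "workforce": workforce_path,
        "shares": shares_path,
        "config": config_path,
    }
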