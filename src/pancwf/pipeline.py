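"""Pipeline orchestration: config -> demand -> scenarios -> survival -> gaps,
and CSV report rendering mirroring the published table layouts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from importlib.metadata import PackageNotFoundError, version as _dist_version

from .config import ModelConfig
from .demand import (
    allocate_by_remoteness,
    apply_stage_distribution,
    fit_incidence_trend,
    IncidenceHistory,
    project_incidence,
)
from .errors import ValidationError
from .io import read_case_table, read_workforce
from .rounding import display_round
from .scenarios import EarlyCasesGain, additional_early_cases, apply_lead_time
from .survival import (
    SurvivalGain,
    SurvivorTable,
    overall_survival_rate,
    survival_gain,
    survivor_table,
)
from .types import CaseTable, Stage
from .victoria import victoria_fixture
from .workforce import GapReport, compute_gap

log = logging.getLogger("pancwf")

CURRENT = "current"


@dataclass
class ReportBundle:
    """Everything one pipeline run produced.

    ``case_tables``/``survivors`` are keyed by scenario name plus the
    reserved key ``current`` for the status quo; ``gains``/``early_cases``
    hold each scenario's improvement over the status quo.
    """

    case_tables: dict[str, CaseTable]
    case_tables_by_band: dict[str, CaseTable]
    survivors: dict[str, SurvivorTable]
    survivors_by_band: dict[str, SurvivorTable]
    gains: dict[str, SurvivalGain]
    early_cases: dict[str, EarlyCasesGain]
    survival_percent: dict[str, pd.Series]
    gap: GapReport | None
    metadata: dict = field(default_factory=dict)


def _status_quo_table(config: ModelConfig) -> CaseTable:
    """Resolve the demand mode into a stage-resolved status-quo table."""
    mode = config.demand_mode
    if mode == "fixture" and config.cases_path is None and config.demand_totals is None:
        log.info("demand: bundled published case table")
        return victoria_fixture().case_table
    if mode in {"fixture", "cases"} and config.cases_path is not None:
        log.info("demand: case table from %s", config.cases_path)
        table = read_case_table(config.cases_path, name="status_quo")
        if table.is_empty:  # totals-only file: decompose with configured shares
            return apply_stage_distribution(table, config.stage_shares)
        return table
    if mode == "totals" or config.demand_totals is not None:
        log.info("demand: pre-projected totals from config")
        totals = CaseTable.from_totals(
            {y: config.demand_totals[y] for y in sorted(config.demand_totals)},
            explicit=True,
        )
        return apply_stage_distribution(totals, config.stage_shares)
    if mode == "fit":
        log.info("demand: fitting incidence trend from %s", config.cases_path)
        hist_table = read_case_table(config.cases_path, name="history")
        if not hist_table.is_empty:
            raise ValidationError("fit mode expects a stage-free history file")
        history = IncidenceHistory(
            counts={y: hist_table.total(y) for y in hist_table.years}
        )
        trend = fit_incidence_trend(history)
        log.info("fitted annual growth %.4f", trend.annual_growth)
        horizon = [y for y in config.year_range]
        totals = project_incidence(trend, horizon)
        return apply_stage_distribution(totals, config.stage_shares)
    raise ValidationError(f"unresolvable demand mode {mode!r}")


def run_pipeline(config: ModelConfig) -> ReportBundle:
    """Execute demand -> scenarios -> survival -> gap, in order.

    Deterministic given the config and input files; each stage logs at info
    level and any stage error aborts the run naming the stage.
    """
    try:
        status_quo = _status_quo_table(config)
    except Exception as err:
        raise type(err)(f"demand stage failed: {err}") from err

    case_tables: dict[str, CaseTable] = {CURRENT: status_quo}
    early_cases: dict[str, EarlyCasesGain] = {}
    try:
        for scenario in config.scenarios:
            log.info("scenario %s: r=%.2f q=%.4f L=%d", scenario.name,
                     scenario.stage_iv_shift, scenario.stage_iii_retained,
                     scenario.lead_time_years)
            table = apply_lead_time(status_quo, scenario)
            case_tables[scenario.name] = table
            if scenario.lead_time_years <= 1:
                early_cases[scenario.name] = additional_early_cases(table, status_quo)
    except Exception as err:
        raise type(err)(f"scenario stage failed: {err}") from err

    try:
        survivors = {
            name: survivor_table(table, config.survival_rates)
            for name, table in case_tables.items()
        }
        gains = {
            name: survival_gain(survivors[name], survivors[CURRENT])
            for name in case_tables
            if name != CURRENT
        }
        survival_percent = {
            name: overall_survival_rate(survivors[name], case_tables[name])
            for name in case_tables
        }
    except Exception as err:
        raise type(err)(f"survival stage failed: {err}") from err

    try:
        by_band = {
            name: allocate_by_remoteness(table, config.remoteness_shares)
            for name, table in case_tables.items()
        }
        survivors_by_band = {
            name: survivor_table(table, config.survival_rates)
            for name, table in by_band.items()
        }
    except Exception as err:
        raise type(err)(f"remoteness stage failed: {err}") from err

    gap = None
    try:
        supply_by_band = None
        if config.workforce_by_band_path is not None:
            supply_by_band = read_workforce(config.workforce_by_band_path)
        elif config.workforce_path is not None:
            wf = read_workforce(config.workforce_path)
            if wf.is_stratified:
                supply_by_band = wf
        else:
            supply_by_band = victoria_fixture().supply_by_band
        if supply_by_band is not None and config.scenarios:
            gap_name = config.gap_scenario or max(
                (s for s in config.scenarios),
                key=lambda s: s.stage_iv_shift,
            ).name
            if gap_name in early_cases:
                prop_cells = by_band[gap_name].cells
                cur_cells = by_band[CURRENT].cells
                demand_cells = prop_cells[prop_cells["stage"] == Stage.I_II].copy()
                current_cells = cur_cells[cur_cells["stage"] == Stage.I_II]
                merged = demand_cells.merge(
                    current_cells,
                    on=["year", "stage", "band"],
                    suffixes=("", "_current"),
                )
                merged["cases"] = merged["cases"] - merged["cases_current"]
                demand_table = CaseTable.from_cells(
                    merged[["year", "stage", "band", "cases"]],
                    name=f"additional_early_cases_{gap_name}",
                )
                gap = compute_gap(
                    demand_table, supply_by_band, supply_by_band.professions
                )
                log.info(
                    "gap: %d shortage cells across %d profession-band pairs",
                    int(gap.table["shortage"].sum()), len(gap.travel_necessity),
                )
    except Exception as err:
        raise type(err)(f"gap stage failed: {err}") from err

    try:
        pkg_version = _dist_version("pancwf")
    except PackageNotFoundError:
        pkg_version = "unknown"
    metadata = {
        "version": pkg_version,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "scenarios": [s.name for s in config.scenarios],
        "years": list(config.year_range),
    }
    return ReportBundle(
        case_tables=case_tables,
        case_tables_by_band=by_band,
        survivors=survivors,
        survivors_by_band=survivors_by_band,
        gains=gains,
        early_cases=early_cases,
        survival_percent=survival_percent,
        gap=gap,
        metadata=metadata,
    )


def _header_lines(bundle: ReportBundle) -> list[str]:
    meta = bundle.metadata
    return [
        f"generated_by: pancwf {meta.get('version')}",
        f"config_hash: {meta.get('config_hash')}",
        f"seed: {meta.get('seed')}",
    ]


def render_tables(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as CSV reports (display-rounded, unrounded retained).

    Emits ``cases_by_scenario.csv``, ``survivors.csv``,
    ``survivors_by_band.csv`` and, when a gap analysis ran,
    ``gap_report.csv``. Re-rendering the same bundle yields byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header_lines(bundle)
    paths: dict[str, Path] = {}

    frames = []
    for name, table in bundle.case_tables.items():
        df = table.cells.copy()
        df.insert(0, "scenario", name)
        df["year_total"] = [table.total(int(y)) for y in df["year"]]
        frames.append(df)
    cases = pd.concat(frames, ignore_index=True)
    cases["cases_display"] = display_round(cases["cases"].to_numpy()).astype(int)
    paths["cases_by_scenario"] = _write(
        cases, out / "cases_by_scenario.csv", header
    )

    rows = []
    for name, surv in bundle.survivors.items():
        for y in surv.years:
            s = surv.value(y)
            rows.append(
                {
                    "scenario": name,
                    "year": y,
                    "survivors": s,
                    "survivors_display": surv.display(y),
                    "proportion": float(
                        surv.survivors.loc[surv.survivors["year"] == y, "proportion"].iloc[0]
                    ),
                    "percent_increase": (
                        int(bundle.gains[name].percent_per_year[y])
                        if name in bundle.gains
                        else 0
                    ),
                }
            )
    paths["survivors"] = _write(pd.DataFrame(rows), out / "survivors.csv", header)

    rows = []
    for name, surv in bundle.survivors_by_band.items():
        df = surv.survivors.copy()
        df.insert(0, "scenario", name)
        df["survivors_display"] = display_round(df["survivors"].to_numpy()).astype(int)
        rows.append(df)
    paths["survivors_by_band"] = _write(
        pd.concat(rows, ignore_index=True), out / "survivors_by_band.csv", header
    )

    if bundle.gap is not None:
        gap = bundle.gap.table.copy()
        paths["gap_report"] = _write(gap, out / "gap_report.csv", header)
    return paths


def _write(df: pd.DataFrame, path: Path, header: list[str]) -> Path:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path
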