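"""CSV readers and writers for the model's tabular inputs and outputs.

Schemas
-------
``cases.csv``     — columns ``year, stage, band?, cases, year_total?``.
                    Stage-free rows (empty ``stage``) carry pre-projected
                    year totals; ``year_total`` values, when present,
                    override the per-year cell sum (published rows round
                    each cell independently of the printed total).
``workforce.csv`` — columns ``profession, year, band?, headcount``.
``shares.csv``    — columns ``key, value`` (e.g. ``stage_share.I-II``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rounding import display_round
from .types import CaseTable, WorkforceSeries


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def read_case_table(path, *, name: str | None = None) -> CaseTable:
    """Load a CaseTable from ``cases.csv``.

    Rows with an empty ``stage`` are totals-only rows; an explicit
    ``year_total`` column overrides cell sums for the years where it is set.
    An empty file yields an empty error-free table only when at least the
    header is present and there is nothing to validate; a CaseTable always
    needs totals, so a file with zero data rows raises.
    """
    df = _read_csv(path)
    required = {"year", "stage", "cases"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    stage_blank = df["stage"].isna() | (df["stage"].astype(str).str.strip() == "")
    cell_rows = df[~stage_blank].copy()
    total_rows = df[stage_blank].copy()

    explicit: dict[int, float] = {}
    if "year_total" in df.columns:
        with_totals = df[df["year_total"].notna()]
        for _, row in with_totals.iterrows():
            explicit[int(row["year"])] = float(row["year_total"])
    for _, row in total_rows.iterrows():
        explicit.setdefault(int(row["year"]), float(row["cases"]))

    table_name = name or Path(path).stem
    if len(cell_rows) == 0:
        if not explicit:
            raise ValidationError(f"{path}: no case rows and no year totals")
        return CaseTable.from_totals(explicit, explicit=True, name=table_name)

    keep = ["year", "stage", "cases"] + (["band"] if "band" in df.columns else [])
    cells = cell_rows[keep]
    if "band" in cells.columns and cells["band"].isna().all():
        cells = cells.drop(columns=["band"])
    if explicit:
        years = sorted(cells["year"].astype(int).unique())
        totals = {}
        for y in years:
            if y in explicit:
                totals[y] = explicit[y]
            else:
                totals[y] = float(cells.loc[cells["year"] == y, "cases"].sum())
        return CaseTable.from_cells(cells, totals=totals, name=table_name)
    return CaseTable.from_cells(cells, name=table_name)


def write_case_table(
    table: CaseTable,
    path,
    *,
    rounding: str = "half_away_from_zero",
    keep_unrounded: bool = True,
    header_lines: Iterable[str] = (),
) -> Path:
    """Write a CaseTable as CSV with display-rounded cells.

    ``rounding`` is ``half_away_from_zero`` (default) or ``none``; with
    ``keep_unrounded`` the real-valued cells are preserved in a parallel
    ``cases_unrounded`` column so the file round-trips losslessly.
    """
    path = Path(path)
    out = table.cells.copy()
    if len(out) == 0:
        out = pd.DataFrame(columns=["year", "stage", "cases"])
    totals = table.totals.set_index(
        ["year", "band"] if table.is_stratified else ["year"]
    )["total"]
    if len(out):
        keys = ["year", "band"] if table.is_stratified else ["year"]
        idx = out[keys[0]] if len(keys) == 1 else list(zip(out["year"], out["band"]))
        out["year_total"] = [float(totals.loc[i]) for i in idx]
    else:  # totals-only table
        out = table.totals.rename(columns={"total": "cases"}).copy()
        out["stage"] = ""
        out["year_total"] = out["cases"]
        out = out[["year", "stage", "cases", "year_total"]]
    if rounding == "half_away_from_zero":
        if keep_unrounded:
            out["cases_unrounded"] = out["cases"]
        out["cases"] = display_round(out["cases"].to_numpy()).astype(int)
    elif rounding != "none":
        raise ValidationError(f"unknown rounding mode {rounding!r}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
    return path


def read_workforce(path) -> WorkforceSeries:
    df = _read_csv(path)
    if "band" in df.columns and df["band"].isna().all():
        df = df.drop(columns=["band"])
    frac = df["headcount"].astype(float) % 1.0
    if not np.allclose(frac, 0.0):
        raise ValidationError(f"{path}: observed headcounts must be integers")
    return WorkforceSeries(df)


def write_workforce(series: WorkforceSeries, path, *, header_lines: Iterable[str] = ()) -> Path:
    path = Path(path)
    out = series.data.copy()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
    return path


def read_shares(path) -> dict[str, float]:
    """Read a flat ``key,value`` shares file into a dict."""
    df = _read_csv(path)
    missing = {"key", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return {str(k): float(v) for k, v in zip(df["key"], df["value"])}


def write_shares(shares: dict[str, float], path) -> Path:
    path = Path(path)
    pd.DataFrame({"key": list(shares), "value": list(shares.values())}).to_csv(
        path, index=False
    )
    return path
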