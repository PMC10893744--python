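"""Domain types: stages, remoteness bands, share vectors, case and workforce tables.

Conventions
-----------
* Diagnostic stage is a three-level factor: stages I-II (combined, the
  "early" / localized category), stage III (regional) and stage IV (distant).
* Geography is the Modified Monash Model collapsed to four bands:
  MM1 (metropolitan), MM2 (regional centres), MM3 (large rural towns) and
  MM4-7 combined (medium/small rural towns and beyond).
* Case counts are real-valued internally (expected cases per year); display
  rounding happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

_SUM_TOL = 1e-9
_CELL_TOL = 1e-6


class Stage(str, Enum):
    """Diagnostic stage at presentation, ordered I-II < III < IV."""

    I_II = "I-II"
    III = "III"
    IV = "IV"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Stages in their canonical (early to late) order.
STAGES: tuple[Stage, ...] = (Stage.I_II, Stage.III, Stage.IV)


class RemotenessBand(str, Enum):
    """Modified Monash remoteness bands; MM4 and above form one band."""

    METROPOLITAN = "metropolitan"                      # MM1
    REGIONAL_CENTRES = "regional_centres"              # MM2
    LARGE_RURAL = "large_rural"                        # MM3
    MEDIUM_SMALL_RURAL_PLUS = "medium_small_rural_plus"  # MM4-7 combined

    def __str__(self) -> str:
        return self.value


BANDS: tuple[RemotenessBand, ...] = tuple(RemotenessBand)


def _validate_proportions(
    name: str, values: Mapping, keys: Iterable, must_sum_to_one: bool
) -> dict:
    out = {}
    for key in keys:
        if key not in values:
            raise ValidationError(f"{name}: missing entry for {key!r}")
        v = float(values[key])
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}[{key}] = {v} outside [0, 1]")
        out[key] = v
    extra = set(values) - set(out)
    if extra:
        raise ValidationError(f"{name}: unknown keys {sorted(map(str, extra))}")
    if must_sum_to_one:
        total = sum(out.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(f"{name}: shares sum to {total!r}, expected 1")
    return out


@dataclass(frozen=True)
class StageDistribution:
    """Proportion of incident cases diagnosed at each stage; sums to 1."""

    shares: Mapping[Stage, float]

    def __post_init__(self):
        object.__setattr__(
            self,
            "shares",
            _validate_proportions("stage shares", self.shares, STAGES, True),
        )

    def __getitem__(self, stage: Stage) -> float:
        return self.shares[stage]

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "StageDistribution":
        """Build from (I-II, III, IV) ordered values."""
        return cls(dict(zip(STAGES, values)))


@dataclass(frozen=True)
class SurvivalRates:
    """5-year relative survival probability per stage (a point probability,
    not a curve); no sum constraint."""

    rates: Mapping[Stage, float]

    def __post_init__(self):
        object.__setattr__(
            self,
            "rates",
            _validate_proportions("survival rates", self.rates, STAGES, False),
        )

    def __getitem__(self, stage: Stage) -> float:
        return self.rates[stage]

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "SurvivalRates":
        return cls(dict(zip(STAGES, values)))


@dataclass(frozen=True)
class RemotenessShares:
    """Population/demand proportion per remoteness band; sums to 1."""

    shares: Mapping[RemotenessBand, float]

    def __post_init__(self):
        object.__setattr__(
            self,
            "shares",
            _validate_proportions("remoteness shares", self.shares, BANDS, True),
        )

    def __getitem__(self, band: RemotenessBand) -> float:
        return self.shares[band]

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "RemotenessShares":
        """Build from (MM1, MM2, MM3, MM4+) ordered values."""
        return cls(dict(zip(BANDS, values)))


@dataclass(frozen=True)
class StageShiftScenario:
    """An earlier-diagnosis scenario.

    Parameters
    ----------
    name:
        Scenario identifier (unique within a config).
    stage_iv_shift:
        Fraction r of current stage-IV cases shifted to stages I-II
        (the "X% reduction in current stage IV" headline number).
    stage_iii_retained:
        Fraction q of current stage-III cases that remain stage III; the
        complement also moves to stages I-II. Default 0.8216.
    lead_time_years:
        Years by which detection advances diagnosis; 0 or 1 means the shift
        happens within the diagnosis year (the conservative default). Values
        above 1 trigger the experimental pull-forward variant.
    """

    name: str
    stage_iv_shift: float
    stage_iii_retained: float = 0.8216
    lead_time_years: int = 0

    def __post_init__(self):
        if not 0.0 <= self.stage_iv_shift <= 1.0:
            raise ValidationError(f"stage_iv_shift = {self.stage_iv_shift} outside [0, 1]")
        if not 0.0 <= self.stage_iii_retained <= 1.0:
            raise ValidationError(
                f"stage_iii_retained = {self.stage_iii_retained} outside [0, 1]"
            )
        if int(self.lead_time_years) != self.lead_time_years or self.lead_time_years < 0:
            raise ValidationError("lead_time_years must be a non-negative integer")

    @property
    def is_identity(self) -> bool:
        return self.stage_iv_shift == 0.0 and self.stage_iii_retained == 1.0


def _check_years_consecutive(years: np.ndarray, what: str) -> None:
    if len(years) > 1 and not np.array_equal(np.diff(np.sort(years)), np.ones(len(years) - 1)):
        raise ValidationError(f"{what}: years must be consecutive, got {sorted(years)}")


@dataclass
class CaseTable:
    """Expected new cases by year x stage (x optional remoteness band).

    ``cells`` is a long-format frame with columns ``year``, ``stage``,
    optional ``band`` and ``cases``; it is empty for a totals-only table
    (e.g. a projected incidence series before stage decomposition).
    ``totals`` holds the per-year (and per-band, when stratified) totals
    N_y used by the scenario engine; when ``explicit_totals`` is set they
    came from the input and are allowed to disagree with the cell sums
    (published rows round each cell independently, so 198+297+495 = 990
    may sit under a printed total of 991).
    """

    cells: pd.DataFrame
    totals: pd.DataFrame
    explicit_totals: bool = False
    name: str = "status_quo"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cells = self._normalise_cells(self.cells)
        self.totals = self._normalise_totals(self.totals, self.is_stratified)
        self._validate()

    # -- construction -----------------------------------------------------

    @staticmethod
    def _normalise_cells(cells: pd.DataFrame) -> pd.DataFrame:
        cols = ["year", "stage", "band", "cases"]
        if cells is None or len(cells) == 0:
            base = [c for c in cols if cells is not None and c in getattr(cells, "columns", [])]
            keep = base or ["year", "stage", "cases"]
            return pd.DataFrame(columns=keep)
        cells = cells.copy()
        missing = {"year", "stage", "cases"} - set(cells.columns)
        if missing:
            raise ValidationError(f"case cells missing columns {sorted(missing)}")
        cells["year"] = cells["year"].astype(int)
        cells["stage"] = cells["stage"].map(Stage)
        if "band" in cells.columns:
            cells["band"] = cells["band"].map(RemotenessBand)
        cells["cases"] = cells["cases"].astype(float)
        order = [c for c in cols if c in cells.columns]
        return cells[order].sort_values(order[:-1]).reset_index(drop=True)

    @staticmethod
    def _normalise_totals(totals: pd.DataFrame, stratified: bool) -> pd.DataFrame:
        if totals is None or len(totals) == 0:
            raise ValidationError("a CaseTable requires per-year totals")
        totals = totals.copy()
        if "year" not in totals.columns or "total" not in totals.columns:
            raise ValidationError("totals need columns year, total")
        totals["year"] = totals["year"].astype(int)
        totals["total"] = totals["total"].astype(float)
        if stratified:
            if "band" not in totals.columns:
                raise ValidationError("stratified table needs band-resolved totals")
            totals["band"] = totals["band"].map(RemotenessBand)
            keys = ["year", "band"]
        else:
            totals = totals[["year", "total"]]
            keys = ["year"]
        return totals.sort_values(keys).reset_index(drop=True)

    @classmethod
    def from_totals(
        cls,
        totals: Mapping[int, float],
        *,
        explicit: bool = True,
        name: str = "status_quo",
        metadata: dict | None = None,
    ) -> "CaseTable":
        """Totals-only table (no stage decomposition yet)."""
        frame = pd.DataFrame(
            {"year": list(totals.keys()), "total": list(totals.values())}
        )
        return cls(
            cells=pd.DataFrame(columns=["year", "stage", "cases"]),
            totals=frame,
            explicit_totals=explicit,
            name=name,
            metadata=metadata or {},
        )

    @classmethod
    def from_cells(
        cls,
        cells: pd.DataFrame,
        *,
        totals: Mapping[int, float] | None = None,
        name: str = "status_quo",
        metadata: dict | None = None,
    ) -> "CaseTable":
        """Cell table; totals default to per-year cell sums (implicit)."""
        cells = cls._normalise_cells(cells)
        if totals is None:
            if len(cells) == 0:
                raise ValidationError("cannot infer totals from an empty cell table")
            keys = ["year", "band"] if "band" in cells.columns else ["year"]
            t = cells.groupby(keys, observed=True)["cases"].sum().reset_index()
            t = t.rename(columns={"cases": "total"})
            return cls(cells=cells, totals=t, explicit_totals=False,
                       name=name, metadata=metadata or {})
        frame = pd.DataFrame({"year": list(totals.keys()), "total": list(totals.values())})
        return cls(cells=cells, totals=frame, explicit_totals=True,
                   name=name, metadata=metadata or {})

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        if (self.totals["total"] < 0).any():
            raise ValidationError("year totals must be non-negative")
        _check_years_consecutive(self.totals["year"].unique(), f"CaseTable {self.name!r}")
        if len(self.cells) == 0:
            return
        if (self.cells["cases"] < 0).any():
            bad = self.cells[self.cells["cases"] < 0]
            raise ValidationError(f"negative case counts:\n{bad}")
        keys = ["year", "stage"] + (["band"] if self.is_stratified else [])
        if self.cells.duplicated(subset=keys).any():
            raise ValidationError(f"duplicate {tuple(keys)} rows in case table")
        if not self.explicit_totals:
            gkeys = ["year", "band"] if self.is_stratified else ["year"]
            sums = self.cells.groupby(gkeys, observed=True)["cases"].sum()
            for idx, total_row in self.totals.set_index(gkeys).iterrows():
                s = sums.get(idx, 0.0)
                if abs(s - total_row["total"]) > _CELL_TOL:
                    raise ValidationError(
                        f"cells for {idx} sum to {s}, stored total {total_row['total']}"
                    )

    # -- accessors --------------------------------------------------------

    @property
    def is_stratified(self) -> bool:
        return "band" in self.cells.columns

    @property
    def years(self) -> list[int]:
        return sorted(self.totals["year"].unique().tolist())

    @property
    def is_empty(self) -> bool:
        return len(self.cells) == 0

    def total(self, year: int, band: RemotenessBand | None = None) -> float:
        t = self.totals
        mask = t["year"] == year
        if band is not None:
            if "band" not in t.columns:
                raise ValidationError("table is not band-stratified")
            mask &= t["band"] == band
        sub = t.loc[mask, "total"]
        if len(sub) != 1:
            raise KeyError(f"no unique total for year={year}, band={band}")
        return float(sub.iloc[0])

    def value(self, year: int, stage: Stage, band: RemotenessBand | None = None) -> float:
        c = self.cells
        mask = (c["year"] == year) & (c["stage"] == stage)
        if band is not None:
            mask &= c["band"] == band
        sub = c.loc[mask, "cases"]
        if band is None and self.is_stratified:
            return float(sub.sum())
        if len(sub) != 1:
            raise KeyError(f"no unique cell for year={year}, stage={stage}, band={band}")
        return float(sub.iloc[0])

    def stage_cells(self, year: int, band: RemotenessBand | None = None) -> dict[Stage, float]:
        return {k: self.value(year, k, band) for k in STAGES}

    def rename(self, name: str, **metadata) -> "CaseTable":
        meta = {**self.metadata, **metadata}
        return replace(self, cells=self.cells.copy(), totals=self.totals.copy(),
                       name=name, metadata=meta)


@dataclass
class WorkforceSeries:
    """Registered-practitioner headcounts by profession x year (x band).

    Headcounts are persons registered at their primary practice location,
    not full-time equivalents. Observed registry series are integers;
    projected series may hold real values and are rounded at display.
    """

    data: pd.DataFrame  # columns: profession, year, [band], headcount

    def __post_init__(self):
        df = self.data.copy()
        missing = {"profession", "year", "headcount"} - set(df.columns)
        if missing:
            raise ValidationError(f"workforce series missing columns {sorted(missing)}")
        df["profession"] = df["profession"].astype(str)
        df["year"] = df["year"].astype(int)
        if "band" in df.columns:
            df["band"] = df["band"].map(RemotenessBand)
        df["headcount"] = df["headcount"].astype(float)
        if (df["headcount"] < 0).any():
            raise ValidationError("headcounts must be non-negative")
        keys = ["profession", "year"] + (["band"] if "band" in df.columns else [])
        if df.duplicated(subset=keys).any():
            raise ValidationError(f"duplicate {tuple(keys)} rows in workforce series")
        self.data = df.sort_values(keys).reset_index(drop=True)

    @property
    def is_stratified(self) -> bool:
        return "band" in self.data.columns

    @property
    def professions(self) -> list[str]:
        return sorted(self.data["profession"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def headcount(
        self, profession: str, year: int | None = None,
        band: RemotenessBand | None = None,
    ) -> float:
        """Headcount for a profession.

        With ``year=None``, or when the requested year is absent, falls back
        to the most recent available year (supply snapshots cover one year
        and are carried forward unchanged).
        """
        df = self.data[self.data["profession"] == profession]
        if len(df) == 0:
            raise KeyError(f"profession {profession!r} absent from supply series")
        if band is not None:
            if not self.is_stratified:
                raise ValidationError("workforce series is not band-stratified")
            df = df[df["band"] == band]
            if len(df) == 0:
                raise KeyError(f"no supply rows for {profession!r} in band {band}")
        elif self.is_stratified:
            df = df.groupby("year", observed=True, as_index=False)["headcount"].sum()
        if year is not None:
            past = df[df["year"] <= year]
            df = past if len(past) else df
            df = df[df["year"] == df["year"].max()]
        sub = df["headcount"]
        if len(sub) != 1:
            raise KeyError(f"no unique headcount for {profession!r}, year={year}, band={band}")
        return float(sub.iloc[0])
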