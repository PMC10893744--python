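"""Model configuration: a YAML dialect with sections
``years / stages / survival / remoteness / scenarios / io / demand / seed``.

Every section is optional; omitted sections fall back to the bundled
published Victorian inputs, so an empty file is a valid config that
reproduces the published base-case analysis.

Example
-------
.. code-block:: yaml

    years: {start: 2023, end: 2027}
    stages:
      shares: {I-II: 0.20, III: 0.30, IV: 0.50}
    survival:
      rates: {I-II: 0.416, III: 0.144, IV: 0.030}
    remoteness:
      shares: {metropolitan: 0.81, regional_centres: 0.0575,
               large_rural: 0.06, medium_small_rural_plus: 0.0725}
    scenarios:
      - {name: shift70, stage_iv_shift: 0.70, stage_iii_retained: 0.8216}
    demand:
      mode: fixture        # fixture | cases | totals | fit
    io:
      rounding: half_away_from_zero
    seed: 1
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import victoria
from .errors import ValidationError
from .types import (
    RemotenessShares,
    StageDistribution,
    StageShiftScenario,
    SurvivalRates,
)

_SCENARIO_KEYS = {"name", "stage_iv_shift", "stage_iii_retained", "lead_time_years"}
_DEMAND_MODES = {"fixture", "cases", "totals", "fit"}


@dataclass(frozen=True)
class ModelConfig:
    """Validated run configuration with fixture defaults applied."""

    years: tuple[int, int]
    stage_shares: StageDistribution
    survival_rates: SurvivalRates
    remoteness_shares: RemotenessShares
    scenarios: tuple[StageShiftScenario, ...]
    demand_mode: str = "fixture"
    demand_totals: dict[int, float] | None = None
    cases_path: Path | None = None
    workforce_path: Path | None = None
    workforce_by_band_path: Path | None = None
    rounding: str = "half_away_from_zero"
    gap_scenario: str | None = None
    seed: int | None = None
    source_text: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]


def _section(raw: dict, name: str) -> dict:
    sec = raw.get(name) or {}
    if not isinstance(sec, dict):
        raise ValidationError(f"config section [{name}] must be a mapping")
    return sec


def _resolve(base: Path, value: str | None) -> Path | None:
    if value is None:
        return None
    p = Path(value)
    return p if p.is_absolute() else base / p


def load_config(path) -> ModelConfig:
    """Load, validate and default-fill a model configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    base = path.parent

    years_sec = _section(raw, "years")
    years = (int(years_sec.get("start", 2023)), int(years_sec.get("end", 2027)))
    if years[1] < years[0]:
        raise ValidationError(f"[years] end {years[1]} before start {years[0]}")

    stages_sec = _section(raw, "stages")
    if "shares" in stages_sec:
        try:
            stage_shares = StageDistribution(
                {k: float(v) for k, v in stages_sec["shares"].items()}
            )
        except ValidationError as err:
            raise ValidationError(f"[stages].shares: {err}") from err
    else:
        stage_shares = StageDistribution.from_sequence(victoria.STAGE_SHARES)

    surv_sec = _section(raw, "survival")
    if "rates" in surv_sec:
        try:
            survival_rates = SurvivalRates(
                {k: float(v) for k, v in surv_sec["rates"].items()}
            )
        except ValidationError as err:
            raise ValidationError(f"[survival].rates: {err}") from err
    else:
        survival_rates = SurvivalRates.from_sequence(victoria.SURVIVAL_RATES)

    remote_sec = _section(raw, "remoteness")
    if "shares" in remote_sec:
        try:
            remoteness_shares = RemotenessShares(
                {k: float(v) for k, v in remote_sec["shares"].items()}
            )
        except ValidationError as err:
            raise ValidationError(f"[remoteness].shares: {err}") from err
    else:
        remoteness_shares = RemotenessShares.from_sequence(victoria.REMOTENESS_SHARES)

    if "scenarios" in raw and raw["scenarios"] is not None:
        scen_list = raw["scenarios"]
        if not isinstance(scen_list, list):
            raise ValidationError("[scenarios] must be a list of mappings")
        scenarios = []
        for i, entry in enumerate(scen_list):
            if not isinstance(entry, dict):
                raise ValidationError(f"[scenarios][{i}] must be a mapping")
            unknown = set(entry) - _SCENARIO_KEYS
            if unknown:
                raise ValidationError(
                    f"[scenarios][{i}]: unknown key(s) {sorted(unknown)}"
                )
            if "name" not in entry or "stage_iv_shift" not in entry:
                raise ValidationError(
                    f"[scenarios][{i}]: name and stage_iv_shift are required"
                )
            scenarios.append(StageShiftScenario(**entry))
        scenarios = tuple(scenarios)
    else:
        scenarios = victoria.victoria_fixture().scenarios
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValidationError(f"scenario names must be unique, got {names}")

    demand_sec = _section(raw, "demand")
    demand_mode = str(demand_sec.get("mode", "fixture"))
    if demand_mode not in _DEMAND_MODES:
        raise ValidationError(
            f"[demand].mode must be one of {sorted(_DEMAND_MODES)}, got {demand_mode!r}"
        )
    demand_totals = None
    if "totals" in demand_sec:
        demand_totals = {int(y): float(v) for y, v in demand_sec["totals"].items()}
    if demand_mode == "totals" and demand_totals is None:
        raise ValidationError("[demand].mode=totals requires [demand].totals")

    io_sec = _section(raw, "io")
    cases_path = _resolve(base, io_sec.get("cases"))
    workforce_path = _resolve(base, io_sec.get("workforce"))
    workforce_by_band_path = _resolve(base, io_sec.get("workforce_by_band"))
    for label, p in (
        ("io.cases", cases_path),
        ("io.workforce", workforce_path),
        ("io.workforce_by_band", workforce_by_band_path),
    ):
        if p is not None and not p.exists():
            raise ValidationError(f"[{label}] references missing file {p}")
    if demand_mode in {"cases", "fit"} and cases_path is None:
        raise ValidationError(f"[demand].mode={demand_mode} requires [io].cases")
    rounding = str(io_sec.get("rounding", "half_away_from_zero"))
    if rounding not in {"half_away_from_zero", "none"}:
        raise ValidationError(f"unknown rounding mode {rounding!r}")

    gap_scenario = raw.get("gap_scenario")
    if gap_scenario is not None and gap_scenario not in names:
        raise ValidationError(
            f"gap_scenario {gap_scenario!r} not among scenarios {names}"
        )

    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)

    return ModelConfig(
        years=years,
        stage_shares=stage_shares,
        survival_rates=survival_rates,
        remoteness_shares=remoteness_shares,
        scenarios=scenarios,
        demand_mode=demand_mode,
        demand_totals=demand_totals,
        cases_path=cases_path,
        workforce_path=workforce_path,
        workforce_by_band_path=workforce_by_band_path,
        rounding=rounding,
        gap_scenario=gap_scenario,
        seed=seed,
        source_text=text,
    )
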