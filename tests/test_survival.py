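"""Expected 5-year survivor counts and derived gain metrics."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pancwf import (
    Stage,
    StageShiftScenario,
    SurvivalRates,
    ValidationError,
    allocate_by_remoteness,
    build_scenario_table,
    expected_survivors,
    overall_survival_rate,
    survival_gain,
    survivor_table,
)
from pancwf.types import BANDS, CaseTable

RATES = SurvivalRates.from_sequence((0.416, 0.144, 0.030))


def scenario(r, name=None):
    return StageShiftScenario(name=name or f"shift{int(r*100)}", stage_iv_shift=r)


class TestExpectedSurvivors:
    def test_status_quo_2023(self):
        s = expected_survivors(
            {Stage.I_II: 198.0, Stage.III: 297.0, Stage.IV: 495.0}, RATES
        )
        assert s == pytest.approx(139.986)

    def test_twenty_percent_2023(self):
        s = expected_survivors(
            {Stage.I_II: 351.0, Stage.III: 244.0, Stage.IV: 396.0}, RATES
        )
        assert s == pytest.approx(193.03, abs=0.01)

    def test_zero_cases(self):
        assert expected_survivors(
            {Stage.I_II: 0.0, Stage.III: 0.0, Stage.IV: 0.0}, RATES
        ) == 0.0


class TestSurvivorTable:
    def test_current_column_matches_published(self, status_quo):
        surv = survivor_table(status_quo, RATES)
        published = {2023: 140, 2024: 145, 2025: 148, 2026: 152, 2027: 155}
        for y, expected in published.items():
            assert abs(surv.display(y) - expected) <= 1

    def test_metropolitan_current_2023(self, status_quo, fx):
        by_band = allocate_by_remoteness(status_quo, fx.remoteness_shares)
        surv = survivor_table(by_band, RATES)
        assert surv.display(2023, BANDS[0]) == 113

    def test_current_band_row_2023(self, status_quo, fx):
        by_band = allocate_by_remoteness(status_quo, fx.remoteness_shares)
        surv = survivor_table(by_band, RATES)
        published = (113, 8, 8, 10)
        for band, expected in zip(BANDS, published):
            assert abs(surv.display(2023, band) - expected) <= 1

    def test_zero_rates_give_zero_survivors(self, status_quo):
        surv = survivor_table(
            status_quo, SurvivalRates.from_sequence((0.0, 0.0, 0.0))
        )
        assert (surv.per_year() == 0).all()

    def test_unit_rates_recover_cell_sums(self, status_quo):
        surv = survivor_table(
            status_quo, SurvivalRates.from_sequence((1.0, 1.0, 1.0))
        )
        for y in status_quo.years:
            assert surv.value(y) == pytest.approx(
                sum(status_quo.stage_cells(y).values())
            )

    def test_band_survivors_sum_to_state_total(self, status_quo, fx):
        whole = survivor_table(status_quo, RATES)
        split = survivor_table(
            allocate_by_remoteness(status_quo, fx.remoteness_shares), RATES
        )
        for y in status_quo.years:
            assert split.value(y) == pytest.approx(whole.value(y), abs=1e-9)


class TestSurvivalGain:
    def test_twenty_percent_gain_38_percent(self, status_quo):
        cur = survivor_table(status_quo, RATES)
        new = survivor_table(build_scenario_table(status_quo, scenario(0.2)), RATES)
        gain = survival_gain(new, cur)
        assert int(gain.percent_per_year[2023]) == 38

    def test_identity_scenario_zero_gain(self, status_quo):
        cur = survivor_table(status_quo, RATES)
        same = survivor_table(
            build_scenario_table(
                status_quo,
                StageShiftScenario(name="id", stage_iv_shift=0.0, stage_iii_retained=1.0),
            ),
            RATES,
        )
        gain = survival_gain(same, cur)
        assert (gain.per_year == 0).all()
        assert (gain.percent_per_year == 0).all()

    def test_survivors_monotone_in_shift_fraction(self, status_quo):
        cur = survivor_table(status_quo, RATES)
        values = [
            survivor_table(
                build_scenario_table(status_quo, scenario(r, name=f"r{r}")), RATES
            ).value(2023)
            for r in (0.0, 0.2, 0.5, 0.7, 1.0)
        ]
        assert values == sorted(values)
        assert values[0] < values[-1]

    @given(r=st.floats(0.0, 0.999), dr=st.floats(1e-3, 0.5))
    def test_monotone_property(self, r, dr):
        rows = [
            {"year": 2023, "stage": s, "cases": c}
            for s, c in zip(["I-II", "III", "IV"], (200.0, 300.0, 500.0))
        ]
        table = CaseTable.from_cells(pd.DataFrame(rows))
        r2 = min(r + dr, 1.0)
        s_lo = survivor_table(
            build_scenario_table(table, scenario(r, name="lo")), RATES
        ).value(2023)
        s_hi = survivor_table(
            build_scenario_table(table, scenario(r2, name="hi")), RATES
        ).value(2023)
        assert s_hi > s_lo

    def test_mismatched_years_rejected(self, status_quo):
        cur = survivor_table(status_quo, RATES)
        short = CaseTable.from_cells(
            pd.DataFrame(
                [{"year": 2023, "stage": s, "cases": 10.0} for s in ["I-II", "III", "IV"]]
            )
        )
        with pytest.raises(ValidationError):
            survival_gain(survivor_table(short, RATES), cur)


class TestOverallSurvivalRate:
    def test_current_14_percent(self, status_quo):
        surv = survivor_table(status_quo, RATES)
        rate = overall_survival_rate(surv, status_quo)
        assert int(rate[2023]) == 14

    def test_seventy_percent_scenario_29_percent(self, status_quo):
        table = build_scenario_table(status_quo, scenario(0.7))
        rate = overall_survival_rate(survivor_table(table, RATES), table)
        assert int(rate[2023]) == 29

    def test_survivors_equal_totals_is_100_percent(self):
        rows = [
            {"year": 2023, "stage": s, "cases": c}
            for s, c in zip(["I-II", "III", "IV"], (200.0, 300.0, 500.0))
        ]
        t = CaseTable.from_cells(pd.DataFrame(rows))
        surv = survivor_table(t, SurvivalRates.from_sequence((1.0, 1.0, 1.0)))
        assert int(overall_survival_rate(surv, t)[2023]) == 100

    def test_zero_total_reported_missing(self):
        t = CaseTable.from_cells(
            pd.DataFrame(
                [{"year": 2023, "stage": s, "cases": 0.0} for s in ["I-II", "III", "IV"]]
            )
        )
        rate = overall_survival_rate(survivor_table(t, RATES), t)
        assert rate[2023] is pd.NA


class TestBoundedness:
    @given(
        cells=st.tuples(
            st.floats(0.0, 1e4), st.floats(0.0, 1e4), st.floats(0.0, 1e4)
        )
    )
    def test_survivors_never_exceed_total(self, cells):
        rows = [
            {"year": 2023, "stage": s, "cases": c}
            for s, c in zip(["I-II", "III", "IV"], cells)
        ]
        t = CaseTable.from_cells(pd.DataFrame(rows))
        surv = survivor_table(t, RATES)
        assert surv.value(2023) <= t.total(2023) + 1e-9
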