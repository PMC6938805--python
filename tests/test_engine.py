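"""Simulation orchestration: onsets, superposition, linearity, multi-year runs."""

import math

import numpy as np
import pytest

from sprayrisk.engine import simulate

from conftest import FLAT_CROPTAB, make_event, make_scenario, make_substance


def one_sub_matrix(events, days=120, temps=(20.0,) * 12, **kw):
    sub = make_substance(0, dt50=10.0, kfoc=100.0)
    scenario = make_scenario(events, days=days, temps=temps)
    return simulate(scenario, [sub], FLAT_CROPTAB, **kw), scenario, sub


class TestStructure:
    def test_zero_before_onset_and_piec_exact_on_application_day(self):
        m, scenario, _ = one_sub_matrix([make_event(day=50, rate=1.0)])
        # 1000 g/ha, CIF 0, mix rule with kfoc 100 -> 2.5 cm, p 1.5
        expected_piec = 1000.0 / (100.0 * 2.5 * 1.5)
        assert np.all(m.values[:49, 0] == 0.0)
        assert m.values[49, 0] == expected_piec

    def test_six_event_series_has_six_chronological_columns(self, apple_example):
        scenario, compounds, croptab = apple_example
        m = simulate(scenario, compounds, croptab)
        assert m.values.shape == (365, 6)
        onsets = [int(np.nonzero(m.values[:, j])[0][0]) + 1 for j in range(6)]
        assert onsets == [91, 101, 104, 106, 113, 120]
        assert m.labels == ["Mancozeb"] * 3 + ["Pyrimethanil", "Mancozeb", "Pyrimethanil"]

    def test_cumulative_is_row_sum(self, apple_example):
        scenario, compounds, croptab = apple_example
        m = simulate(scenario, compounds, croptab)
        assert np.array_equal(m.cumulative, m.values.sum(axis=1))

    def test_frozen_soil_keeps_series_constant(self):
        m, _, _ = one_sub_matrix([make_event(day=10)], temps=(-5.0,) * 12,
                                 freeze_stop=True)
        assert m.values[9, 0] > 0
        assert np.all(m.values[9:, 0] == m.values[9, 0])

    def test_series_strictly_decreasing_under_positive_rate(self):
        m, _, _ = one_sub_matrix([make_event(day=10)])
        col = m.values[9:, 0]
        assert np.all(np.diff(col) < 0)


class TestSuperposition:
    def test_two_identical_events_add_up(self):
        m, _, _ = one_sub_matrix(
            [make_event(0, day=1), make_event(1, day=11)], days=30
        )
        single = m.values[:, 0]
        # same pulse, shifted: the later column equals the earlier one shifted 10 d
        assert m.values[10:, 1] == pytest.approx(single[:20], rel=1e-12)
        assert m.cumulative[10] == pytest.approx(single[10] + single[0], rel=1e-12)

    def test_same_day_events_have_separate_columns(self):
        m, _, _ = one_sub_matrix(
            [make_event(0, day=15, rate=1.0), make_event(1, day=15, rate=2.0)],
            days=30,
        )
        assert m.values[14, 1] == pytest.approx(2.0 * m.values[14, 0], rel=1e-12)

    def test_same_day_event_order_does_not_change_cumulative(self):
        ma, _, _ = one_sub_matrix(
            [make_event(0, day=15, rate=1.0), make_event(1, day=15, rate=2.0)],
            days=30,
        )
        mb, _, _ = one_sub_matrix(
            [make_event(0, day=15, rate=2.0), make_event(1, day=15, rate=1.0)],
            days=30,
        )
        assert np.array_equal(ma.cumulative, mb.cumulative)


class TestLinearityAndDeterminism:
    def test_doubling_every_rate_doubles_every_entry(self, apple_example):
        scenario, compounds, croptab = apple_example
        base = simulate(scenario, compounds, croptab)
        scaled_events = [
            make_event(e.event_index, e.compound_id, e.application_day,
                       2.0 * e.rate_kg_ai_ha, e.bbch, e.degradation_factor,
                       e.mixing_depth_spec, e.compound_name)
            for e in scenario.events
        ]
        scaled = simulate(
            make_scenario(scaled_events, days=365), compounds, croptab
        )
        # bit-exact in the normal float range; the subnormal tail (< 1e-290,
        # fifty orders below any measurable concentration) may differ in ulps
        normal = 2.0 * base.values > 1e-290
        assert np.array_equal(scaled.values[normal], 2.0 * base.values[normal])
        assert scaled.values[~normal] == pytest.approx(
            2.0 * base.values[~normal], rel=1e-2, abs=5e-324
        )

    def test_horizon_extension_leaves_prefix_bit_identical(self):
        m_short, _, _ = one_sub_matrix([make_event(day=10)], days=100)
        m_long, _, _ = one_sub_matrix([make_event(day=10)], days=300)
        assert np.array_equal(m_long.values[:100], m_short.values)


class TestMultiYear:
    def test_decay_continues_across_the_year_boundary(self):
        sub = make_substance(0, dt50=100.0, kfoc=100.0)
        scenario = make_scenario([make_event(day=300, bbch=5)], days=730,
                                 temps=(20.0,) * 12)
        m = simulate(scenario, [sub], FLAT_CROPTAB)
        col = m.values[:, 0]
        k = math.log(2.0) / 100.0
        # constant temperature: one smooth exponential, no reset at day 366
        assert col[365] == pytest.approx(col[364] * math.exp(-k), rel=1e-12)
        assert col[729] == pytest.approx(col[299] * math.exp(-430 * k), rel=1e-10)

    def test_recycled_monthly_temperatures_repeat_rate_pattern(self):
        sub = make_substance(0, dt50=50.0, kfoc=100.0)
        temps = (0.5, 1.5, 5.0, 9.0, 13.5, 16.5, 18.5, 18.0, 14.5, 9.5, 4.5, 1.5)
        scenario = make_scenario([make_event(day=10, bbch=5)], days=730, temps=temps)
        m = simulate(scenario, [sub], FLAT_CROPTAB)
        col = m.values[:, 0]
        ratio_year1 = col[40] / col[39]  # within February, year 1
        ratio_year2 = col[405] / col[404]  # same calendar day, year 2
        assert ratio_year1 == pytest.approx(ratio_year2, rel=1e-12)
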