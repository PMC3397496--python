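"""Kiss-and-run update dynamics: redistribution, clamping, departures, runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karsim import (
    CompartmentChain,
    DepartureRule,
    DirectionProfile,
    RedistributionRule,
    SourceClamp,
    engine,
)
from karsim.engine import (
    ConfigError,
    apply_phase,
    apply_source_clamp,
    check_departure,
    redistribute_pair,
)

RULE = RedistributionRule(ratio=2.0, rounding="nearest")


def brute_force_depleted(total: int, ratio: int = 2) -> int:
    """Independent oracle: the split p + (T-p) minimizing |T - (1+r)p|."""
    return min(range(total + 1), key=lambda p: abs(total - (1 + ratio) * p))


class TestRedistributePair:
    @pytest.mark.parametrize(
        "total, orientation, expected",
        [
            (20, "anterograde", (7, 13)),
            (0, "anterograde", (0, 0)),
            (13, "anterograde", (4, 9)),
            (27, "anterograde", (9, 18)),
            (26, "retrograde", (17, 9)),
        ],
    )
    def test_integer_splits(self, total, orientation, expected):
        out = redistribute_pair(total, orientation, RULE, "integer")
        assert (out.proximal_amount, out.distal_amount) == expected
        assert out.total == total

    def test_real_mode_is_exact_division(self):
        out = redistribute_pair(20.0, "anterograde", RedistributionRule(2.0, "none"), "real")
        assert out.proximal_amount == pytest.approx(20 / 3)
        assert out.distal_amount == pytest.approx(40 / 3)

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            redistribute_pair(-1, "anterograde", RULE, "integer")

    @pytest.mark.parametrize("total", range(0, 1001))
    def test_matches_brute_force_minimizer(self, total):
        out = redistribute_pair(total, "anterograde", RULE, "integer")
        assert out.proximal_amount == brute_force_depleted(total)
        assert out.proximal_amount + out.distal_amount == total

    @given(total=st.integers(min_value=0, max_value=10**6))
    @settings(derandomize=True, max_examples=300)
    def test_conservation_and_nonnegativity(self, total):
        for orientation in ("anterograde", "retrograde"):
            out = redistribute_pair(total, orientation, RULE, "integer")
            assert out.proximal_amount + out.distal_amount == total
            assert out.proximal_amount >= 0 and out.distal_amount >= 0

    @given(total=st.integers(min_value=2, max_value=10**6))
    @settings(derandomize=True, max_examples=300)
    def test_enrichment_direction(self, total):
        ante = redistribute_pair(total, "anterograde", RULE, "integer")
        retro = redistribute_pair(total, "retrograde", RULE, "integer")
        assert ante.distal_amount >= ante.proximal_amount
        assert retro.proximal_amount >= retro.distal_amount


class TestSourceClamp:
    @pytest.mark.parametrize("partner_before", [0, 7, 25])
    def test_partner_set_unconditionally(self, partner_before):
        clamp = SourceClamp(source_index=0, clamp_value=10)
        src, partner = apply_source_clamp(clamp, (0, 1), RULE, "integer")
        assert (src, partner) == (10, 20)

    def test_pair_must_contain_source(self):
        with pytest.raises(ValueError):
            apply_source_clamp(SourceClamp(0, 10), (3, 4), RULE, "integer")


def _chain(contents):
    labels = ("ER", "IC", "cis", "med1", "med2", "med3", "med4", "TGN", "PGC")
    return CompartmentChain(labels, np.asarray(contents, dtype=float))


PHASE1 = ((0, 1), (2, 3), (4, 5), (6, 7))
PHASE2 = ((1, 2), (3, 4), (5, 6), (7, 8))
ALL_ANTE = DirectionProfile(None)
CLAMP = (SourceClamp(0, 10),)


class TestApplyPhase:
    def test_worked_row_four_to_five(self):
        # cargo scenario: round-4 state under phase 1 gives the round-5 row
        state = _chain([10, 8, 16, 3, 6, 0, 0, 0, 0])
        out = apply_phase(state, PHASE1, RULE, ALL_ANTE, CLAMP, "integer")
        np.testing.assert_array_equal(out.contents, [10, 20, 6, 13, 2, 4, 0, 0, 0])

    def test_all_zero_state_stays_zero_without_clamps(self):
        out = apply_phase(_chain(np.zeros(9)), PHASE1, RULE, ALL_ANTE, (), "integer")
        assert out.contents.sum() == 0

    def test_unpaired_compartments_untouched(self):
        state = _chain([10, 0, 0, 0, 0, 0, 0, 0, 42])
        out = apply_phase(state, PHASE1, RULE, ALL_ANTE, CLAMP, "integer")
        assert out["PGC"] == 42

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=9, max_size=9))
    @settings(derandomize=True, max_examples=200)
    def test_matches_pairwise_brute_force(self, contents):
        """A phase equals independent brute-force resplitting of each pair."""
        state = _chain(contents)
        out = apply_phase(state, PHASE2, RULE, ALL_ANTE, (), "integer")
        expected = list(map(float, contents))
        for i, j in PHASE2:
            total = contents[i] + contents[j]
            p = brute_force_depleted(total)
            expected[i], expected[j] = p, total - p
        np.testing.assert_array_equal(out.contents, expected)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=9, max_size=9))
    @settings(derandomize=True, max_examples=200)
    def test_phase_application_is_idempotent(self, contents):
        """Resplitting an already-split pair is a fixed point."""
        state = _chain(contents)
        once = apply_phase(state, PHASE1, RULE, ALL_ANTE, CLAMP, "integer")
        twice = apply_phase(once, PHASE1, RULE, ALL_ANTE, CLAMP, "integer")
        np.testing.assert_array_equal(once.contents, twice.contents)

    def test_already_split_pair_is_fixed_point(self):
        out = redistribute_pair(7 + 13, "anterograde", RULE, "integer")
        assert (out.proximal_amount, out.distal_amount) == (7, 13)


class TestDeparture:
    RULE5 = DepartureRule(terminal_index=8, threshold_fold=5.0, action="remove_all")

    def test_strictly_above_threshold_triggers(self):
        state = _chain([10, 0, 0, 0, 0, 0, 0, 0, 51])
        new, event = check_departure(state, self.RULE5, round_number=28)
        assert event is not None and event.amount == 51 and event.round == 28
        assert new["PGC"] == 0

    def test_exactly_at_threshold_does_not_trigger(self):
        state = _chain([10, 0, 0, 0, 0, 0, 0, 0, 50])
        new, event = check_departure(state, self.RULE5, round_number=1)
        assert event is None and new["PGC"] == 50

    def test_remove_half_leaves_rounded_half(self):
        rule = DepartureRule(8, 5.0, action="remove_half")
        state = _chain([10, 0, 0, 0, 0, 0, 0, 0, 51])
        new, event = check_departure(state, rule, round_number=1)
        assert new["PGC"] == 26 and event.amount == 25

    def test_first_departure_in_cargo_run(self, table1_run):
        assert table1_run.events[0].round == 32


class TestRun:
    def test_cargo_first_round(self, table1_config):
        traj = engine.run(table1_config, n_rounds=1)
        np.testing.assert_array_equal(traj.states[1], [10, 20, 0, 0, 0, 0, 0, 0, 0])

    def test_enzyme_round_four(self, table2_config):
        traj = engine.run(table2_config, n_rounds=4)
        np.testing.assert_array_equal(traj.states[4], [10, 9, 19, 9, 18, 22, 11, 9, 4])

    def test_invalid_config_raises_with_violations(self, table1_config):
        from dataclasses import replace
        from karsim import PairingSchedule

        bad = replace(table1_config, schedule=PairingSchedule((((0, 1), (1, 2)),)))
        with pytest.raises(ConfigError) as exc_info:
            engine.run(bad)
        assert any("disjoint" in v for v in exc_info.value.violations)

    def test_trajectory_is_nonnegative_and_integral(self, table1_run):
        assert np.all(table1_run.states >= 0)
        np.testing.assert_array_equal(table1_run.states, np.round(table1_run.states))

    def test_influx_logged_on_clamp_rounds(self, table1_config):
        traj = engine.run(table1_config, n_rounds=2)
        # round 1: ER-IC clamp injects 20 into the empty system
        assert traj.influx[1] == 20
        # round 2: ER idle (phase 2), no injection
        assert traj.influx[2] == 0
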