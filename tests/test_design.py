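"""Experiment design: pair sets, digit rules, run constraints, yoking,
event-table round trip."""

import numpy as np
import pandas as pd
import pytest

from densnav import design
from densnav.design import (
    Condition,
    build_run,
    digit_count_rule,
    events_to_run,
    make_pair_set,
    read_events,
    run_to_events,
    slot_onsets,
    write_events,
    yoke_trials,
)


class TestConditions:
    def test_code_flags(self):
        assert Condition("MA").has_memory and Condition("MA").has_adjust
        assert not Condition("NP").has_memory and not Condition("NP").has_adjust
        with pytest.raises(ValueError):
            Condition("XX")


class TestPairSet:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_pair_set_balance(self, scale, seed):
        ps = make_pair_set(scale, seed)
        assert len(ps.pairs) == 28
        starts = np.array([p[0] for p in ps.pairs])
        targets = np.array([p[1] for p in ps.pairs])
        assert np.all(starts != targets)
        # half of targets in each half of the scale
        assert np.sum(targets < scale.n_levels / 2) == 14
        # 14 upward, 14 downward trajectories
        assert np.sum(targets > starts) == 14
        # trajectories at least 5 steps
        assert np.all(np.abs(starts - targets) >= 5)


class TestDigitRules:
    def test_stochastic_rounding_bootstrap(self):
        rng = np.random.default_rng(0)
        draws = {digit_count_rule(3, None, rng) for _ in range(200)}
        assert draws == {3, 4}

    def test_integral_sum_is_exact(self):
        assert digit_count_rule(3, 1.0, rng=0) == 4

    def test_clamped_to_slots(self):
        assert digit_count_rule(6, 2.0, rng=0) == 6
        assert digit_count_rule(0, 0.0, rng=0) == 1

    def test_slot_onsets_domain(self):
        assert slot_onsets(6, rng=0) == (2, 3, 4, 5, 6, 7)
        onsets = slot_onsets(1, rng=1)
        assert len(onsets) == 1 and onsets[0] in {2, 3, 4, 5, 6, 7}
        with pytest.raises(ValueError):
            slot_onsets(7)
        with pytest.raises(ValueError):
            slot_onsets(0)


class TestRunConstruction:
    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_run_satisfies_printed_structure(self, scale, seed):
        rng = np.random.default_rng(seed)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        assert len(run.trials) == 28
        codes = [t.condition.code for t in run.trials]
        assert all(codes.count(c) == 7 for c in ("MA", "MP", "NA", "NP"))
        for block in run.sets:
            order = {t.condition.code: i for i, t in enumerate(block)}
            assert order["MA"] < order["NA"]
            assert order["MP"] < order["NP"]
        assert all(a != b for a, b in zip(codes, codes[1:]))

    def test_phase_structure(self, scale):
        rng = np.random.default_rng(5)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        for t in run.trials:
            assert len(t.initial_series) == 10
            assert 1.0 <= t.silence_s <= 3.0
            assert 0.0 <= t.iti_s <= 2.0
            if t.condition.has_memory:
                assert set(t.initial_series) == {t.target_level}
            else:
                assert t.target_level is None
                assert set(t.initial_series) == {0, scale.n_levels - 1}
                assert all(a != b for a, b in
                           zip(t.initial_series, t.initial_series[1:]))


class TestYoking:
    @pytest.fixture()
    def yoked(self, scale):
        rng = np.random.default_rng(21)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        series = {
            t.index: tuple(
                np.clip(
                    t.start_level + np.arange(40) * np.sign(
                        (t.target_level or 13) - t.start_level
                    ),
                    0,
                    25,
                ).astype(int)
            )
            for t in run.trials
            if t.condition.has_adjust
        }
        return yoke_trials(run, series, scale, rng), series

    def test_parity_series_copy_adjustment(self, yoked):
        run, series = yoked
        last = {"MA": None, "NA": None}
        for t in run.trials:
            code = t.condition.code
            if t.condition.has_adjust:
                assert t.adjust_series == series[t.index]
                last[code] = t
            else:
                src_stream = "MA" if t.condition.has_memory else "NA"
                if last[src_stream] is not None:
                    assert t.adjust_series == last[src_stream].adjust_series
                    assert t.yoke_source == last[src_stream].index
                else:
                    assert t.yoke_source is None  # dummy series bootstrap

    def test_adjustment_digits_copy_parity(self, yoked):
        run, _ = yoked
        last = {"MP": None, "NP": None}
        for t in run.trials:
            code = t.condition.code
            if not t.condition.has_adjust:
                last[code] = t
            else:
                src_stream = "MP" if t.condition.has_memory else "NP"
                if last[src_stream] is not None:
                    assert t.digit_slots == last[src_stream].digit_slots
                    assert t.digit_yoke_source == last[src_stream].index
                else:
                    assert 1 <= len(t.digit_slots) <= 6  # dummy digits

    def test_acoustic_matching_over_run(self, yoked):
        """Every non-bootstrap P-trial series is the exact series of an
        earlier A trial of the same memory stream, so pooled adjust-phase
        acoustics are matched across the task factor."""
        run, _ = yoked
        a_series = {t.index: t.adjust_series for t in run.trials
                    if t.condition.has_adjust}
        n_copies = 0
        for t in run.trials:
            if not t.condition.has_adjust and t.yoke_source is not None:
                assert t.adjust_series == a_series[t.yoke_source]
                assert t.yoke_source < t.index
                n_copies += 1
        assert n_copies >= 12  # at most one dummy bootstrap per stream

    def test_unresolved_series_error(self, scale):
        rng = np.random.default_rng(2)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        with pytest.raises(ValueError):
            yoke_trials(run, {}, scale, rng)


class TestEventTable:
    def test_round_trip_through_tsv(self, session, tmp_path):
        events = run_to_events(session.run)
        path = write_events(events, tmp_path / "events.tsv")
        reloaded = events_to_run(read_events(path))
        for a, b in zip(session.run.trials, reloaded.trials):
            assert a.condition.code == b.condition.code
            assert a.initial_series == b.initial_series
            assert a.adjust_series == b.adjust_series
            assert a.digit_slots == b.digit_slots
            assert a.target_level == b.target_level
            assert a.silence_s == pytest.approx(b.silence_s)
            assert a.iti_s == pytest.approx(b.iti_s)

    def test_stack_counts_per_trial(self, session):
        events = run_to_events(session.run)
        for _, g in events.groupby("trial_index"):
            assert (g.event_type == "initial_stack").sum() == 10
            assert (g.event_type == "adjust_stack").sum() == 40
            assert 1 <= (g.event_type == "digit").sum() <= 6
            digits = g[g.event_type == "digit"]
            adj0 = g[g.event_type == "adjust_stack"]["onset"].min()
            rel = (digits["onset"] - adj0).round(6)
            assert rel.isin([2, 3, 4, 5, 6, 7]).all()

    def test_serialization_requires_yoked_run(self, scale):
        rng = np.random.default_rng(3)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        with pytest.raises(ValueError):
            run_to_events(run)
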