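"""Observer models: psychometrics, staircase dynamics, navigation, parity."""

import numpy as np
import pytest
from scipy.stats import norm

from densnav.design import DigitSlot, build_run, make_pair_set
from densnav.observer import (
    DEFAULT_PILOT_SIGMA_LOG,
    NavigationObserver,
    PILOT_REFERENCE_DENSITIES,
    PsychometricObserver,
    StaircaseState,
    observer_respond,
    run_staircase,
    simulate_adjustment,
    simulate_parity,
    simulate_session,
    staircase_update,
)


class TestPsychometrics:
    def test_zero_difference_is_a_coin_flip(self):
        obs = PsychometricObserver(sigma_log=0.5)
        rng = np.random.default_rng(0)
        noisier = sum(
            observer_respond(obs, 1.0, 1.0, rng) == "noisier" for _ in range(4000)
        )
        assert noisier / 4000 == pytest.approx(0.5, abs=0.03)

    def test_large_difference_always_correct(self):
        obs = PsychometricObserver(sigma_log=0.1, lapse_rate=0.0)
        rng = np.random.default_rng(1)
        assert all(
            observer_respond(obs, 1.0, 5.0, rng) == "noisier" for _ in range(200)
        )

    def test_empirical_rate_matches_closed_form(self):
        """At delta = sqrt(2)*sigma*Phi^-1(0.707) the observer is 70.7% correct."""
        sigma = 0.4
        obs = PsychometricObserver(sigma_log=sigma)
        delta = np.sqrt(2) * sigma * norm.ppf(0.707)
        rng = np.random.default_rng(2)
        n = 100_000
        correct = sum(
            observer_respond(obs, 0.0, delta, rng) == "noisier" for _ in range(n)
        )
        assert correct / n == pytest.approx(0.707, abs=0.005)
        assert obs.p_correct(delta) == pytest.approx(0.707, abs=1e-6)


class TestStaircase:
    def test_two_down_one_up_rule(self):
        s = StaircaseState(1.0, 9.1)
        s = staircase_update(s, True)
        assert s.delta_log == 1.0  # one correct: no change yet
        s = staircase_update(s, True)
        assert s.delta_log == pytest.approx(1.0 - 1 / 3)
        s = staircase_update(s, False)
        assert s.delta_log == pytest.approx(1.0)  # error: back up

    def test_step_switches_after_second_reversal(self):
        s = StaircaseState(1.0, 9.1)
        # down, down (reversal 1 up? no: first change is down), up (rev 1),
        # down-down (rev 2) -> fine step from then on
        for correct in (True, True, False, True, True):
            s = staircase_update(s, correct)
        assert len(s.reversals) == 2
        assert s.step == pytest.approx(1 / 6)
        before = s.delta_log
        s = staircase_update(s, False)
        assert s.delta_log == pytest.approx(before + 1 / 6)

    def test_reversals_recorded_at_turning_points(self):
        s = StaircaseState(1.0, 9.1)
        for correct in (True, True, False):
            s = staircase_update(s, correct)
        assert s.reversals == [pytest.approx(1.0 - 1 / 3)]

    def test_ideal_observer_threshold_shrinks_with_sigma(self):
        ths = []
        for sigma in (1.2, 0.3):
            rng = np.random.default_rng(5)
            obs = PsychometricObserver(sigma_log=sigma)
            ths.append(
                np.mean(
                    [run_staircase(obs, 9.1, rng).threshold_delta_log
                     for _ in range(80)]
                )
            )
        assert ths[1] < ths[0]

    def test_nonconvergence_raises(self):
        obs = PsychometricObserver(sigma_log=1.0)
        with pytest.raises(RuntimeError):
            run_staircase(obs, 9.1, rng=0, max_trials=5)

    def test_weber_observer_jnds_increase_with_reference(self):
        """Constant log-noise (Weber) observer: linear-unit JNDs grow across
        the four pilot reference densities."""
        obs = PsychometricObserver(sigma_log=DEFAULT_PILOT_SIGMA_LOG)
        rng = np.random.default_rng(11)
        jnds = []
        for ref in PILOT_REFERENCE_DENSITIES:
            jnds.append(
                np.mean(
                    [run_staircase(obs, ref, rng).jnd_components_per_octave
                     for _ in range(60)]
                )
            )
        assert all(b > a for a, b in zip(jnds, jnds[1:]))


class TestAdjustment:
    @pytest.fixture()
    def ma_trial(self, scale):
        rng = np.random.default_rng(3)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        return next(t for t in run.trials if t.condition.code == "MA")

    def test_noiseless_agent_reaches_target(self, scale, ma_trial):
        agent = NavigationObserver(0.0, 0.0, 0.0)
        presses, series, final = simulate_adjustment(agent, ma_trial, scale, rng=0)
        assert final == ma_trial.target_level
        assert series[0] == ma_trial.start_level
        net = sum(p.n_steps if p.direction == "denser" else -p.n_steps
                  for p in presses)
        assert net == ma_trial.target_level - ma_trial.start_level

    def test_one_step_per_stack_bound(self, scale, ma_trial):
        agent = NavigationObserver(0.5, 0.3, 0.05)
        _, series, _ = simulate_adjustment(agent, ma_trial, scale, rng=4)
        assert len(series) == 40
        assert np.all(np.abs(np.diff(series)) <= 1)
        assert min(series) >= 0 and max(series) <= scale.n_levels - 1

    def test_na_policy_matches_press_count(self, scale):
        rng = np.random.default_rng(9)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        na = next(t for t in run.trials if t.condition.code == "NA")
        agent = NavigationObserver()
        presses, series, _ = simulate_adjustment(agent, na, scale, rng=1,
                                                 n_press_steps=8)
        assert sum(p.n_steps for p in presses) == 8
        assert series[0] == na.start_level

    def test_calibrated_agent_mostly_improves_and_undershoots(self, scale):
        """Noisy navigation mostly ends closer to the target than it began,
        with undershoot in a nonzero fraction of trials."""
        agent = NavigationObserver()
        rng = np.random.default_rng(17)
        closer = under = n = 0
        for seed in range(120):
            run = build_run(make_pair_set(scale, rng), scale, rng)
            t = next(tr for tr in run.trials if tr.condition.code == "MA")
            _, _, final = simulate_adjustment(agent, t, scale, rng)
            d0, d1 = abs(t.start_level - t.target_level), abs(final - t.target_level)
            n += 1
            closer += d1 < d0
            under += (
                np.sign(final - t.target_level) == np.sign(t.start_level - t.target_level)
                and final != t.target_level
            )
        assert closer / n > 0.5
        assert under / n > 0.0

    def test_parity_trial_rejected(self, scale):
        rng = np.random.default_rng(4)
        run = build_run(make_pair_set(scale, rng), scale, rng)
        mp = next(t for t in run.trials if t.condition.code == "MP")
        with pytest.raises(ValueError):
            simulate_adjustment(NavigationObserver(), mp, scale, rng)


class TestParity:
    slots = tuple(
        DigitSlot(float(o), v, "female") for o, v in zip((2, 3, 4), (1, 2, 7))
    )

    def test_perfect_observer(self):
        resp = simulate_parity(0.0, self.slots, rng=0, miss_rate=0.0)
        assert [r.parity for r in resp] == ["odd", "even", "odd"]

    def test_half_lapse_accuracy(self):
        rng = np.random.default_rng(1)
        correct = total = 0
        for _ in range(3000):
            for r in simulate_parity(0.5, self.slots, rng):
                total += 1
                correct += (r.parity == "odd") == (r.digit_value % 2 == 1)
        assert correct / total == pytest.approx(0.75, abs=0.02)

    def test_full_miss_gives_no_responses(self):
        assert simulate_parity(0.0, self.slots, rng=0, miss_rate=1.0) == ()


class TestSession:
    def test_session_is_fully_resolved(self, session):
        for t in session.run.trials:
            assert t.adjust_series is not None
            assert 1 <= len(t.digit_slots) <= 6
        assert len(session.outcomes) == 28

    def test_na_press_counts_track_ma(self, session):
        steps = {c: [] for c in ("MA", "NA")}
        for out in session.outcomes:
            if out.condition in steps:
                steps[out.condition].append(out.press_steps)
        # matched-count policy: NA press budget comes from the MA mean
        assert abs(np.mean(steps["NA"]) - np.mean(steps["MA"])) < 4

    def test_behaviour_rows_present(self, session):
        types = set(session.events.event_type)
        assert {"press", "parity_response", "rating_response"} <= types
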