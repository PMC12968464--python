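"""Simulated observers: density discrimination, adaptive staircases, and
in-scanner navigation/parity behaviour.

Density is treated logarithmically throughout (the dimension is Weber-like:
JNDs grow roughly in proportion to density), so discrimination noise,
memory noise and staircase steps all operate on log2 tone-count units.

The discrimination observer compares two stacks through a signal-detection
channel: each stack's log-density is perceived with independent Gaussian
noise of SD ``sigma_log``, giving

    P(correct) = (1 - lapse) * Phi(|delta| / (sqrt(2) * sigma_log)) + lapse / 2

for a log-density difference ``delta``.  A two-down/one-up staircase on this
observer converges at the difference where P(correct) = sqrt(0.5) ~ 70.7%.

The navigation observer stands in for participants in adjustment trials: it
stores a noisy memory of the target, perceives the current density noisily,
and presses toward the remembered target until the perceived distance falls
below a stop criterion.  The no-target variant presses at random, matched in
press count.  Neither observer is fit to human data; their parameters are
calibration knobs for the synthetic pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .design import (
    DigitSlot,
    MAX_DIGITS,
    N_ADJUST_STACKS,
    Run,
    STACK_PERIOD_S,
    Trial,
    digit_count_rule,
    make_dummy_digits,
    run_to_events,
    slot_onsets,
    yoke_trials,
)
from .stimulus import DensityScale

__all__ = [
    "PsychometricObserver",
    "StaircaseState",
    "StaircaseResult",
    "NavigationObserver",
    "PressEvent",
    "ParityResponse",
    "observer_respond",
    "staircase_update",
    "run_staircase",
    "simulate_adjustment",
    "simulate_parity",
    "simulate_session",
    "SimulatedSession",
]

#: Staircase step sizes in log2-density units.
STEP_COARSE = 1.0 / 3.0
STEP_FINE = 1.0 / 6.0
#: Reversal after which the fine step takes over.
STEP_SWITCH_REVERSAL = 2
#: Floor keeping the tracked difference positive.
MIN_DELTA_LOG = 1e-3

#: Reference densities (components/octave) used in the discrimination pilot.
PILOT_REFERENCE_DENSITIES = (3.5, 9.1, 25.2, 66.5)

#: Default discrimination noise of the simulated pilot observer, in log2
#: units.  Density is a hard dimension: navigation behaviour implies an
#: uncertainty near one octave (a JND of roughly a density doubling), i.e.
#: sigma ~ 1.3.  This also puts the staircase in its validated regime: the
#: fine 1/6 step is small relative to sigma (the two-down/one-up analysis
#: assumes small steps) and the one-octave starting difference lies within
#: a coarse step of the threshold, so six reversals reach stationarity.
DEFAULT_PILOT_SIGMA_LOG = 1.3
#: Default starting difference of a track, one octave.
DEFAULT_INITIAL_DELTA_LOG = 1.0


@dataclass(frozen=True)
class PsychometricObserver:
    """Cumulative-Gaussian discrimination observer in log2-density units."""

    sigma_log: float
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    def p_correct(self, delta_log: float) -> float:
        """Closed-form probability of a correct 2AFC comparison."""
        p = norm.cdf(abs(delta_log) / (np.sqrt(2.0) * self.sigma_log))
        return (1.0 - self.lapse_rate) * p + self.lapse_rate / 2.0


def observer_respond(
    observer: PsychometricObserver,
    ref_level_log: float,
    cmp_level_log: float,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Judge whether the comparison stack is 'noisier' or 'beepier'.

    Each stack is perceived with independent Gaussian noise; on a lapse the
    response is a coin flip.
    """
    rng = np.random.default_rng(rng)
    if rng.random() < observer.lapse_rate:
        return "noisier" if rng.random() < 0.5 else "beepier"
    x_ref = ref_level_log + rng.normal(0.0, observer.sigma_log)
    x_cmp = cmp_level_log + rng.normal(0.0, observer.sigma_log)
    return "noisier" if x_cmp > x_ref else "beepier"


@dataclass
class StaircaseState:
    """Bookkeeping for one two-down/one-up track."""

    delta_log: float
    reference_density: float
    n_correct_in_row: int = 0
    reversals: list[float] = field(default_factory=list)
    last_change: int | None = None  # sign of the previous delta change
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.delta_log <= 0:
            raise ValueError("delta_log must be positive")

    @property
    def step(self) -> float:
        return STEP_COARSE if len(self.reversals) < STEP_SWITCH_REVERSAL else STEP_FINE


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial's outcome under the two-down/one-up rule.

    Two consecutive correct responses shrink the difference by the current
    step; any error grows it.  A change of direction relative to the
    previous change is a reversal, recorded at the pre-update difference;
    from the second reversal on, the step halves from 1/3 to 1/6.
    """
    state = replace(state, reversals=list(state.reversals))
    state.n_trials += 1
    if correct:
        state.n_correct_in_row += 1
        if state.n_correct_in_row < 2:
            return state
        state.n_correct_in_row = 0
        change = -1
    else:
        state.n_correct_in_row = 0
        change = +1
    if state.last_change is not None and change != state.last_change:
        state.reversals.append(state.delta_log)
    state.delta_log = max(state.delta_log + change * state.step, MIN_DELTA_LOG)
    state.last_change = change
    return state


@dataclass(frozen=True)
class StaircaseResult:
    """Threshold estimate from one track."""

    threshold_delta_log: float
    jnd_components_per_octave: float
    reference_density: float
    n_trials: int
    reversals: tuple[float, ...]


def run_staircase(
    observer: PsychometricObserver,
    reference_density: float,
    rng: np.random.Generator | int | None = None,
    initial_delta_log: float = 1.0,
    n_reversals: int = 6,
    n_average: int = 2,
    max_trials: int = 200,
) -> StaircaseResult:
    """Run one adaptive track to six reversals and estimate the JND.

    The threshold is the mean log2-density difference over the final two
    reversals, converted to a components/octave difference at the reference:
    ``jnd = reference * (2**threshold - 1)``.
    """
    rng = np.random.default_rng(rng)
    state = StaircaseState(initial_delta_log, reference_density)
    ref_log = float(np.log2(reference_density))
    while len(state.reversals) < n_reversals:
        if state.n_trials >= max_trials:
            raise RuntimeError(
                f"staircase failed to reach {n_reversals} reversals "
                f"within {max_trials} trials"
            )
        sign = 1 if rng.random() < 0.5 else -1
        cmp_log = ref_log + sign * state.delta_log
        response = observer_respond(observer, ref_log, cmp_log, rng)
        correct = (response == "noisier") == (sign > 0)
        state = staircase_update(state, correct)
    threshold = float(np.mean(state.reversals[n_reversals - n_average : n_reversals]))
    return StaircaseResult(
        threshold_delta_log=threshold,
        jnd_components_per_octave=reference_density * (2.0**threshold - 1.0),
        reference_density=reference_density,
        n_trials=state.n_trials,
        reversals=tuple(state.reversals),
    )


# ---------------------------------------------------------------------------
# Navigation (adjustment) behaviour


@dataclass(frozen=True)
class NavigationObserver:
    """Agent steering the stack density toward a remembered target.

    All noise terms are in log2-density units.  ``stop_criterion`` is the
    perceived absolute distance below which the agent stops pressing.  The
    defaults are calibrated so simulated cohorts land in the reported range
    of human navigation behaviour: ~0.9 octaves of memory noise and a
    conservative ~0.9-octave stop band reproduce finishing closer to the
    target on the large majority of trials, a mean final distance around
    15% of the density scale, and a tendency (about 70% of trials) to stop
    on the starting side of the target (undershoot).
    """

    memory_sigma: float = 0.9
    perceive_sigma: float = 0.05
    stop_criterion: float = 0.9
    press_latency_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.memory_sigma, self.perceive_sigma, self.stop_criterion,
               self.press_latency_s) < 0:
            raise ValueError("observer parameters must be nonnegative")


@dataclass(frozen=True)
class PressEvent:
    """A button hold: onset within the 8-s phase, duration, direction.

    ``n_steps`` is the number of 200-ms stacks the hold spans; each stack
    moves the density one scale level in the held direction.
    """

    onset_s: float
    duration_s: float
    direction: str  # "denser" | "sparser"
    n_steps: int


def _merge_steps(steps: list[int], press_latency_s: float) -> tuple[PressEvent, ...]:
    """Collapse per-stack signed steps (+1/-1/0) into hold events."""
    events = []
    t = 0
    n = len(steps)
    while t < n:
        d = steps[t]
        if d == 0:
            t += 1
            continue
        t0 = t
        while t < n and steps[t] == d:
            t += 1
        events.append(
            PressEvent(
                onset_s=t0 * STACK_PERIOD_S + press_latency_s,
                duration_s=(t - t0) * STACK_PERIOD_S,
                direction="denser" if d > 0 else "sparser",
                n_steps=t - t0,
            )
        )
    return tuple(events)


def simulate_adjustment(
    observer: NavigationObserver,
    trial: Trial,
    scale: DensityScale,
    rng: np.random.Generator | int | None = None,
    n_press_steps: int | None = None,
) -> tuple[tuple[PressEvent, ...], tuple[int, ...], int]:
    """Simulate the 8-s adjustment phase of an MA or NA trial.

    Returns (press events, resolved 40-stack level series, final level).
    The series starts at the trial's start level; a press during stack ``t``
    moves the level one scale step for stack ``t + 1``, clipped at the scale
    boundaries.  MA trials steer toward a noisy memory of the target until
    the perceived distance drops below the stop criterion; NA trials execute
    a random press policy spending ``n_press_steps`` press-steps (matched to
    MA behaviour by the session simulator).
    """
    if not trial.condition.has_adjust:
        raise ValueError("adjustment simulation requires an MA or NA trial")
    rng = np.random.default_rng(rng)
    top = scale.n_levels - 1
    if trial.condition.has_memory:
        target_mem = scale.log2_density(trial.target_level) + rng.normal(
            0.0, observer.memory_sigma
        )
        level = trial.start_level
        levels = [level]
        steps: list[int] = []
        for _ in range(N_ADJUST_STACKS - 1):
            perceived = scale.log2_density(level) + rng.normal(
                0.0, observer.perceive_sigma
            )
            d = target_mem - perceived
            step = int(np.sign(d)) if abs(d) > observer.stop_criterion else 0
            steps.append(step)
            level = int(np.clip(level + step, 0, top))
            levels.append(level)
    else:
        if n_press_steps is None:
            n_press_steps = int(rng.integers(4, 13))
        steps = [0] * (N_ADJUST_STACKS - 1)
        t = 0
        remaining = n_press_steps
        while remaining > 0 and t < N_ADJUST_STACKS - 1:
            t += int(rng.integers(0, 4))  # idle gap
            if t >= N_ADJUST_STACKS - 1:
                break
            d = 1 if rng.random() < 0.5 else -1
            run_len = int(min(remaining, rng.integers(1, 6),
                              N_ADJUST_STACKS - 1 - t))
            for _ in range(run_len):
                steps[t] = d
                t += 1
            remaining -= run_len
        level = trial.start_level
        levels = [level]
        for step in steps:
            level = int(np.clip(level + step, 0, top))
            levels.append(level)
    presses = _merge_steps(steps, observer.press_latency_s)
    return presses, tuple(levels), levels[-1]


@dataclass(frozen=True)
class ParityResponse:
    """One odd/even judgement: which digit, when, and what was said."""

    digit_onset_s: float
    rt_s: float
    parity: str  # "odd" | "even"
    digit_value: int


def simulate_parity(
    lapse_rate: float,
    digit_slots: tuple[DigitSlot, ...],
    rng: np.random.Generator | int | None = None,
    miss_rate: float = 0.0,
    rt_range_s: tuple[float, float] = (0.3, 0.9),
) -> tuple[ParityResponse, ...]:
    """Simulate odd/even responses to the spoken digits of one trial.

    Each digit is answered with probability ``1 - miss_rate``; on a lapse
    (probability ``lapse_rate``) the response is a uniform guess, otherwise
    it is correct.
    """
    if not 0.0 <= lapse_rate <= 1.0 or not 0.0 <= miss_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    responses = []
    for slot in digit_slots:
        if rng.random() < miss_rate:
            continue
        true_parity = "odd" if slot.value % 2 else "even"
        if rng.random() < lapse_rate:
            parity = "odd" if rng.random() < 0.5 else "even"
        else:
            parity = true_parity
        responses.append(
            ParityResponse(
                digit_onset_s=slot.onset_s,
                rt_s=float(rng.uniform(*rt_range_s)),
                parity=parity,
                digit_value=slot.value,
            )
        )
    return tuple(responses)


# ---------------------------------------------------------------------------
# Full-session simulation


def _distance_rating_bin(distance_steps: int) -> int:
    """Map final-to-target distance to the 1-4 similarity scale (1 = very similar)."""
    if distance_steps <= 1:
        return 1
    if distance_steps <= 4:
        return 2
    if distance_steps <= 8:
        return 3
    return 4


def _density_rating_bin(level: int, n_levels: int) -> int:
    """Map a final level to the 1-4 beepy/noisy scale (4 = very noisy)."""
    return int(level * 4 // n_levels) + 1 if level < n_levels else 4


@dataclass
class TrialOutcome:
    """Behavioural record of one simulated trial."""

    trial_index: int
    condition: str
    final_level: int | None
    press_steps: int
    presses: tuple[PressEvent, ...]
    parity_responses: tuple[ParityResponse, ...]
    n_digits: int
    rating: int | None
    rating_truth: int


@dataclass
class SimulatedSession:
    """A yoked run plus everything the observer did in it."""

    run: Run
    outcomes: list[TrialOutcome]
    events: "pd.DataFrame"  # noqa: F821 - annotation only


def simulate_session(
    run: Run,
    scale: DensityScale,
    nav_observer: NavigationObserver | None = None,
    parity_lapse: float = 0.05,
    parity_miss: float = 0.08,
    rating_sigma: float = 0.7,
    rating_miss: float = 0.03,
    rng: np.random.Generator | int | None = None,
) -> SimulatedSession:
    """Play one run trial by trial, resolving behaviour and yoking.

    Adjustment series are produced by the navigation observer (NA press
    counts matched to the running mean of MA press-step counts), parity
    digit counts follow the count rule using actual unanswered digits, and
    both yoking directions (series A->P, digits P->A) are applied with
    seeded dummy trials bootstrapping each stream.
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    if nav_observer is None:
        nav_observer = NavigationObserver()
    trials = [replace(t) for t in run.trials]
    series_out: dict[int, tuple[int, ...]] = {}
    last_digits: dict[str, tuple[int, ...] | None] = {"MP": None, "NP": None}
    digit_sets: dict[int, tuple[DigitSlot, ...]] = {}
    unanswered: list[int] = []
    last_adjust_count: int | None = None
    ma_step_counts: list[int] = []
    outcomes: list[TrialOutcome] = []
    behaviour_rows: list[dict] = []

    for i, tr in enumerate(trials):
        code = tr.condition.code
        if tr.condition.has_adjust:
            stream = "MP" if tr.condition.has_memory else "NP"
            digits = last_digits[stream]
            if digits is None:
                digits = make_dummy_digits(rng)
            digit_sets[i] = digits
            n_steps = None
            if not tr.condition.has_memory:
                n_steps = (
                    int(round(np.mean(ma_step_counts)))
                    if ma_step_counts
                    else int(rng.integers(4, 13))
                )
            presses, series, final = simulate_adjustment(
                nav_observer, tr, scale, rng, n_press_steps=n_steps
            )
            series_out[i] = series
            total_steps = sum(p.n_steps for p in presses)
            if tr.condition.has_memory:
                ma_step_counts.append(total_steps)
            last_adjust_count = len(digits)
            if tr.condition.has_memory:
                truth = _distance_rating_bin(abs(final - tr.target_level))
            else:
                truth = _density_rating_bin(final, scale.n_levels)
            outcomes.append(
                TrialOutcome(i, code, final, total_steps, presses, (), len(digits),
                             None, truth)
            )
        else:
            prev_count = (
                last_adjust_count
                if last_adjust_count is not None
                else int(rng.integers(1, MAX_DIGITS + 1))
            )
            mean_un = float(np.mean(unanswered)) if unanswered else None
            count = digit_count_rule(prev_count, mean_un, rng)
            digits = tuple(
                DigitSlot(
                    float(o),
                    int(rng.integers(1, 11)),
                    ("female", "male")[int(rng.integers(2))],
                )
                for o in slot_onsets(count, rng)
            )
            digit_sets[i] = digits
            trials[i] = replace(tr, digit_slots=digits)
            responses = simulate_parity(parity_lapse, digits, rng, parity_miss)
            unanswered.append(len(digits) - len(responses))
            outcomes.append(
                TrialOutcome(i, code, None, 0, (), responses, len(digits), None, 0)
            )
        last_digits_update = not tr.condition.has_adjust
        if last_digits_update:
            last_digits[code] = digit_sets[i]

    base_run = Run([
        replace(t, digit_slots=digit_sets[t.index]) if not t.condition.has_adjust
        else t
        for t in trials
    ])
    yoked = yoke_trials(base_run, series_out, scale, rng)
    # yoke_trials regenerates A-trial digits from P streams / dummies; align
    # the session's record to the yoked run (authoritative).
    for i, tr in enumerate(yoked.trials):
        if tr.condition.has_adjust:
            outcomes[i].n_digits = len(tr.digit_slots)

    # Ratings: noisy report of the truth bin; P-trial truths need the yoked
    # series (final stack level).
    for i, tr in enumerate(yoked.trials):
        out = outcomes[i]
        if not tr.condition.has_adjust:
            final = tr.adjust_series[-1]
            out.final_level = final
            if tr.condition.has_memory:
                out.rating_truth = _distance_rating_bin(abs(final - tr.target_level))
            else:
                out.rating_truth = _density_rating_bin(final, scale.n_levels)
        if rng.random() >= rating_miss:
            noisy = out.rating_truth + int(round(rng.normal(0.0, rating_sigma)))
            out.rating = int(np.clip(noisy, 1, 4))

    events = run_to_events(yoked)
    # Append behaviour rows (presses, parity responses, ratings).
    trial_starts = {}
    t0 = 0.0
    for tr in yoked.trials:
        trial_starts[tr.index] = t0
        t0 += tr.duration_s
    for i, tr in enumerate(yoked.trials):
        out = outcomes[i]
        adjust_onset = trial_starts[i] + tr.phase_onsets()["adjust_phase"]
        base = dict(condition=tr.condition.code, trial_index=i,
                    set_index=tr.set_index)
        for p in out.presses:
            behaviour_rows.append(
                dict(base, onset=adjust_onset + p.onset_s, duration=p.duration_s,
                     event_type="press", value=p.direction)
            )
        for r in out.parity_responses:
            behaviour_rows.append(
                dict(base, onset=adjust_onset + r.digit_onset_s + r.rt_s,
                     duration=0.0, event_type="parity_response", value=r.parity,
                     digit_value=r.digit_value)
            )
        if out.rating is not None:
            rating_onset = trial_starts[i] + tr.phase_onsets()["rating"]
            behaviour_rows.append(
                dict(base, onset=rating_onset + 0.8, duration=0.0,
                     event_type="rating_response", value=out.rating)
            )
    if behaviour_rows:
        events = (
            pd.concat([events, pd.DataFrame(behaviour_rows)], ignore_index=True)
            .sort_values("onset", kind="stable")
            .reset_index(drop=True)
        )
    return SimulatedSession(run=yoked, outcomes=outcomes, events=events)
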