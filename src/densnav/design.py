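"""Four-condition trial scheduling with yoked acoustics.

The design crosses two factors: memory (hold a target density in mind: M)
versus no memory (N), and adjustment (steer the density of an ongoing stack
series with button presses: A) versus parity judgement on spoken digits (P).
Each run has 28 trials, grouped into seven sets of four with one trial of
each condition; within a set the MA trial precedes NA and MP precedes NP,
and no two consecutive trials share a condition.

A trial unfolds as: 2 s instructions (silence), a 2-s series of ten stacks
(constant at the target density for M trials; alternating between the scale
extremes as an ignored dummy for N trials), 1-3 s silence (the maintenance
interval for M trials), an 8-s phase with 40 stacks plus one to six spoken
digits, a 3-s rating window, and a 0-2 s inter-trial interval.

Acoustic and motor demands are matched across conditions by yoking: each P
trial's 40-stack density series copies the most recent A trial of the same
memory stream, and the (ignored) digits of each A trial copy the most recent
P trial of that stream, falling back to a seeded dummy trial at the start of
a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import DensityScale

__all__ = [
    "CONDITIONS",
    "Condition",
    "DigitSlot",
    "Trial",
    "PairSet",
    "Run",
    "make_pair_set",
    "digit_count_rule",
    "slot_onsets",
    "make_dummy_digits",
    "build_run",
    "yoke_trials",
    "run_to_events",
    "events_to_run",
    "write_events",
    "read_events",
]

CONDITIONS = ("MA", "MP", "NA", "NP")

#: Phase durations (seconds).
INSTRUCTION_S = 2.0
INITIAL_SERIES_S = 2.0
ADJUST_PHASE_S = 8.0
RATING_WINDOW_S = 3.0
STACK_PERIOD_S = 0.2
N_INITIAL_STACKS = 10
N_ADJUST_STACKS = 40

#: Digit slots start at one-second intervals from second two of the 8-s
#: phase, leaving its first and final second digit-free.
DIGIT_SLOTS = (2, 3, 4, 5, 6, 7)
MAX_DIGITS = len(DIGIT_SLOTS)

#: Minimum trajectory length (in scale steps) between start and target.
MIN_TRAJECTORY_STEPS = 5


@dataclass(frozen=True)
class Condition:
    code: str

    def __post_init__(self) -> None:
        if self.code not in CONDITIONS:
            raise ValueError(f"unknown condition code {self.code!r}")

    @property
    def has_memory(self) -> bool:
        return self.code[0] == "M"

    @property
    def has_adjust(self) -> bool:
        return self.code[1] == "A"


@dataclass(frozen=True)
class DigitSlot:
    """One spoken digit: onset within the 8-s phase, value 1-10, voice."""

    onset_s: float
    value: int
    voice: str

    def __post_init__(self) -> None:
        if not 1 <= self.value <= 10:
            raise ValueError("digit value must be in 1..10")
        if self.voice not in ("female", "male"):
            raise ValueError("voice must be 'female' or 'male'")


@dataclass
class Trial:
    condition: Condition
    index: int
    set_index: int
    start_level: int
    target_level: int | None
    initial_series: tuple[int, ...]
    silence_s: float
    iti_s: float
    adjust_series: tuple[int, ...] | None = None
    digit_slots: tuple[DigitSlot, ...] = ()
    rating_window_s: float = RATING_WINDOW_S
    yoke_source: int | None = None        # trial index the series was copied from
    digit_yoke_source: int | None = None  # trial index the digits were copied from

    def __post_init__(self) -> None:
        if self.condition.has_memory:
            if self.target_level is None:
                raise ValueError("memory trials need a target level")
            if any(l != self.target_level for l in self.initial_series):
                raise ValueError("memory-trial initial series must sit at target")
        else:
            if self.target_level is not None:
                raise ValueError("no-memory trials carry no target")
        if len(self.initial_series) != N_INITIAL_STACKS:
            raise ValueError(f"initial series must have {N_INITIAL_STACKS} stacks")
        if self.adjust_series is not None and len(self.adjust_series) != N_ADJUST_STACKS:
            raise ValueError(f"adjust series must have {N_ADJUST_STACKS} stacks")
        if not 1.0 <= self.silence_s <= 3.0:
            raise ValueError("maintenance silence must lie in [1, 3] s")
        if not 0.0 <= self.iti_s <= 2.0:
            raise ValueError("inter-trial interval must lie in [0, 2] s")
        if self.digit_slots:
            if not 1 <= len(self.digit_slots) <= MAX_DIGITS:
                raise ValueError("digit count must lie in 1..6")
            if any(s.onset_s not in DIGIT_SLOTS for s in self.digit_slots):
                raise ValueError("digit onsets must be integer seconds in 2..7")

    @property
    def duration_s(self) -> float:
        return (
            INSTRUCTION_S
            + INITIAL_SERIES_S
            + self.silence_s
            + ADJUST_PHASE_S
            + self.rating_window_s
            + self.iti_s
        )

    def phase_onsets(self) -> dict[str, float]:
        """Onsets of the trial's phases relative to trial start."""
        t = 0.0
        onsets = {"instruction": t}
        t += INSTRUCTION_S
        onsets["initial_series"] = t
        t += INITIAL_SERIES_S
        onsets["maintenance"] = t
        t += self.silence_s
        onsets["adjust_phase"] = t
        t += ADJUST_PHASE_S
        onsets["rating"] = t
        t += self.rating_window_s
        onsets["iti"] = t
        return onsets


@dataclass(frozen=True)
class PairSet:
    """The predetermined (start, target) level pairs for one run."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if any(s == t for s, t in self.pairs):
            raise ValueError("start and target levels must differ")


@dataclass
class Run:
    trials: list[Trial]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n_sets = len(self.trials) // 4
        if len(self.trials) != 4 * n_sets:
            raise ValueError("run length must be a multiple of four")
        counts = {c: 0 for c in CONDITIONS}
        for tr in self.trials:
            counts[tr.condition.code] += 1
        if len(set(counts.values())) != 1:
            raise ValueError("conditions must appear equally often")
        for s in range(n_sets):
            block = self.trials[4 * s : 4 * s + 4]
            order = {tr.condition.code: i for i, tr in enumerate(block)}
            if len(order) != 4:
                raise ValueError("each set must contain all four conditions")
            if order["MA"] > order["NA"] or order["MP"] > order["NP"]:
                raise ValueError("within a set MA precedes NA and MP precedes NP")
        for a, b in zip(self.trials, self.trials[1:]):
            if a.condition.code == b.condition.code:
                raise ValueError("two consecutive trials share a condition")

    @property
    def sets(self) -> list[list[Trial]]:
        return [self.trials[i : i + 4] for i in range(0, len(self.trials), 4)]

    @property
    def duration_s(self) -> float:
        return sum(tr.duration_s for tr in self.trials)


def make_pair_set(
    scale: DensityScale,
    rng: np.random.Generator | int | None = None,
    n_pairs: int = 28,
) -> PairSet:
    """Sample (start, target) level pairs spanning the density space.

    Targets are stratified into the four quartiles of the level range
    (``n_pairs/4`` per quartile) so high- and low-density sounds are sampled
    equally; trajectories split half upward, half downward, each at least
    five scale steps long.  Lowest-quartile targets are approached from
    above and highest-quartile targets from below (shorter approaches do not
    exist there); the two middle quartiles share the remaining up/down
    assignments at random.
    """
    if scale.n_levels < 4:
        raise ValueError("pair construction needs at least four levels")
    if n_pairs % 4:
        raise ValueError("n_pairs must be divisible by four")
    rng = np.random.default_rng(rng)
    per_q = n_pairs // 4
    # Quartiles nested in halves, so exactly half the targets fall in the
    # lower half of the scale.
    half = scale.n_levels // 2
    quartiles = np.array_split(np.arange(half), 2) + np.array_split(
        np.arange(half, scale.n_levels), 2
    )
    pairs: list[tuple[int, int]] = []
    # Upward counts per quartile: Q1 none, Q4 all, Q2/Q3 complementary random.
    k = int(rng.integers(0, per_q + 1))
    n_up = {0: 0, 1: k, 2: per_q - k, 3: per_q}
    for q, levels in enumerate(quartiles):
        targets = rng.choice(levels, size=per_q, replace=per_q > len(levels))
        ups = [True] * n_up[q] + [False] * (per_q - n_up[q])
        rng.shuffle(ups)
        for target, up in zip(targets, ups):
            target = int(target)
            if up:
                lo, hi = 0, target - MIN_TRAJECTORY_STEPS
            else:
                lo, hi = target + MIN_TRAJECTORY_STEPS, scale.n_levels - 1
            if lo > hi:
                raise ValueError(
                    "no admissible start level; scale too short for trajectory rule"
                )
            start = int(rng.integers(lo, hi + 1))
            pairs.append((start, target))
    order = rng.permutation(len(pairs))
    return PairSet(tuple(pairs[i] for i in order))


def digit_count_rule(
    prev_adjust_digit_count: int,
    mean_unanswered: float | None,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Digits to present in a parity trial.

    Previous A-trial digit count plus the mean number of unanswered digits
    over all previous parity trials of the block (0.5 when none exist yet),
    rounded up or down at random when fractional, clamped to the 1-6 slots.
    """
    if prev_adjust_digit_count < 0:
        raise ValueError("digit count cannot be negative")
    rng = np.random.default_rng(rng)
    x = prev_adjust_digit_count + (0.5 if mean_unanswered is None else mean_unanswered)
    lo = int(np.floor(x))
    if x > lo:
        x = lo + int(rng.random() < 0.5)
    return int(np.clip(x, 1, MAX_DIGITS))


def slot_onsets(
    n_digits: int, rng: np.random.Generator | int | None = None
) -> tuple[int, ...]:
    """Draw ``n_digits`` distinct onset seconds from the admissible slots."""
    if not 1 <= n_digits <= MAX_DIGITS:
        raise ValueError(f"n_digits must lie in 1..{MAX_DIGITS}")
    rng = np.random.default_rng(rng)
    chosen = rng.choice(DIGIT_SLOTS, size=n_digits, replace=False)
    return tuple(int(s) for s in np.sort(chosen))


def make_dummy_digits(
    rng: np.random.Generator, n_digits: int | None = None
) -> tuple[DigitSlot, ...]:
    """Digits of a randomly generated dummy trial (block bootstrap)."""
    if n_digits is None:
        n_digits = int(rng.integers(1, MAX_DIGITS + 1))
    onsets = slot_onsets(n_digits, rng)
    return tuple(
        DigitSlot(
            onset_s=float(o),
            value=int(rng.integers(1, 11)),
            voice=("female", "male")[int(rng.integers(2))],
        )
        for o in onsets
    )


def _order_one_set(rng: np.random.Generator, prev_code: str | None) -> list[str]:
    """Order of one set of four conditions satisfying the constraints."""
    for _ in range(200):
        order = list(CONDITIONS)
        rng.shuffle(order)
        if order.index("MA") > order.index("NA"):
            continue
        if order.index("MP") > order.index("NP"):
            continue
        if prev_code is not None and order[0] == prev_code:
            continue
        return order
    raise RuntimeError("failed to order a condition set")  # pragma: no cover


def _alternating_series(scale: DensityScale, rng: np.random.Generator) -> tuple[int, ...]:
    """Ignored dummy sound: stacks alternating between the scale extremes."""
    poles = (0, scale.n_levels - 1)
    first = int(rng.integers(2))
    return tuple(poles[(first + i) % 2] for i in range(N_INITIAL_STACKS))


def build_run(
    pair_set: PairSet,
    scale: DensityScale,
    rng: np.random.Generator | int | None = None,
    n_sets: int = 7,
) -> Run:
    """Assemble one run: condition order, pair assignment, timing, digits.

    The shuffled pairs are dealt one per trial in presentation order; memory
    trials use both members, no-memory trials only the start level.  Digit
    slots are assigned with the count rule bootstrapped at 0.5 unanswered
    digits (behavioural simulation can re-resolve counts trial by trial, see
    :func:`densnav.observer.simulate_session`).  Adjustment series remain
    unresolved until :func:`yoke_trials`.
    """
    if len(pair_set.pairs) != 4 * n_sets:
        raise ValueError("pair set size must equal the trial count")
    rng = np.random.default_rng(rng)
    pair_order = list(rng.permutation(len(pair_set.pairs)))
    trials: list[Trial] = []
    prev_code: str | None = None
    for s in range(n_sets):
        for code in _order_one_set(rng, prev_code):
            cond = Condition(code)
            start, target = pair_set.pairs[pair_order[len(trials)]]
            if cond.has_memory:
                initial = (target,) * N_INITIAL_STACKS
            else:
                target = None
                initial = _alternating_series(scale, rng)
            digits: tuple[DigitSlot, ...]
            if cond.has_adjust:
                # Placeholder; yoking replaces these with the most recent
                # parity trial's digits (or a dummy at block start).
                digits = ()
            else:
                # Behaviour-free bootstrap: previous adjustment-trial digit
                # counts exist only once a session is simulated, so a dummy
                # count stands in here.
                count = digit_count_rule(
                    int(rng.integers(1, MAX_DIGITS + 1)), None, rng
                )
                onsets = slot_onsets(count, rng)
                digits = tuple(
                    DigitSlot(
                        float(o),
                        int(rng.integers(1, 11)),
                        ("female", "male")[int(rng.integers(2))],
                    )
                    for o in onsets
                )
            trials.append(
                Trial(
                    condition=cond,
                    index=len(trials),
                    set_index=s,
                    start_level=int(start),
                    target_level=target,
                    initial_series=initial,
                    silence_s=float(rng.uniform(1.0, 3.0)),
                    iti_s=float(rng.uniform(0.0, 2.0)),
                    digit_slots=digits,
                )
            )
            prev_code = code
    run = Run(trials)
    return run


def _dummy_series(start_level: int, scale: DensityScale, rng: np.random.Generator) -> tuple[int, ...]:
    """Random-walk adjustment series for a dummy trial (block bootstrap)."""
    level = start_level
    out = [level]
    for _ in range(N_ADJUST_STACKS - 1):
        step = int(rng.integers(-1, 2))
        level = int(np.clip(level + step, 0, scale.n_levels - 1))
        out.append(level)
    return tuple(out)


def yoke_trials(
    run: Run,
    simulated_adjust_outputs: dict[int, tuple[int, ...]],
    scale: DensityScale,
    rng: np.random.Generator | int | None = None,
) -> Run:
    """Resolve the acoustic and digit yoking of a run.

    ``simulated_adjust_outputs`` maps the index of each adjustment (MA/NA)
    trial to its resolved 40-stack density series.  Each MP trial copies the
    most recent MA series and each NP the most recent NA series; each MA/NA
    trial's digits copy the most recent MP/NP trial respectively.  Where no
    predecessor exists at the start of the block, a seeded dummy trial
    provides the series or digits.
    """
    rng = np.random.default_rng(rng)
    last_series: dict[str, tuple[int, tuple[int, ...]]] = {}
    last_digits: dict[str, tuple[int, tuple[DigitSlot, ...]]] = {}
    new_trials: list[Trial] = []
    for tr in run.trials:
        code = tr.condition.code
        if tr.condition.has_adjust:
            if tr.index not in simulated_adjust_outputs:
                raise ValueError(f"trial {tr.index} has no resolved adjust series")
            series = tuple(simulated_adjust_outputs[tr.index])
            digit_stream = "MP" if tr.condition.has_memory else "NP"
            if digit_stream in last_digits:
                src, digits = last_digits[digit_stream]
            else:
                src, digits = None, make_dummy_digits(rng)
            tr = replace(
                tr, adjust_series=series, digit_slots=digits, digit_yoke_source=src
            )
            last_series[code] = (tr.index, series)
        else:
            series_stream = "MA" if tr.condition.has_memory else "NA"
            if series_stream in last_series:
                src, series = last_series[series_stream]
            else:
                src, series = None, _dummy_series(tr.start_level, scale, rng)
            # The copied series supersedes the dealt start level.
            tr = replace(
                tr, adjust_series=series, start_level=series[0], yoke_source=src
            )
            last_digits[code] = (tr.index, tr.digit_slots)
        new_trials.append(tr)
    return Run(new_trials)


# ---------------------------------------------------------------------------
# Event-table serialization (BIDS-events-like TSV)

EVENT_COLUMNS = [
    "onset",
    "duration",
    "event_type",
    "condition",
    "trial_index",
    "set_index",
    "density_level",
    "target_level",
    "digit_value",
    "voice",
    "value",
]


def run_to_events(run: Run) -> pd.DataFrame:
    """Flatten a (yoked) run into one event row per stimulus element."""
    rows: list[dict] = []
    t0 = 0.0
    for tr in run.trials:
        ph = tr.phase_onsets()
        base = dict(
            condition=tr.condition.code,
            trial_index=tr.index,
            set_index=tr.set_index,
            target_level=tr.target_level,
        )
        rows.append(
            dict(base, onset=t0, duration=INSTRUCTION_S, event_type="instruction")
        )
        for i, lvl in enumerate(tr.initial_series):
            rows.append(
                dict(
                    base,
                    onset=t0 + ph["initial_series"] + i * STACK_PERIOD_S,
                    duration=STACK_PERIOD_S,
                    event_type="initial_stack",
                    density_level=lvl,
                )
            )
        rows.append(
            dict(
                base,
                onset=t0 + ph["maintenance"],
                duration=tr.silence_s,
                event_type="maintenance",
            )
        )
        if tr.adjust_series is None:
            raise ValueError("run must be yoked before serialization")
        for i, lvl in enumerate(tr.adjust_series):
            rows.append(
                dict(
                    base,
                    onset=t0 + ph["adjust_phase"] + i * STACK_PERIOD_S,
                    duration=STACK_PERIOD_S,
                    event_type="adjust_stack",
                    density_level=lvl,
                )
            )
        for slot in tr.digit_slots:
            rows.append(
                dict(
                    base,
                    onset=t0 + ph["adjust_phase"] + slot.onset_s,
                    duration=0.4,
                    event_type="digit",
                    digit_value=slot.value,
                    voice=slot.voice,
                )
            )
        rows.append(
            dict(
                base,
                onset=t0 + ph["rating"],
                duration=tr.rating_window_s,
                event_type="rating_window",
            )
        )
        rows.append(
            dict(base, onset=t0 + ph["iti"], duration=tr.iti_s, event_type="iti")
        )
        t0 += tr.duration_s
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[EVENT_COLUMNS]


def events_to_run(events: pd.DataFrame) -> Run:
    """Rebuild the trial schedule from an event table (inverse of run_to_events)."""
    trials = []
    for idx, g in events.groupby("trial_index", sort=True):
        cond = Condition(g["condition"].iloc[0])
        init = g[g.event_type == "initial_stack"].sort_values("onset")
        adj = g[g.event_type == "adjust_stack"].sort_values("onset")
        digits = g[g.event_type == "digit"].sort_values("onset")
        maint = g[g.event_type == "maintenance"].iloc[0]
        iti = g[g.event_type == "iti"].iloc[0]
        rating = g[g.event_type == "rating_window"].iloc[0]
        adjust_onset = adj["onset"].iloc[0]
        target = g["target_level"].iloc[0]
        trials.append(
            Trial(
                condition=cond,
                index=int(idx),
                set_index=int(g["set_index"].iloc[0]),
                start_level=int(adj["density_level"].iloc[0]),
                target_level=None if pd.isna(target) else int(target),
                initial_series=tuple(int(v) for v in init["density_level"]),
                silence_s=float(maint["duration"]),
                iti_s=float(iti["duration"]),
                adjust_series=tuple(int(v) for v in adj["density_level"]),
                digit_slots=tuple(
                    DigitSlot(
                        onset_s=float(round(r.onset - adjust_onset)),
                        value=int(r.digit_value),
                        voice=r.voice,
                    )
                    for r in digits.itertuples()
                ),
                rating_window_s=float(rating["duration"]),
            )
        )
    return Run(trials)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False: the condition code "NA" is data, not missing.
    return pd.read_csv(
        path, sep="\t", na_values=["n/a"], keep_default_na=False
    )
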