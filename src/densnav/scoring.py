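"""Behavioural scoring: navigation success, parity accuracy, rating accuracy,
variance-stabilising transforms, and participant exclusion flags.

Navigation success is the absolute number of steps in density space between
the final adjusted stack and the target; a trial also records whether the
observer finished closer to the target than it started and whether it
undershot (stopped on the starting side of the target).

Parity judgements are scored as matches divided by the larger of the digit
count and the response count.  When the response series contains an extra or
a missing response, it is allowed to be dislocated by one position: the
score takes the best alignment over all single insertions or deletions of a
response.  Equal-count series are scored positionally, so a guessing
responder who answers every digit sits at 50% in the long run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "TrialScore",
    "navigation_score",
    "parity_score",
    "rating_accuracy",
    "transform_stats",
    "arcsine_sqrt",
    "fisher_z",
    "exclusion_flags",
    "score_session",
    "subject_summary",
]


@dataclass(frozen=True)
class TrialScore:
    """Scores for one trial (fields apply per condition; unused ones None)."""

    final_distance_steps: int | None = None
    closer_than_start: bool | None = None
    undershoot: bool | None = None
    parity_accuracy: float | None = None
    rating: int | None = None


def navigation_score(
    start_level: int, final_level: int, target_level: int
) -> tuple[int, bool, bool | None]:
    """Score one adjustment trial against its target.

    Returns ``(final_distance_steps, closer_than_start, undershoot)`` where
    distance is in scale steps, ``closer_than_start`` compares final and
    starting distances, and ``undershoot`` is True when the final level lies
    strictly between start and target on the starting side (None when the
    trial started on the target, where the notion is undefined).
    """
    distance = abs(final_level - target_level)
    closer = distance < abs(start_level - target_level)
    if start_level == target_level:
        undershoot = None
    else:
        undershoot = (
            np.sign(final_level - target_level) == np.sign(start_level - target_level)
            and final_level != target_level
        )
    return int(distance), bool(closer), undershoot


def _positional_matches(digits: list[str], responses: list[str]) -> int:
    return sum(d == r for d, r in zip(digits, responses))


def parity_score(digit_parities, response_parities) -> float:
    """Dislocation-tolerant parity accuracy in [0, 1].

    ``matches / max(n_digits, n_responses)``, where matches is the best
    positional agreement over alignments of the response series.  The series
    may be realigned only when it holds an extra response (one deletion
    considered at every position) or is missing one (one gap insertion
    considered at every position); the unshifted alignment always competes.
    No responses scores 0.
    """
    digits = [str(p).lower() for p in digit_parities]
    responses = [str(p).lower() for p in response_parities]
    if not responses:
        return 0.0
    if not digits:
        return 0.0
    nd, nr = len(digits), len(responses)
    best = _positional_matches(digits, responses)
    if nr == nd + 1:  # one extra response: try deleting each
        for i in range(nr):
            trimmed = responses[:i] + responses[i + 1 :]
            best = max(best, _positional_matches(digits, trimmed))
    elif nr == nd - 1:  # one missing response: try a gap at each position
        for i in range(nd):
            padded = responses[:i] + ["<gap>"] + responses[i:]
            best = max(best, _positional_matches(digits, padded))
    return best / max(nd, nr)


def rating_accuracy(responses_1to4, true_values) -> float | None:
    """Spearman rank correlation of 1-4 ratings with their true values.

    Missing responses (None or NaN) are replaced by 2.5, the midpoint of
    both rating scales.  Returns None with fewer than three trials or when
    either series has zero variance (rank correlation undefined).
    """
    resp = np.array(
        [2.5 if r is None or (isinstance(r, float) and np.isnan(r)) else float(r)
         for r in responses_1to4]
    )
    truth = np.asarray(true_values, dtype=float)
    if resp.size != truth.size:
        raise ValueError("responses and true values must have equal length")
    if resp.size < 3:
        return None
    if np.ptp(resp) == 0 or np.ptp(truth) == 0:
        return None
    rho = spearmanr(resp, truth).statistic
    return float(rho)


def arcsine_sqrt(p) -> np.ndarray | float:
    """Variance-stabilising transform for proportions: asin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def fisher_z(r) -> np.ndarray | float:
    """Fisher z-transform for correlations: atanh(r); rejects r = +/-1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def transform_stats(values, kind: str):
    """Apply the group-statistics transform: 'proportion' or 'correlation'."""
    if kind == "proportion":
        return arcsine_sqrt(values)
    if kind == "correlation":
        return fisher_z(values)
    raise ValueError(f"unknown transform kind {kind!r}")


def exclusion_flags(
    adjustment_scores,
    motion_series_mm,
    sd_threshold: float = 2.0,
    motion_threshold_mm: float = 3.0,
) -> pd.DataFrame:
    """Flag low performers and movers for exclusion.

    ``adjustment_scores`` is one mean final-distance per subject (lower is
    better); performance is sign-flipped before the rule flagging subjects
    more than two group SDs below the mean.  ``motion_series_mm`` is one
    displacement series per subject; any displacement above one voxel (3 mm)
    flags the subject.  With zero score variance nobody is flagged.
    """
    scores = np.asarray(adjustment_scores, dtype=float)
    if scores.size < 3:
        raise ValueError("the SD rule needs at least three subjects")
    perf = -scores
    sd = perf.std(ddof=1)
    low = (
        perf < perf.mean() - sd_threshold * sd
        if sd > 0
        else np.zeros(scores.size, dtype=bool)
    )
    movers = np.array(
        [bool(np.max(np.abs(np.asarray(m, dtype=float))) > motion_threshold_mm)
         for m in motion_series_mm]
    )
    if movers.size != scores.size:
        raise ValueError("one motion series per subject required")
    return pd.DataFrame(
        {
            "low_performance": low,
            "high_motion": movers,
            "excluded": low | movers,
        }
    )


# ---------------------------------------------------------------------------
# Event-table scoring


def _trial_truth_bins(events_trial: pd.DataFrame, n_levels: int) -> int:
    """Recompute the rating truth bin for one trial from its events."""
    adj = events_trial[events_trial.event_type == "adjust_stack"]
    final = int(adj.sort_values("onset")["density_level"].iloc[-1])
    target = events_trial["target_level"].iloc[0]
    if pd.notna(target):
        d = abs(final - int(target))
        return 1 if d <= 1 else 2 if d <= 4 else 3 if d <= 8 else 4
    return int(final * 4 // n_levels) + 1 if final < n_levels else 4


def score_session(events: pd.DataFrame, n_levels: int) -> pd.DataFrame:
    """Score every trial of a simulated (or recorded) session event table.

    Returns one row per trial with navigation, parity and rating scores;
    fields that do not apply to a condition are NaN.
    """
    rows = []
    for idx, g in events.groupby("trial_index", sort=True):
        cond = g["condition"].iloc[0]
        adj = g[g.event_type == "adjust_stack"].sort_values("onset")
        start = int(adj["density_level"].iloc[0])
        final = int(adj["density_level"].iloc[-1])
        row = dict(trial_index=int(idx), condition=cond, start_level=start,
                   final_level=final)
        target = g["target_level"].iloc[0]
        if cond == "MA" and pd.notna(target):
            dist, closer, under = navigation_score(start, final, int(target))
            row.update(final_distance_steps=dist, closer_than_start=closer,
                       undershoot=under)
        if cond in ("MP", "NP"):
            digits = g[g.event_type == "digit"].sort_values("onset")
            resp = g[g.event_type == "parity_response"].sort_values("onset")
            digit_par = ["odd" if int(v) % 2 else "even"
                         for v in digits["digit_value"]]
            row["parity_accuracy"] = parity_score(digit_par, list(resp["value"]))
        rating = g[g.event_type == "rating_response"]
        row["rating"] = int(rating["value"].iloc[0]) if len(rating) else None
        row["rating_truth"] = _trial_truth_bins(g, n_levels)
        rows.append(row)
    return pd.DataFrame(rows)


def subject_summary(trial_scores: pd.DataFrame) -> dict:
    """Aggregate one subject's trial scores to the session level."""
    ma = trial_scores[trial_scores.condition == "MA"]
    out = {
        "mean_final_distance": float(ma["final_distance_steps"].mean()),
        "prop_closer": float(ma["closer_than_start"].mean()),
        "prop_undershoot": float(ma["undershoot"].dropna().astype(bool).mean()),
    }
    for cond in ("MP", "NP"):
        sub = trial_scores[trial_scores.condition == cond]
        out[f"parity_accuracy_{cond}"] = float(sub["parity_accuracy"].mean())
    for conds, name in ((("MA", "MP"), "memory"), (("NA", "NP"), "nomem")):
        sub = trial_scores[trial_scores.condition.isin(conds)]
        out[f"rating_rho_{name}"] = rating_accuracy(
            list(sub["rating"]), list(sub["rating_truth"])
        )
    return out
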