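"""Model-agnostic behavioral statistics for reversal sessions.

* trials to criterion, per phase and total;
* perseverative errors after each reversal ("7 of the last 10
  responses incorrect" rule);
* win-stay and lose-shift probabilities over consecutive trial pairs;
* self-administration escalation ratio and the cohort median split
  into low- (LE) and high-escalation (HE) groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .task import Session, TaskConfig, check_criterion

__all__ = [
    "SessionSummary",
    "EscalationRecord",
    "win_stay_lose_shift",
    "trials_to_criterion",
    "perseverative_errors",
    "escalation_ratio",
    "median_split",
    "summarize_session",
    "spearman_permutation_test",
]


@dataclass(frozen=True)
class SessionSummary:
    subject_id: str
    group: str
    timepoint: str
    trials_to_criterion: int
    perseverative_errors: int
    win_stay: Optional[float]
    lose_shift: Optional[float]
    completer: bool


@dataclass
class EscalationRecord:
    """Daily infusion counts over 6 short-access + 7 long-access days."""

    subject_id: str
    daily_counts: List[int]
    escalation_ratio: Optional[float] = None
    group: Optional[str] = None  # LE / HE, assigned by the cohort median split

    def __post_init__(self):
        if len(self.daily_counts) != 13:
            raise ValueError("expected 13 daily counts (days 1-13)")
        if any(c < 0 for c in self.daily_counts):
            raise ValueError("infusion counts must be non-negative")


def win_stay_lose_shift(
    session: Session,
    include_boundary_pairs: bool = True,
    include_retention: bool = True,
) -> Tuple[Optional[float], Optional[float]]:
    """(win_stay, lose_shift) over consecutive trial pairs.

    win_stay: P(repeat previous choice | previous trial rewarded);
    lose_shift: P(switch | previous trial unrewarded). Pairs are pooled
    over the whole session; pairs straddling a reversal boundary and
    retention-phase pairs are included by default (the subject cannot
    observe the reversal) but can be excluded. A probability is None
    when it has no eligible pairs.
    """
    trials = session.trials
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    boundaries = set(session.phase_starts[1:])  # 1-based first trials of reversal phases
    retention_end = (session.phase_starts[1] - 1) if session.n_phases > 1 else len(trials)
    ws_num = ws_den = ls_num = ls_den = 0
    for prev, cur in zip(trials[:-1], trials[1:]):
        if not include_boundary_pairs and cur.trial_index in boundaries:
            continue
        if not include_retention and cur.trial_index <= retention_end:
            continue
        stay = cur.choice == prev.choice
        if prev.reward == 1:
            ws_den += 1
            ws_num += stay
        else:
            ls_den += 1
            ls_num += not stay
    win_stay = ws_num / ws_den if ws_den else None
    lose_shift = ls_num / ls_den if ls_den else None
    return win_stay, lose_shift


def trials_to_criterion(
    session: Session, config: TaskConfig | None = None
) -> Tuple[List[int], int, bool]:
    """Per-phase trial counts to criterion and their total.

    Each completed phase's count is the 1-based index (within the
    phase) of the trial at which the criterion was first satisfied.
    A final phase that never reaches criterion contributes its capped
    trial count and marks the session incomplete.
    """
    config = config or TaskConfig()
    per_phase: List[int] = []
    complete = True
    for sl in session.phase_slices():
        outcomes = [r.reward for r in session.trials[sl]]
        hit = None
        for t in range(1, len(outcomes) + 1):
            if check_criterion(outcomes[:t], config):
                hit = t
                break
        if hit is None:
            per_phase.append(len(outcomes))
            complete = False
        else:
            per_phase.append(hit)
    return per_phase, sum(per_phase), complete


def perseverative_errors(
    session: Session, config: TaskConfig | None = None
) -> Tuple[List[int], int]:
    """Perseverative errors per reversal phase and their total.

    An animal is perseverating after a reversal while at least 7 of its
    last min(t, 10) responses in the phase are incorrect. Errors are
    counted from the phase onset up to the first trial at which that
    condition fails after having held at least once; if it never holds
    (the animal switches quickly), the phase contributes 0.
    """
    config = config or TaskConfig()
    threshold = round(0.7 * config.criterion_window)  # 7 of 10 by default
    window = config.criterion_window
    per_phase: List[int] = []
    for sl in session.phase_slices()[1:]:  # reversal phases only
        errors = [1 - r.reward for r in session.trials[sl]]
        armed = False
        count = 0
        running = 0
        for t, e in enumerate(errors, start=1):
            running += e
            in_window = sum(errors[max(0, t - window) : t])
            if armed and in_window < threshold:
                break
            count = running
            if in_window >= threshold:
                armed = True
        per_phase.append(count if armed else 0)
    return per_phase, sum(per_phase)


def escalation_ratio(daily_counts: Sequence[float]) -> Optional[float]:
    """mean(day 12, day 13) / day 7 — intake on the last two long-access
    days relative to the first. None (flagged) when day 7 is 0."""
    if len(daily_counts) < 13:
        raise ValueError("need counts for days 1-13")
    day7, day12, day13 = daily_counts[6], daily_counts[11], daily_counts[12]
    if day7 == 0:
        warnings.warn("day 7 intake is 0; escalation ratio undefined", stacklevel=2)
        return None
    return (day12 + day13) / 2.0 / day7


def median_split(ratios: Sequence[float]) -> List[str]:
    """Label each subject HE (ratio >= cohort median) or LE (below).

    With an odd cohort the median element joins HE, giving the 9 LE /
    10 HE split of a 19-rat cohort. Ties at the median all go to HE."""
    ratios = list(ratios)
    if len(ratios) < 2:
        raise ValueError("median split needs at least 2 subjects")
    med = float(np.median(ratios))
    labels = ["HE" if r >= med else "LE" for r in ratios]
    if all(lab == "HE" for lab in labels):
        warnings.warn("all ratios at or above the median; every subject labelled HE",
                      stacklevel=2)
    return labels


def summarize_session(session: Session, config: TaskConfig | None = None) -> SessionSummary:
    config = config or TaskConfig()
    _, total, phases_complete = trials_to_criterion(session, config)
    _, persev = perseverative_errors(session, config)
    ws, ls = win_stay_lose_shift(session)
    return SessionSummary(
        subject_id=session.subject_id,
        group=session.group,
        timepoint=session.timepoint,
        trials_to_criterion=total,
        perseverative_errors=persev,
        win_stay=ws,
        lose_shift=ls,
        completer=session.completed and phases_complete,
    )


def spearman_permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 5000,
    rng: np.random.Generator | int | None = 0,
    alternative: str = "less",
) -> Tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    ``alternative='less'`` tests for a negative association (used for
    the stickiness -> lose-shift relationship).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    observed = _corr(rx, ry)
    hits = 0
    for _ in range(n_permutations):
        perm = _corr(rx, rng.permutation(ry))
        if alternative == "less":
            hits += perm <= observed
        elif alternative == "greater":
            hits += perm >= observed
        else:
            hits += abs(perm) >= abs(observed)
    p = (hits + 1) / (n_permutations + 1)
    return observed, float(p)
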