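"""Criterion-driven serial spatial-reversal task simulator.

A session starts with a retention phase (the side rewarded on the
previous day stays correct). Each phase ends on the first trial at
which the subject has made at least ``criterion_correct`` correct
responses over the last ``criterion_window`` trials (evaluated over all
trials so far while fewer than a full window has elapsed, so nine
straight correct responses complete a phase at trial nine). On
criterion the correct side flips, silently for the agent: Q values and
the previous-choice indicator carry over. Reward is deterministic —
choosing the correct side always pays 1, the other side 0.

Sessions that fail to complete all reversals within the per-phase trial
cap are flagged as non-completers, mirroring the exclusion of animals
that did not finish three reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

from .qmodels import (
    AgentParams,
    QState,
    Side,
    TrialRecord,
    init_state,
    simulate_choice,
    update_q,
)

__all__ = [
    "TaskConfig",
    "Session",
    "check_criterion",
    "run_session",
    "run_fixed_trials",
    "validate_session",
    "phase_name",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task constants. Defaults are the study's: 9-of-10 criterion,
    retention phase plus three reversals, and a 400-trial cap per phase
    standing in for the 1 h session limit."""

    criterion_correct: int = 9
    criterion_window: int = 10
    n_reversals: int = 3
    max_trials_per_phase: int = 400
    initial_correct_side: Side = "L"
    q0: float = 0.0

    def __post_init__(self):
        if self.criterion_correct > self.criterion_window:
            raise ValueError("criterion_correct must be <= criterion_window")
        if self.criterion_correct < 1 or self.criterion_window < 1:
            raise ValueError("criterion must be positive")
        if self.n_reversals < 0:
            raise ValueError("n_reversals must be >= 0")
        if self.max_trials_per_phase < self.criterion_window:
            raise ValueError("max_trials_per_phase must be >= criterion_window")
        if self.initial_correct_side not in ("L", "R"):
            raise ValueError("initial_correct_side must be 'L' or 'R'")


def phase_name(phase_index: int) -> str:
    """0 -> 'retention', i -> 'rev{i}'."""
    return "retention" if phase_index == 0 else f"rev{phase_index}"


@dataclass
class Session:
    """One subject x timepoint trial sequence."""

    subject_id: str
    group: str
    timepoint: str
    trials: List[TrialRecord] = field(default_factory=list)
    #: 1-based indices of the first trial of each phase (starts with 1)
    phase_starts: List[int] = field(default_factory=list)
    completed: bool = True

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_phases(self) -> int:
        return len(self.phase_starts)

    def phase_slices(self) -> List[slice]:
        """0-based slices of ``trials`` per phase, in order."""
        starts = [s - 1 for s in self.phase_starts] + [len(self.trials)]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]


def check_criterion(outcomes: Sequence[int], config: TaskConfig) -> bool:
    """True iff >= criterion_correct of the last min(t, window) outcomes are 1."""
    t = len(outcomes)
    if t == 0:
        raise ValueError("outcome history is empty")
    window = min(t, config.criterion_window)
    return sum(outcomes[-window:]) >= config.criterion_correct


def _simulate(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    n_reversals: int,
    n_trials: int | None,
    subject_id: str,
    group: str,
    timepoint: str,
) -> Session:
    session = Session(subject_id, group, timepoint, phase_starts=[1])
    state = init_state(config.q0)
    correct = config.initial_correct_side
    phase_idx = 0
    phase_outcomes: List[int] = []
    t = 0
    while True:
        if n_trials is not None and t >= n_trials:
            break
        if n_trials is None and phase_idx > n_reversals:
            break
        choice = simulate_choice(state, params, rng)
        reward = int(choice == correct)
        t += 1
        session.trials.append(
            TrialRecord(choice, reward, correct, phase_name(phase_idx), t)
        )
        state = update_q(state, choice, reward, params)
        phase_outcomes.append(reward)
        if check_criterion(phase_outcomes, config):
            phase_idx += 1
            if n_trials is None and phase_idx > n_reversals:
                break
            if n_trials is not None and t >= n_trials:
                break
            correct = "R" if correct == "L" else "L"
            session.phase_starts.append(t + 1)
            phase_outcomes = []
        elif len(phase_outcomes) >= config.max_trials_per_phase:
            session.completed = False
            break
    return session


def run_session(
    params: AgentParams,
    config: TaskConfig,
    rng: Union[int, np.random.Generator],
    *,
    subject_id: str = "sim",
    group: str = "unknown",
    timepoint: str = "pre",
) -> Session:
    """Simulate a retention + ``n_reversals`` session.

    Hitting the per-phase cap flags the session as a non-completer
    rather than raising. Fully reproducible given an integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return _simulate(
        params,
        config,
        rng,
        n_reversals=config.n_reversals,
        n_trials=None,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def run_fixed_trials(
    params: AgentParams,
    config: TaskConfig,
    n_trials: int,
    rng: Union[int, np.random.Generator],
    *,
    subject_id: str = "sim",
    group: str = "unknown",
    timepoint: str = "pre",
) -> Session:
    """Simulate exactly ``n_trials`` trials, reversing on criterion
    indefinitely (phases beyond rev3 are labelled rev4, rev5, ...).

    Used for parameter-recovery studies, where a fixed, longer sequence
    makes estimation quality comparable across subjects.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return _simulate(
        params,
        config,
        rng,
        n_reversals=0,
        n_trials=n_trials,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def validate_session(
    session: Session,
    config: TaskConfig | None = None,
    *,
    require_final_criterion: bool | None = None,
) -> List[str]:
    """Check Session invariants; returns human-readable findings ([] = valid).

    Checks: deterministic reward consistency, one correct side per
    phase, alternation of correct sides across phases, criterion
    satisfied at each phase boundary and not earlier. The final phase
    must end at criterion only when the session is a completer (or when
    ``require_final_criterion`` overrides; fixed-length recovery
    sessions are truncated mid-phase, so pass False for those).
    """
    config = config or TaskConfig()
    findings: List[str] = []
    if not session.trials:
        return ["session has no trials"]
    if session.phase_starts[:1] != [1]:
        findings.append("first phase must start at trial 1")
    for rec, expect in zip(session.trials, range(1, len(session.trials) + 1)):
        if rec.trial_index != expect:
            findings.append(f"trial index {rec.trial_index} out of order (expected {expect})")
        if rec.reward != int(rec.choice == rec.correct_side):
            findings.append(f"trial {rec.trial_index}: reward inconsistent with correct side")
    prev_side = None
    slices = session.phase_slices()
    for k, sl in enumerate(slices):
        phase = session.trials[sl]
        if not phase:
            findings.append(f"phase {k} is empty")
            continue
        sides = {r.correct_side for r in phase}
        if len(sides) != 1:
            findings.append(f"phase {k} has multiple correct sides {sorted(sides)}")
            continue
        side = phase[0].correct_side
        if prev_side is not None and side == prev_side:
            findings.append(f"phase {k} does not reverse the correct side")
        prev_side = side
        outcomes = [r.reward for r in phase]
        is_last = k == len(slices) - 1
        final_required = (
            session.completed if require_final_criterion is None else require_final_criterion
        )
        complete = not is_last or final_required
        for t in range(1, len(outcomes) + 1):
            met = check_criterion(outcomes[:t], config)
            if met and t < len(outcomes):
                findings.append(f"phase {k}: criterion met at trial {t} but phase continued")
                break
            if t == len(outcomes) and complete and not met:
                findings.append(f"phase {k}: ends without satisfying the criterion")
    return findings
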