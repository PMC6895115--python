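import numpy as np
import pytest

from revlearn.qmodels import AgentParams, Model, TrialRecord
from revlearn.task import Session, TaskConfig, run_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def task_config():
    return TaskConfig()


def make_session(choices, correct_sides, subject_id="s1", group="control", timepoint="pre"):
    """Build a session from explicit choice / correct-side sequences,
    deriving rewards and phase boundaries from correct-side changes."""
    trials = []
    phase_starts = [1]
    phase_idx = 0
    for t, (c, cs) in enumerate(zip(choices, correct_sides), start=1):
        if t > 1 and cs != correct_sides[t - 2]:
            phase_idx += 1
            phase_starts.append(t)
        phase = "retention" if phase_idx == 0 else f"rev{phase_idx}"
        trials.append(TrialRecord(c, int(c == cs), cs, phase, t))
    return Session(subject_id, group, timepoint, trials, phase_starts, True)


@pytest.fixture
def session_factory():
    """Random sessions from an M3 agent, one per call."""
    counter = [0]

    def _make(seed=None, n_trials=None, beta=0.4, kappa=0.2, alpha=0.6):
        from revlearn.task import run_fixed_trials

        counter[0] += 1
        seed = counter[0] if seed is None else seed
        params = AgentParams.make("M3", alpha=alpha, beta=beta, kappa=kappa)
        cfg = TaskConfig()
        if n_trials is None:
            return run_session(params, cfg, seed)
        return run_fixed_trials(params, cfg, n_trials, seed)

    return _make


@pytest.fixture
def coin_flip_session_factory():
    """Sessions whose choices are fair coin flips (no model structure)."""

    def _make(seed, n_trials=40):
        rng = np.random.default_rng(seed)
        choices = ["L" if rng.random() < 0.5 else "R" for _ in range(n_trials)]
        correct = ["L"] * n_trials
        return make_session(choices, correct)

    return _make
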