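"""Model-free Q-learning agents for a two-choice spatial task.

Four nested variants are defined, all built on Rescorla–Wagner value
updating and a softmax choice rule with a temperature convention
(Q divided by beta, so *larger* beta means *more* exploration):

==== =========================================  ==============
id   free parameters                            k
==== =========================================  ==============
M1   alpha, beta                                2
M2   alpha_reward, alpha_noreward, beta         3
M3   alpha, beta, kappa                         3
M4   alpha_reward, alpha_noreward, beta, kappa  4
==== =========================================  ==============

kappa is a choice-autocorrelation ("stickiness") weight added to the
softmax argument of whichever side was chosen on the previous trial;
it is added outside the 1/beta scaling. M1 and M2 are the kappa = 0
special cases, so every model can be evaluated through the same code
path. Values are updated only for the chosen option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "Model",
    "Side",
    "AgentParams",
    "QState",
    "TrialRecord",
    "init_state",
    "update_q",
    "choice_prob",
    "simulate_choice",
    "MODEL_N_PARAMS",
]


class Model(str, Enum):
    """The four agent variants."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"


#: number of free parameters k per model
MODEL_N_PARAMS = {Model.M1: 2, Model.M2: 3, Model.M3: 3, Model.M4: 4}

#: models with separate learning rates for rewarded / unrewarded trials
DUAL_RATE_MODELS = frozenset({Model.M2, Model.M4})

#: models with a free stickiness parameter
STICKY_MODELS = frozenset({Model.M3, Model.M4})

Side = str  # "L" or "R"
SIDES = ("L", "R")


def _check_side(side: Side) -> None:
    if side not in SIDES:
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one agent.

    alpha_reward / alpha_noreward are stored for every model; for the
    single-rate models (M1, M3) they are equal and exposed as ``alpha``.
    kappa is exactly 0 for the non-sticky models (M1, M2).
    """

    model: Model
    alpha_reward: float
    alpha_noreward: float
    beta: float
    kappa: float = 0.0

    def __post_init__(self):
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        for name in ("alpha_reward", "alpha_noreward"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name}={a} outside [0, 1]")
        if not (self.beta > 0.0 and math.isfinite(self.beta)):
            raise ValueError(f"beta={self.beta} must be positive and finite")
        if not -1.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa={self.kappa} outside [-1, 1]")
        if model not in DUAL_RATE_MODELS and self.alpha_reward != self.alpha_noreward:
            raise ValueError(f"{model.value} uses a single learning rate")
        if model not in STICKY_MODELS and self.kappa != 0.0:
            raise ValueError(f"{model.value} requires kappa = 0")

    @classmethod
    def make(
        cls,
        model: Union[Model, str],
        *,
        alpha: float | None = None,
        alpha_reward: float | None = None,
        alpha_noreward: float | None = None,
        beta: float,
        kappa: float = 0.0,
    ) -> "AgentParams":
        """Build params using each model's natural parameterization."""
        model = Model(model)
        if model in DUAL_RATE_MODELS:
            if alpha_reward is None or alpha_noreward is None:
                if alpha is None:
                    raise ValueError(f"{model.value} needs alpha_reward and alpha_noreward")
                alpha_reward = alpha_noreward = alpha
        else:
            if alpha is None:
                raise ValueError(f"{model.value} needs alpha")
            alpha_reward = alpha_noreward = alpha
        if model not in STICKY_MODELS and kappa != 0.0:
            raise ValueError(f"{model.value} requires kappa = 0")
        return cls(model, alpha_reward, alpha_noreward, beta, kappa)

    @property
    def alpha(self) -> float:
        if self.alpha_reward != self.alpha_noreward:
            raise AttributeError("dual-rate model has no single alpha")
        return self.alpha_reward

    @property
    def n_free_params(self) -> int:
        return MODEL_N_PARAMS[self.model]


@dataclass(frozen=True)
class QState:
    """Agent state before a trial: the two Q values and the
    previous-choice indicators L_{t-1}, R_{t-1} (both 0 before trial 1)."""

    q_left: float
    q_right: float
    prev_left: int = 0
    prev_right: int = 0

    def __post_init__(self):
        if self.prev_left + self.prev_right not in (0, 1):
            raise ValueError("at most one previous-choice indicator may be set")


@dataclass(frozen=True)
class TrialRecord:
    """One observed (or simulated) trial."""

    choice: Side
    reward: int
    correct_side: Side
    phase: str
    trial_index: int  # 1-based within the session

    def __post_init__(self):
        _check_side(self.choice)
        _check_side(self.correct_side)
        if self.reward not in (0, 1):
            raise ValueError("reward must be 0 or 1")
        if self.reward != int(self.choice == self.correct_side):
            raise ValueError(
                f"trial {self.trial_index}: reward inconsistent with deterministic contingency"
            )


def init_state(q0: float = 0.0) -> QState:
    """Fresh state with both Q values at ``q0`` and no previous choice."""
    if not 0.0 <= q0 <= 1.0:
        raise ValueError(f"q0={q0} outside [0, 1]")
    return QState(q0, q0, 0, 0)


def update_q(state: QState, choice: Side, reward: int, params: AgentParams) -> QState:
    """Rescorla–Wagner delta-rule update of the chosen option.

    Q(c) <- Q(c) + alpha_eff * (r - Q(c)) with alpha_eff selected by the
    outcome for the dual-rate models. The unchosen option is unchanged;
    previous-choice indicators are set to this trial's choice.
    """
    _check_side(choice)
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    alpha = params.alpha_reward if reward == 1 else params.alpha_noreward
    if choice == "L":
        q_left = state.q_left + alpha * (reward - state.q_left)
        return QState(q_left, state.q_right, 1, 0)
    q_right = state.q_right + alpha * (reward - state.q_right)
    return QState(state.q_left, q_right, 0, 1)


def choice_prob(state: QState, params: AgentParams) -> float:
    """P(choose L) under the softmax rule with stickiness.

    P(L) = exp(Q(L)/beta + kappa*L_{t-1})
           / [exp(Q(L)/beta + kappa*L_{t-1}) + exp(Q(R)/beta + kappa*R_{t-1})]

    computed through the logistic of the argument difference for
    numerical stability. Strictly inside (0, 1).
    """
    z = (state.q_left - state.q_right) / params.beta + params.kappa * (
        state.prev_left - state.prev_right
    )
    return float(np.exp(-np.logaddexp(0.0, -z)))


def simulate_choice(state: QState, params: AgentParams, rng: np.random.Generator) -> Side:
    """Draw a choice from the model's choice distribution."""
    return "L" if rng.random() < choice_prob(state, params) else "R"
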