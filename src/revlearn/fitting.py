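"""Per-subject maximum-likelihood fitting over a discrete parameter grid.

The hypothesis space is treated as discrete: every combination of grid
values is evaluated exhaustively and the maximizer returned (no local
optimization, no restarts). Default axes are

    alpha: 0.001 to 1 in steps of 0.08   (13 points)
    beta:  0.005 to 5 in steps of 0.08   (63 points)
    kappa: -1 to 1 in steps of 0.08      (26 points)

The log-likelihood of a session factorizes over trials,
log P(D | M, theta) = sum_t log P(c_t | Q_t, prev choice), which lets
the grid search be organized efficiently: the Q-value trajectory
depends only on the learning rate(s), so for each learning-rate point
the (beta, kappa) plane is evaluated with one broadcast expression.
Per-element arithmetic and the trial-axis summation are identical
between this vectorized path and ``sequence_loglik``, so a naive
nested loop over grid points reproduces ``grid_fit`` exactly.

Ties (common in short sessions) are broken by scan order: learning
rates ascending (reward rate outermost), then beta, then kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .comparison import bic, pseudo_r2
from .qmodels import (
    DUAL_RATE_MODELS,
    MODEL_N_PARAMS,
    STICKY_MODELS,
    AgentParams,
    Model,
)
from .task import Session

__all__ = [
    "ParameterGrid",
    "FitResult",
    "build_axis",
    "paper_grid",
    "session_arrays",
    "sequence_loglik",
    "grid_fit",
    "fit_all_models",
]

_AXIS_TOL = 1e-9


def build_axis(lower: float, upper: float, step: float) -> np.ndarray:
    """Grid axis lower, lower+step, ... while <= upper (tolerance 1e-9)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lower >= upper:
        raise ValueError("lower must be < upper")
    n = int(np.floor((upper - lower) / step + _AXIS_TOL)) + 1
    return lower + step * np.arange(n)


@dataclass(frozen=True)
class ParameterGrid:
    """Discrete axes for the three parameters. Dual learning rates share
    the alpha axis. ``augmented`` adds the neutral points (kappa = 0)
    needed for exact nesting of the sticky models."""

    alpha_axis: np.ndarray
    beta_axis: np.ndarray
    kappa_axis: np.ndarray

    def __post_init__(self):
        for name, axis, lo, hi in (
            ("alpha_axis", self.alpha_axis, 0.0, 1.0),
            ("beta_axis", self.beta_axis, 0.0, np.inf),
            ("kappa_axis", self.kappa_axis, -1.0, 1.0),
        ):
            axis = np.asarray(axis, dtype=float)
            object.__setattr__(self, name, axis)
            if axis.ndim != 1 or axis.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-d array")
            if np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if axis[0] < lo - _AXIS_TOL or axis[-1] > hi + _AXIS_TOL:
                raise ValueError(f"{name} outside [{lo}, {hi}]")
        if self.beta_axis[0] <= 0:
            raise ValueError("beta axis must be strictly positive")

    def augmented(self) -> "ParameterGrid":
        """Axes with kappa = 0 inserted if absent."""
        kappa = self.kappa_axis
        if not np.any(np.isclose(kappa, 0.0, atol=_AXIS_TOL)):
            kappa = np.sort(np.append(kappa, 0.0))
        return ParameterGrid(self.alpha_axis, self.beta_axis, kappa)


def paper_grid() -> ParameterGrid:
    """The study's published axes."""
    return ParameterGrid(
        alpha_axis=build_axis(0.001, 1.0, 0.08),
        beta_axis=build_axis(0.005, 5.0, 0.08),
        kappa_axis=build_axis(-1.0, 1.0, 0.08),
    )


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and fit statistics for one session x model."""

    model: Model
    params: AgentParams
    log_likelihood: float
    n_trials: int
    n_free_params: int
    pseudo_r2: float
    bic: float

    def __post_init__(self):
        if self.log_likelihood > 0:
            raise ValueError("log-likelihood of a choice sequence cannot be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def session_arrays(session: Session) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(choices, rewards, dprev) as arrays.

    choices: 0 = L, 1 = R; rewards in {0, 1};
    dprev[t] = +1 if trial t repeats the previous choice, -1 if it
    switches, 0 on the first trial (no previous-choice indicator set).
    """
    if not session.trials:
        raise ValueError("session has no trials")
    choices = np.fromiter((0 if r.choice == "L" else 1 for r in session.trials), dtype=np.int64)
    rewards = np.fromiter((r.reward for r in session.trials), dtype=np.float64)
    dprev = np.zeros(len(choices))
    same = choices[1:] == choices[:-1]
    dprev[1:] = np.where(same, 1.0, -1.0)
    return choices, rewards, dprev


def _dq_trajectories(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha_reward: np.ndarray,
    alpha_noreward: np.ndarray,
    q0: float,
) -> np.ndarray:
    """Q(chosen) - Q(unchosen) before each trial, for each learning-rate
    pair; shape (n_pairs, n_trials). The trajectory is independent of
    beta and kappa, which enter the observation rule only."""
    a_r = np.atleast_1d(np.asarray(alpha_reward, dtype=float))
    a_nr = np.atleast_1d(np.asarray(alpha_noreward, dtype=float))
    n_pairs = a_r.shape[0]
    T = choices.shape[0]
    q = np.full((n_pairs, 2), float(q0))
    dq = np.empty((n_pairs, T))
    for t in range(T):
        c = choices[t]
        dq[:, t] = q[:, c] - q[:, 1 - c]
        alpha = a_r if rewards[t] == 1.0 else a_nr
        q[:, c] = q[:, c] + alpha * (rewards[t] - q[:, c])
    return dq


def _per_trial_logp(dq: np.ndarray, dprev: np.ndarray, beta, kappa) -> np.ndarray:
    """log P(observed choice) per trial; broadcasts over beta/kappa axes."""
    z = dq / beta + kappa * dprev
    return -np.logaddexp(0.0, -z)


def sequence_loglik(session: Session, params: AgentParams, q0: float = 0.0) -> float:
    """Natural-log likelihood of the observed choice sequence under the
    model, advancing the Q state trial by trial."""
    choices, rewards, dprev = session_arrays(session)
    dq = _dq_trajectories(
        choices, rewards, [params.alpha_reward], [params.alpha_noreward], q0
    )[0]
    return float(np.sum(_per_trial_logp(dq, dprev, params.beta, params.kappa)))


def _model_axes(
    model: Model, grid: ParameterGrid
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(alpha_reward, alpha_noreward) pairs in scan order plus the beta
    and kappa axes for the model (kappa pinned to 0 for M1/M2)."""
    a = grid.alpha_axis
    if model in DUAL_RATE_MODELS:
        a_r = np.repeat(a, a.size)
        a_nr = np.tile(a, a.size)
    else:
        a_r = a_nr = a
    kappa = grid.kappa_axis if model in STICKY_MODELS else np.array([0.0])
    return a_r, a_nr, grid.beta_axis, kappa


def grid_fit(
    session: Session,
    model: Model | str,
    grid: ParameterGrid | None = None,
    q0: float = 0.0,
) -> FitResult:
    """Exhaustive maximum-likelihood search over the model's grid.

    Equivalent to evaluating ``sequence_loglik`` at every grid point and
    taking the first maximizer in scan order (learning rates ascending,
    then beta, then kappa).
    """
    model = Model(model)
    grid = grid or paper_grid()
    choices, rewards, dprev = session_arrays(session)
    a_r, a_nr, beta_axis, kappa_axis = _model_axes(model, grid)
    dq = _dq_trajectories(choices, rewards, a_r, a_nr, q0)

    beta_col = beta_axis[:, None, None]
    kappa_col = kappa_axis[None, :, None]
    best_ll = -np.inf
    best = (0, 0, 0)
    for i in range(a_r.size):
        # (n_beta, n_kappa): sum over the trial axis, same reduction as
        # the scalar path so results match a nested loop bit for bit
        ll = np.sum(_per_trial_logp(dq[i], dprev, beta_col, kappa_col), axis=-1)
        flat = int(np.argmax(ll))
        top = float(ll.flat[flat])
        if top > best_ll:
            best_ll = top
            best = (i, *np.unravel_index(flat, ll.shape))
    i, j, k = best
    params = AgentParams(
        model,
        float(a_r[i]),
        float(a_nr[i]),
        float(beta_axis[j]),
        float(kappa_axis[k]),
    )
    n = len(session.trials)
    k_free = MODEL_N_PARAMS[model]
    return FitResult(
        model=model,
        params=params,
        log_likelihood=best_ll,
        n_trials=n,
        n_free_params=k_free,
        pseudo_r2=pseudo_r2(best_ll, n),
        bic=bic(best_ll, k_free, n),
    )


def fit_all_models(
    session: Session,
    grid: ParameterGrid | None = None,
    models: Iterable[Model | str] = tuple(Model),
    q0: float = 0.0,
) -> dict:
    """Fit each requested model to the session."""
    return {Model(m): grid_fit(session, m, grid, q0) for m in models}
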