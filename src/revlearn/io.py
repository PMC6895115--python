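"""CSV interchange formats, YAML run configuration and run logging.

Trials table columns (header required)::

    subject_id, group, timepoint, phase, trial, choice, correct_side, reward

Rows are sorted by subject, timepoint, trial; trial indices are 1-based
and strictly increasing within a subject x timepoint; reward must be
consistent with choice == correct_side (deterministic contingency).
Schema violations are reported with their row numbers.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import EscalationRecord
from .fitting import FitResult, ParameterGrid, build_axis, paper_grid
from .task import Session, TaskConfig
from .qmodels import TrialRecord

__all__ = [
    "TrialsParseError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_infusions",
    "write_infusions",
    "fits_to_frame",
    "load_config",
    "save_config",
    "config_hash",
    "write_run_log",
]

TRIALS_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "phase",
    "trial",
    "choice",
    "correct_side",
    "reward",
]

TIMEPOINT_ORDER = {"pre": 0, "post": 1}


class TrialsParseError(ValueError):
    """Raised on trials-table schema violations; carries row numbers."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def write_trials(sessions: Sequence[Session], path) -> None:
    rows = []
    for s in sessions:
        for r in s.trials:
            rows.append(
                (s.subject_id, s.group, s.timepoint, r.phase, r.trial_index,
                 r.choice, r.correct_side, r.reward)
            )
    df = pd.DataFrame(rows, columns=TRIALS_COLUMNS)
    df = df.sort_values(
        ["subject_id", "timepoint", "trial"],
        key=lambda col: col.map(TIMEPOINT_ORDER) if col.name == "timepoint" else col,
        kind="stable",
    )
    df.to_csv(path, index=False)


def read_trials(path) -> List[Session]:
    """Parse and validate a trials CSV into Sessions.

    Phase boundaries are reconstructed from phase-label changes.
    Violations (missing columns, bad values, inconsistent reward bits,
    non-increasing trial indices) raise TrialsParseError naming the
    offending data rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise TrialsParseError([f"missing columns: {', '.join(missing)}"])
    problems: List[str] = []
    sessions: List[Session] = []
    for (subject, tp), sub in df.groupby(["subject_id", "timepoint"], sort=True):
        session = Session(str(subject), str(sub["group"].iloc[0]), str(tp), [], [], True)
        prev_trial = 0
        prev_phase = None
        for row_no, row in zip(sub.index + 2, sub.itertuples(index=False)):
            # row_no: 1-based file line (header is line 1)
            try:
                trial = int(row.trial)
                reward = int(row.reward)
            except (TypeError, ValueError):
                problems.append(f"row {row_no}: non-integer trial or reward")
                continue
            if row.choice not in ("L", "R") or row.correct_side not in ("L", "R"):
                problems.append(f"row {row_no}: choice/correct_side must be L or R")
                continue
            if reward != int(row.choice == row.correct_side):
                problems.append(f"row {row_no}: reward inconsistent with choice vs correct_side")
                continue
            if trial <= prev_trial:
                problems.append(
                    f"row {row_no}: trial index {trial} not increasing within "
                    f"{subject}/{tp}"
                )
                continue
            prev_trial = trial
            if row.phase != prev_phase:
                session.phase_starts.append(trial)
                prev_phase = row.phase
            session.trials.append(
                TrialRecord(row.choice, reward, row.correct_side, str(row.phase), trial)
            )
        if session.trials:
            sessions.append(session)
    if problems:
        raise TrialsParseError(problems)
    return sessions


def write_infusions(records: Sequence[EscalationRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id}
        row.update({f"day{d}": c for d, c in enumerate(rec.daily_counts, start=1)})
        row["escalation_ratio"] = rec.escalation_ratio
        row["group"] = rec.group
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_infusions(path) -> List[EscalationRecord]:
    df = pd.read_csv(path)
    day_cols = [f"day{d}" for d in range(1, 14)]
    missing = [c for c in ["subject_id", *day_cols] if c not in df.columns]
    if missing:
        raise TrialsParseError([f"infusions table missing columns: {', '.join(missing)}"])
    records = []
    for row in df.itertuples(index=False):
        rec = EscalationRecord(
            subject_id=str(row.subject_id),
            daily_counts=[int(getattr(row, c)) for c in day_cols],
        )
        if "escalation_ratio" in df.columns and pd.notna(row.escalation_ratio):
            rec.escalation_ratio = float(row.escalation_ratio)
        if "group" in df.columns and pd.notna(row.group):
            rec.group = str(row.group)
        records.append(rec)
    return records


def fits_to_frame(fits: Dict[Tuple[str, str], Dict], subsets: Dict[Tuple[str, str], str] | None = None) -> pd.DataFrame:
    """Long-format fits table: one row per subject x timepoint x model."""
    rows = []
    for (subject, tp), per_model in fits.items():
        for model, fit in per_model.items():
            rows.append(
                {
                    "subject_id": subject,
                    "timepoint": tp,
                    "subset": subsets.get((subject, tp)) if subsets else tp,
                    "model": fit.model.value,
                    "k": fit.n_free_params,
                    "alpha_reward": fit.params.alpha_reward,
                    "alpha_noreward": fit.params.alpha_noreward,
                    "beta": fit.params.beta,
                    "kappa": fit.params.kappa,
                    "n_trials": fit.n_trials,
                    "log_likelihood": fit.log_likelihood,
                    "pseudo_r2": fit.pseudo_r2,
                    "bic": fit.bic,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the published grid and
    task constants. Round-trips losslessly through YAML."""

    alpha_range: Tuple[float, float, float] = (0.001, 1.0, 0.08)
    beta_range: Tuple[float, float, float] = (0.005, 5.0, 0.08)
    kappa_range: Tuple[float, float, float] = (-1.0, 1.0, 0.08)
    models: Tuple[str, ...] = ("M1", "M2", "M3", "M4")
    criterion_correct: int = 9
    criterion_window: int = 10
    n_reversals: int = 3
    max_trials_per_phase: int = 400
    q0: float = 0.0
    selection_subset: str = "post:HE"
    include_noncompleters: bool = False
    base_seed: int = 0

    def grid(self) -> ParameterGrid:
        return ParameterGrid(
            build_axis(*self.alpha_range),
            build_axis(*self.beta_range),
            build_axis(*self.kappa_range),
        )

    def task(self) -> TaskConfig:
        return TaskConfig(
            criterion_correct=self.criterion_correct,
            criterion_window=self.criterion_window,
            n_reversals=self.n_reversals,
            max_trials_per_phase=self.max_trials_per_phase,
            q0=self.q0,
        )


def save_config(config: RunConfig, path) -> None:
    data = asdict(config)
    data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("alpha_range", "beta_range", "kappa_range", "models"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    data = asdict(config)
    canonical = json.dumps(data, sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_run_log(out_dir, config: RunConfig, seed: int, command: str) -> Path:
    """Machine-readable provenance record written next to every artifact
    set: config hash, seed and software version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "version": __version__,
        "python": platform.python_version(),
    }
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return path
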