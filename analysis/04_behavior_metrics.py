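"""Behavioral statistics of the simulated cohort.

Per subject x timepoint: total trials to criterion, perseverative
errors, win-stay and lose-shift probabilities; per drug-group subject:
escalation ratio with the cohort median split. Group x timepoint means
are printed for a quick read of the headline behavioral pattern.
"""

from pathlib import Path

import pandas as pd

from revlearn.behavior_metrics import median_split, summarize_session
from revlearn.io import RunConfig, read_infusions, read_trials
from revlearn.task import TaskConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = RunConfig()
    sessions = read_trials(OUT / "trials.csv")
    rows = []
    for session in sessions:
        summary = summarize_session(session, config.task())
        if summary.completer:
            rows.append(summary.__dict__)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "behavior_summary.csv", index=False)

    records = read_infusions(OUT / "infusions.csv")
    ratios = [r.escalation_ratio for r in records]
    labels = median_split(ratios)
    esc = pd.DataFrame({"subject_id": [r.subject_id for r in records],
                        "escalation_ratio": ratios, "split": labels})
    esc.to_csv(OUT / "escalation_split.csv", index=False)

    print("group x timepoint means:")
    means = df.groupby(["timepoint", "group"])[
        ["trials_to_criterion", "perseverative_errors", "win_stay", "lose_shift"]
    ].mean().round(3)
    print(means.to_string())
    print("\nescalation ratio by split:")
    print(esc.groupby("split")["escalation_ratio"].agg(["mean", "sem", "count"]).round(2).to_string())


if __name__ == "__main__":
    main()
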