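"""Simulate the synthetic study cohort.

Generates the default three-group (control / low-escalation /
high-escalation) x two-timepoint cohort of criterion-driven serial
reversal sessions, plus 13-day infusion series for the drug groups, and
writes trials.csv, infusions.csv and ground_truth.csv under results/.
"""

from pathlib import Path

from revlearn.behavior_metrics import median_split
from revlearn.io import RunConfig, write_infusions, write_run_log, write_trials
from revlearn.synth_cohort import default_cohort_spec, generate_cohort

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = default_cohort_spec(base_seed=SEED)
    cohort = generate_cohort(spec)

    write_trials(cohort.sessions, OUT / "trials.csv")
    ratios = [r.escalation_ratio for r in cohort.escalation]
    for rec, label in zip(cohort.escalation, median_split(ratios)):
        rec.group = label
    write_infusions(cohort.escalation, OUT / "infusions.csv")
    cohort.ground_truth.to_csv(OUT / "ground_truth.csv", index=False)
    write_run_log(OUT, RunConfig(base_seed=SEED), SEED, "01_simulate_cohort")

    n_sessions = len(cohort.sessions)
    n_noncompleters = sum(not s.completed for s in cohort.sessions)
    lengths = [len(s) for s in cohort.sessions]
    print(f"simulated {n_sessions} sessions "
          f"({spec.n_control}+{spec.n_le}+{spec.n_he} subjects x 2 timepoints)")
    print(f"session length: median {sorted(lengths)[n_sessions // 2]} trials, "
          f"range {min(lengths)}-{max(lengths)}")
    print(f"non-completers flagged: {n_noncompleters}")
    print(f"escalation ratios: {min(ratios):.2f}-{max(ratios):.2f}, "
          f"median split -> {sum(l == 'LE' for l in median_split(ratios))} LE / "
          f"{sum(l == 'HE' for l in median_split(ratios))} HE")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
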