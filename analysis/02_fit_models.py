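"""Fit all four Q-learning models to every simulated session.

Reads results/trials.csv (from 01_simulate_cohort.py), runs the
exhaustive grid search per subject x timepoint x model over the
published axes, and writes results/fits.csv. Non-completer sessions are
excluded, mirroring the study's exclusion rule.
"""

from pathlib import Path

from revlearn.behavior_metrics import trials_to_criterion
from revlearn.fitting import grid_fit
from revlearn.io import RunConfig, fits_to_frame, read_trials, write_run_log
from revlearn.qmodels import Model

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = RunConfig()
    sessions = read_trials(OUT / "trials.csv")
    grid = config.grid()
    fits, subsets = {}, {}
    excluded = 0
    for session in sessions:
        _, _, complete = trials_to_criterion(session, config.task())
        if not (complete and session.completed):
            excluded += 1
            continue
        key = (session.subject_id, session.timepoint)
        subsets[key] = f"{session.timepoint}:{session.group}"
        fits[key] = {m: grid_fit(session, m, grid, q0=config.q0) for m in Model}
    table = fits_to_frame(fits, subsets)
    table.to_csv(OUT / "fits.csv", index=False)
    write_run_log(OUT, config, config.base_seed, "02_fit_models")

    print(f"fitted {len(fits)} sessions x 4 models ({excluded} non-completers excluded)")
    post = table[table.subset.str.startswith("post")]
    for model, sub in post.groupby("model"):
        print(f"  {model}: post-session mean logL {sub.log_likelihood.mean():7.2f}, "
              f"mean pseudo-r2 {sub.pseudo_r2.mean():.3f}, mean BIC {sub.bic.mean():7.2f}")
    print(f"wrote {OUT / 'fits.csv'}")


if __name__ == "__main__":
    main()
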