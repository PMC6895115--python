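"""Nested model comparison on the fitted cohort.

Per subject: likelihood-ratio tests for M1 vs M2, M1 vs M3 and M3 vs
M4. Per cohort cell: mean pseudo-r2 and mean BIC per model, with the
preferred model chosen by mean BIC on the post-exposure high-escalation
cell (the cell the sticky model exists to explain).
"""

from pathlib import Path

import pandas as pd

from revlearn.comparison import select_model
from revlearn.qmodels import MODEL_N_PARAMS, Model
from scipy import stats

OUT = Path(__file__).resolve().parents[1] / "results"
NESTED_PAIRS = [("M1", "M2"), ("M1", "M3"), ("M3", "M4")]


def main() -> None:
    fits = pd.read_csv(OUT / "fits.csv")
    report = select_model(fits, primary_subset="post:HE")

    rows = []
    for (subject, tp), sub in fits.groupby(["subject_id", "timepoint"]):
        by_model = {r.model: r for r in sub.itertuples(index=False)}
        for small, big in NESTED_PAIRS:
            d = max(2.0 * (by_model[big].log_likelihood - by_model[small].log_likelihood), 0.0)
            df = MODEL_N_PARAMS[Model(big)] - MODEL_N_PARAMS[Model(small)]
            rows.append(dict(subject_id=subject, timepoint=tp,
                             nested_pair=f"{small}<{big}", d=d, df=df,
                             significant=bool(stats.chi2.sf(d, df) < 0.05)))
    lrt = pd.DataFrame(rows)
    lrt.to_csv(OUT / "lrt.csv", index=False)
    report.mean_bic.to_csv(OUT / "mean_bic.csv")
    report.mean_pseudo_r2.to_csv(OUT / "mean_pseudo_r2.csv")

    print("per-subject LRT: share significant (p < 0.05) by nested pair")
    print(lrt.groupby("nested_pair")["significant"].mean().round(2).to_string())
    print("\nmean BIC by cohort cell (larger = better):")
    print(report.mean_bic.round(2).to_string())
    print(f"\nselected model on {report.primary_subset}: {report.selected_model}")


if __name__ == "__main__":
    main()
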