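"""Response stratification: DCR/SCR composition of the longitudinal
categories (double-negative / clearance / residual-positive), Kaplan-Meier
medians, and the integrated Group A/B comparison.

Reads scratch/cohort/clinical.csv and results/pipeline/longitudinal.tsv,
writes results/survival_stratification.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cfmon.outcomes import cox_fit, dichotomize_response, km_logrank

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    clinical = pd.read_csv(ROOT / "scratch" / "cohort" / "clinical.csv")
    longitudinal = pd.read_csv(
        ROOT / "results" / "pipeline" / "longitudinal.tsv", sep="\t")
    df = clinical.merge(longitudinal, on="subject_id")
    df["response"] = [dichotomize_response(t, e) for t, e
                      in zip(df["pfs_months"], df["pfs_event"])]

    print("response by longitudinal category:")
    print(pd.crosstab(df["category"], df["response"]))

    rows = []
    for label, col in [("residual_ctdna_cycle4", "cycle4_residual"),
                       ("group_b", "group_ab")]:
        sub = df.copy()
        if col == "group_ab":
            sub = sub[sub["group_ab"].isin(["A", "B"])]
            sub["_flag"] = (sub["group_ab"] == "B").astype(int)
        else:
            sub["_flag"] = sub[col].astype(int)
        if sub["_flag"].nunique() < 2:
            continue
        fit = cox_fit(sub["pfs_months"], sub["pfs_event"], sub[["_flag"]],
                      grouping=label)
        lr = km_logrank(sub["pfs_months"], sub["pfs_event"], sub["_flag"])
        medians = {g: curve.attrs["median"]
                   for g, curve in lr["curves"].items()}
        rows.append({"grouping": label, "endpoint": "PFS",
                     "hr": fit.hazard_ratio, "ci_low": fit.ci95[0],
                     "ci_high": fit.ci95[1], "cox_p": fit.p_value,
                     "logrank_p": lr["p"],
                     "median_pfs_neg": medians.get("0"),
                     "median_pfs_pos": medians.get("1")})
    fits = pd.DataFrame(rows)
    out = ROOT / "results" / "survival_stratification.tsv"
    fits.to_csv(out, sep="\t", index=False)
    print(fits.to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
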