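"""Clinical associations and survival of the called subtypes.

Reports triple-negative enrichment of claudin-low tumors (chi-square),
pathological complete response of claudin-low vs basal-like tumors (Fisher
exact), relapse-free survival of claudin-low vs luminal A (Kaplan-Meier,
log-rank, Cox hazard ratio), and the prognostic value of the differentiation
score split (cohort-stratified Cox).
"""

import pandas as pd
from _common import outdir, test_config, train_config

from claudinlow.diffscore import (
    compute_differentiation_scores,
    dichotomize_scores,
    fit_differentiation_model,
)
from claudinlow.expression import normalize_matrix
from claudinlow.survival import chi2_2x2, cox_ph, fisher_exact_2x2, km_logrank
from claudinlow.synthetic import generate_sorted_populations, generate_tumor_cohort


def main() -> None:
    out = outdir("clinical")
    expr, clinical, labels = generate_tumor_cohort(test_config(), "TEST")

    tn = (clinical[["er", "pr", "her2"]] == 0).all(axis=1)
    is_cl = labels == "ClaudinLow"
    table = [
        [int((is_cl & tn).sum()), int((is_cl & ~tn).sum())],
        [int((~is_cl & tn).sum()), int((~is_cl & ~tn).sum())],
    ]
    chi2, p = chi2_2x2(table)
    print(f"triple-negative: {100 * tn[is_cl].mean():.0f}% of claudin-low vs "
          f"{100 * tn[~is_cl].mean():.0f}% of others (chi2={chi2:.2f}, p={p:.2g})")

    cl_pcr = clinical.loc[is_cl, "pcr"]
    bl_pcr = clinical.loc[labels == "Basal", "pcr"]
    fisher_p = fisher_exact_2x2([
        [int(cl_pcr.sum()), int((1 - cl_pcr).sum())],
        [int(bl_pcr.sum()), int((1 - bl_pcr).sum())],
    ])
    print(f"pCR: claudin-low {100 * cl_pcr.mean():.1f}% vs basal-like "
          f"{100 * bl_pcr.mean():.1f}% (Fisher p={fisher_p:.2g})")

    keep = labels.isin(["ClaudinLow", "LumA"])
    sub = clinical.loc[keep.index[keep]]
    curves, lr_chi2, lr_p = km_logrank(
        sub["rfs_time"], sub["rfs_event"], labels.loc[sub.index]
    )
    cl_vs_la = cox_ph(
        sub["rfs_time"], sub["rfs_event"],
        pd.DataFrame({"claudinlow": (labels.loc[sub.index] == "ClaudinLow").astype(float)}),
    )
    hr = cl_vs_la.loc["claudinlow"]
    print(f"RFS claudin-low vs luminal A: HR {hr['hr']:.2f} "
          f"(95% CI {hr['hr_lower']:.2f}-{hr['hr_upper']:.2f}), "
          f"log-rank p={lr_p:.2g}")
    cl_vs_la.to_csv(out / "cox_claudinlow_vs_luma.tsv", sep="\t",
                    float_format="%.4g")

    # differentiation-score split, stratified by cohort
    pops, pop_labels = generate_sorted_populations(train_config())
    groups = {p: pops[pop_labels.index[pop_labels == p]] for p in ("MaSC", "pL", "mL")}
    model = fit_differentiation_model(groups["MaSC"], groups["pL"], groups["mL"])
    scores = compute_differentiation_scores(model, normalize_matrix(expr))
    split = dichotomize_scores(scores["score"])
    cox_split = cox_ph(
        clinical.loc[split.index, "rfs_time"],
        clinical.loc[split.index, "rfs_event"],
        pd.DataFrame({"low_diff": (split == "low").astype(float)}),
        strata=clinical.loc[split.index, "cohort"],
    )
    cox_split.to_csv(out / "cox_differentiation_split.tsv", sep="\t",
                     float_format="%.4g")
    hr2 = cox_split.loc["low_diff"]
    print(f"RFS low vs high differentiation: HR {hr2['hr']:.2f} "
          f"(95% CI {hr2['hr_lower']:.2f}-{hr2['hr_upper']:.2f}, p={hr2['p']:.2g})")


if __name__ == "__main__":
    main()
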