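"""Train and evaluate the claudin-low and normal-breast centroid predictors.

SAM (two-class, unpaired) selects genes separating claudin-low tumors from
all others at FDR < 5% (and normal-like tissue from tumors at FDR 0%);
Euclidean centroids built on those genes classify a held-out cohort, and the
binary claudin-low predictor is scored against the generating labels.
"""

import pandas as pd
from _common import SEED, outdir, test_config, train_config

from claudinlow.centroid import (
    build_centroid_model,
    calls_to_frame,
    classify_nearest_centroid,
    evaluate_binary_predictor,
)
from claudinlow.expression import normalize_matrix
from claudinlow.sam import sam_fdr_select
from claudinlow.synthetic import generate_tumor_cohort


def main() -> None:
    out = outdir("predictor")
    train_expr, _, train_labels = generate_tumor_cohort(train_config(), "TRAIN")
    test_expr, _, test_labels = generate_tumor_cohort(test_config(), "TEST")
    train_norm = normalize_matrix(train_expr)
    test_norm = normalize_matrix(test_expr)

    cl_sam = sam_fdr_select(
        train_norm, (train_labels == "ClaudinLow").astype(int),
        fdr_target=0.05, n_permutations=200, seed=SEED,
    )
    print(f"claudin-low SAM: {len(cl_sam.up_genes)} up / "
          f"{len(cl_sam.down_genes)} down genes at FDR<=5% "
          f"(s0={cl_sam.s0:.3f}, delta={cl_sam.delta:.3f})")
    cl_sam.to_json(out / "claudinlow_sam.json")

    nl_sam = sam_fdr_select(
        train_norm, (train_labels == "NormalLike").astype(int),
        fdr_target=0.0, n_permutations=200, seed=SEED + 1,
    )
    print(f"normal-breast SAM: {len(nl_sam.up_genes)} up / "
          f"{len(nl_sam.down_genes)} down genes at FDR 0%")
    nl_sam.to_json(out / "normal_sam.json")

    model = build_centroid_model(
        train_norm, train_labels.where(train_labels == "ClaudinLow", "others"),
        gene_ids=cl_sam.up_genes + cl_sam.down_genes, tie_class="others",
    )
    model.to_json(out / "claudinlow_model.json")

    calls = classify_nearest_centroid(model, test_norm)
    calls_to_frame(calls).to_csv(out / "heldout_calls.tsv", sep="\t",
                                 float_format="%.8g")
    pred = pd.Series({c.sample_id: c.call == "ClaudinLow" for c in calls})
    ev = evaluate_binary_predictor(pred, test_labels == "ClaudinLow")
    print(
        "held-out claudin-low predictor: "
        f"sensitivity {ev['sensitivity_pct']}%, specificity {ev['specificity_pct']}%, "
        f"PPV {ev['ppv_pct']}%, NPV {ev['npv_pct']}% "
        f"(TP={ev['tp']} FP={ev['fp']} FN={ev['fn']} TN={ev['tn']})"
    )


if __name__ == "__main__":
    main()
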