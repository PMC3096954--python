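"""Simulate the synthetic study cohorts.

Generates the training and held-out tumor cohorts (six intrinsic subtypes,
module-structured expression plus immune/stromal contamination and clinical
outcomes), the contamination-free cell-line panel, and the FACS-sorted
mammary populations; writes everything as TSV under results/data/.
"""

from _common import outdir, test_config, train_config

from claudinlow.expression import write_expression_tsv
from claudinlow.synthetic import (
    generate_cell_line_panel,
    generate_sorted_populations,
    generate_tumor_cohort,
)


def main() -> None:
    out = outdir("data")
    for tag, cfg in (("train", train_config()), ("test", test_config())):
        expr, clinical, labels = generate_tumor_cohort(cfg, cohort=tag.upper())
        write_expression_tsv(expr, out / f"{tag}_expression.tsv")
        clinical.to_csv(out / f"{tag}_clinical.tsv", sep="\t")
        labels.rename("label").to_csv(out / f"{tag}_labels.tsv", sep="\t")
        counts = labels.value_counts().to_dict()
        print(f"{tag} cohort: {expr.shape[0]} genes x {expr.shape[1]} tumors {counts}")

    lines, line_labels = generate_cell_line_panel(train_config())
    write_expression_tsv(lines, out / "cell_lines.tsv")
    line_labels.rename("label").to_csv(out / "cell_line_labels.tsv", sep="\t")
    print(f"cell-line panel: {lines.shape[1]} lines, "
          f"{(line_labels == 'ClaudinLow').sum()} claudin-low")

    pops, pop_labels = generate_sorted_populations(train_config())
    write_expression_tsv(pops, out / "sorted_populations.tsv")
    pop_labels.rename("label").to_csv(out / "population_labels.tsv", sep="\t")
    print(f"sorted populations: {pop_labels.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
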