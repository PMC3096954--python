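"""End-to-end synthetic analysis pipeline.

Stage order mirrors the analysis workflow: simulate a cohort, preprocess,
train the claudin-low and normal-breast centroid predictors (SAM gene
selection + Euclidean centroids), classify a held-out cohort with the
claudin-low override rule, score gene signatures, fit the differentiation
axis and score/dichotomize samples, and run the clinical association and
survival statistics.  Every number written to the report is recomputable by
calling the corresponding library function on the intermediate files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centroid, diffscore, dwd, sam, signatures, survival, synthetic
from .expression import GeneSignature, normalize_matrix, write_expression_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    sam_fdr: float = 0.05
    normal_sam_fdr: float = 0.0
    n_permutations: int = 200
    dwd: dwd.DwdConfig = field(default_factory=dwd.DwdConfig)

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = synthetic.SyntheticConfig(seed=self.seed)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            p = json.load(fh)
        syn = p.pop("synthetic", None)
        dwd_cfg = p.pop("dwd", None)
        cfg = cls(**p)
        if syn is not None:
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if dwd_cfg is not None:
            cfg.dwd = dwd.DwdConfig(**dwd_cfg)
        return cfg


def _derived_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _module_signatures(cfg: synthetic.SyntheticConfig) -> list[GeneSignature]:
    mods = synthetic.gene_modules(cfg)
    return [
        GeneSignature(name=m, gene_ids=tuple(mods[m]))
        for m in synthetic.MODULES
    ]


@_stage("simulate")
def _simulate(cfg: PipelineConfig, out: Path):
    syn_train = dataclasses.replace(cfg.synthetic, seed=_derived_seed(cfg.seed, 10))
    syn_test = dataclasses.replace(cfg.synthetic, seed=_derived_seed(cfg.seed, 11))
    train_expr, train_clin, train_labels = synthetic.generate_tumor_cohort(syn_train, "TRAIN")
    test_expr, test_clin, test_labels = synthetic.generate_tumor_cohort(syn_test, "TEST")
    pops_expr, pops_labels = synthetic.generate_sorted_populations(syn_train)
    write_expression_tsv(train_expr, out / "train_expression.tsv")
    write_expression_tsv(test_expr, out / "test_expression.tsv")
    write_expression_tsv(pops_expr, out / "sorted_populations.tsv")
    train_clin.to_csv(out / "train_clinical.tsv", sep="\t")
    test_clin.to_csv(out / "test_clinical.tsv", sep="\t")
    train_labels.rename("label").to_csv(out / "train_labels.tsv", sep="\t")
    test_labels.rename("label").to_csv(out / "test_labels.tsv", sep="\t")
    pops_labels.rename("label").to_csv(out / "population_labels.tsv", sep="\t")
    return (train_expr, train_clin, train_labels, test_expr, test_clin, test_labels,
            pops_expr, pops_labels)


@_stage("train_predictors")
def _train(cfg: PipelineConfig, out: Path, train_norm, train_labels):
    cl_binary = (train_labels == "ClaudinLow").astype(int)
    cl_sam = sam.sam_fdr_select(
        train_norm,
        cl_binary,
        fdr_target=cfg.sam_fdr,
        n_permutations=cfg.n_permutations,
        seed=_derived_seed(cfg.seed, 20),
    )
    cl_genes = cl_sam.up_genes + cl_sam.down_genes
    cl_model = centroid.build_centroid_model(
        train_norm,
        train_labels.where(train_labels == "ClaudinLow", "others"),
        gene_ids=cl_genes,
        metric="euclidean",
        tie_class="others",
        training_provenance="synthetic training cohort, SAM-selected genes",
    )
    nl_binary = (train_labels == "NormalLike").astype(int)
    nl_sam = sam.sam_fdr_select(
        train_norm,
        nl_binary,
        fdr_target=cfg.normal_sam_fdr,
        n_permutations=cfg.n_permutations,
        seed=_derived_seed(cfg.seed, 21),
    )
    nl_genes = nl_sam.up_genes + nl_sam.down_genes
    nl_model = centroid.build_centroid_model(
        train_norm,
        train_labels.where(train_labels == "NormalLike", "tumor"),
        gene_ids=nl_genes,
        metric="euclidean",
        tie_class="tumor",
        training_provenance="synthetic training cohort, SAM-selected genes",
    )
    # intrinsic-list centroids: restrict to the structured modules (plus the
    # HER2 marker), mirroring how published subtype predictors use a curated
    # gene list rather than the whole array
    modules = synthetic.gene_modules(cfg.synthetic)
    intrinsic = [g for name, ids in modules.items() if name != "null" for g in ids]
    primary_model = centroid.build_centroid_model(
        train_norm,
        train_labels,
        gene_ids=[g for g in intrinsic if g in train_norm.index],
        metric="spearman",
        training_provenance="synthetic 6-class intrinsic centroids",
    )
    cl_sam.to_json(out / "claudinlow_sam.json")
    nl_sam.to_json(out / "normal_sam.json")
    cl_model.to_json(out / "claudinlow_model.json")
    nl_model.to_json(out / "normal_model.json")
    primary_model.to_json(out / "primary_model.json")
    return cl_model, nl_model, primary_model, cl_sam, nl_sam


@_stage("classify")
def _classify(out: Path, cl_model, primary_model, test_norm, test_labels):
    cl_calls = centroid.classify_nearest_centroid(cl_model, test_norm)
    primary_calls = centroid.classify_nearest_centroid(primary_model, test_norm)
    cl_flag = pd.Series(
        {c.sample_id: c.call == "ClaudinLow" for c in cl_calls}, name="claudinlow"
    )
    primary = pd.Series({c.sample_id: c.call for c in primary_calls}, name="primary")
    final = centroid.combine_subtype_calls(primary, cl_flag)
    frame = centroid.calls_to_frame(cl_calls)
    frame["primary_call"] = primary
    frame["final_call"] = final
    frame.to_csv(out / "subtype_calls.tsv", sep="\t", float_format="%.8g")
    evaluation = centroid.evaluate_binary_predictor(
        cl_flag, (test_labels == "ClaudinLow")
    )
    return final, cl_flag, evaluation


@_stage("signatures")
def _signatures(cfg: PipelineConfig, out: Path, test_norm, final_calls):
    sigs = _module_signatures(cfg.synthetic)
    scores = signatures.score_signatures(test_norm, sigs)
    scores.to_csv(out / "signature_scores.tsv", sep="\t", float_format="%.8g")
    tests = {}
    for sig in sigs:
        f, p = signatures.compare_subtype_means(
            scores[sig.name], final_calls, test="anova"
        )
        tests[sig.name] = {"anova_F": f, "p": p}
    return scores, tests


@_stage("differentiation")
def _differentiation(cfg: PipelineConfig, out: Path, pops_expr, pops_labels, test_norm,
                     test_clin):
    groups = {
        name: pops_expr[pops_labels.index[pops_labels == name]]
        for name in ("MaSC", "pL", "mL")
    }
    model = diffscore.fit_differentiation_model(
        groups["MaSC"], groups["pL"], groups["mL"], cfg.dwd
    )
    model.to_json(out / "differentiation_model.json")
    scores = diffscore.compute_differentiation_scores(model, test_norm)
    groups_split = diffscore.dichotomize_scores(scores["score"])
    scores["diff_group"] = groups_split
    scores.to_csv(out / "differentiation_scores.tsv", sep="\t", float_format="%.8g")
    clin = test_clin.loc[scores.index]
    _, lr_chi2, lr_p = survival.km_logrank(
        clin["rfs_time"], clin["rfs_event"], groups_split.loc[clin.index]
    )
    cox = survival.cox_ph(
        clin["rfs_time"],
        clin["rfs_event"],
        pd.DataFrame({"low_diff": (groups_split.loc[clin.index] == "low").astype(float)}),
        strata=clin["cohort"],
    )
    return model, scores, {
        "logrank_chi2": lr_chi2,
        "logrank_p": lr_p,
        "cox_low_vs_high_hr": float(cox.loc["low_diff", "hr"]),
        "cox_p": float(cox.loc["low_diff", "p"]),
    }


@_stage("clinical_associations")
def _associations(test_clin, final_calls):
    clin = test_clin.loc[final_calls.index]
    tn = ((clin["er"] == 0) & (clin["pr"] == 0) & (clin["her2"] == 0)).astype(int)
    is_cl = (final_calls == "ClaudinLow").astype(int)
    table_tn = [
        [int(((is_cl == 1) & (tn == 1)).sum()), int(((is_cl == 1) & (tn == 0)).sum())],
        [int(((is_cl == 0) & (tn == 1)).sum()), int(((is_cl == 0) & (tn == 0)).sum())],
    ]
    chi2, chi2_p = survival.chi2_2x2(table_tn)
    cl_pcr = clin.loc[final_calls == "ClaudinLow", "pcr"]
    bl_pcr = clin.loc[final_calls == "Basal", "pcr"]
    table_pcr = [
        [int(cl_pcr.sum()), int((1 - cl_pcr).sum())],
        [int(bl_pcr.sum()), int((1 - bl_pcr).sum())],
    ]
    fisher_p = survival.fisher_exact_2x2(table_pcr)
    out = {
        "triple_negative_table": table_tn,
        "triple_negative_chi2": chi2,
        "triple_negative_chi2_p": chi2_p,
        "pcr_table_cl_vs_basal": table_pcr,
        "pcr_fisher_p": fisher_p,
    }
    if len(cl_pcr):
        out["pcr_rate_claudinlow_pct"] = round(100.0 * cl_pcr.mean(), 1)
    if len(bl_pcr):
        out["pcr_rate_basal_pct"] = round(100.0 * bl_pcr.mean(), 1)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic analysis; returns the JSON-ready summary.

    All stage outputs (expression/clinical TSVs, model JSONs, call and score
    tables, the summary itself) land under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (train_expr, train_clin, train_labels, test_expr, test_clin, test_labels,
     pops_expr, pops_labels) = _simulate(cfg, out)
    train_norm = normalize_matrix(train_expr)
    test_norm = normalize_matrix(test_expr)
    write_expression_tsv(train_norm, out / "train_expression_normalized.tsv")
    write_expression_tsv(test_norm, out / "test_expression_normalized.tsv")

    cl_model, nl_model, primary_model, cl_sam, nl_sam = _train(
        cfg, out, train_norm, train_labels
    )
    final, cl_flag, evaluation = _classify(out, cl_model, primary_model, test_norm,
                                           test_labels)
    _, sig_tests = _signatures(cfg, out, test_norm, final)
    _, _, diff_stats = _differentiation(cfg, out, pops_expr, pops_labels, test_norm,
                                        test_clin)
    assoc = _associations(test_clin, final)

    accuracy = float((final.loc[test_labels.index].eq("ClaudinLow")
                      == test_labels.eq("ClaudinLow")).mean())
    summary = {
        "seed": cfg.seed,
        "n_train": int(train_expr.shape[1]),
        "n_test": int(test_expr.shape[1]),
        "claudinlow_sam_genes": {
            "up": len(cl_sam.up_genes),
            "down": len(cl_sam.down_genes),
        },
        "normal_sam_genes": {"up": len(nl_sam.up_genes), "down": len(nl_sam.down_genes)},
        "claudinlow_predictor_evaluation": evaluation,
        "claudinlow_heldout_accuracy": accuracy,
        "signature_subtype_tests": sig_tests,
        "differentiation": diff_stats,
        "clinical_associations": assoc,
    }
    with open(out / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete; report at %s", out / "report.json")
    return summary
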