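"""Nearest-centroid subtype predictors and predictor evaluation.

Two flavours of centroid classification are supported:

* Euclidean — the claudin-low and normal-breast two-class predictors: a
  class centroid is the per-gene mean over its training samples on a selected
  gene list, and a test sample is assigned the class of the nearest centroid
  in Euclidean distance.
* Spearman — the correlation-to-centroid machinery used for intrinsic
  (PAM50-style) subtyping: a sample is assigned the class whose centroid has
  the highest rank correlation with its profile.  Published centroid values
  can be loaded from JSON; the classification rule itself lives here.

A combined intrinsic call applies the claudin-low override: any sample the
claudin-low predictor flags is called claudin-low regardless of the primary
subtype call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CentroidModel",
    "SubtypeCall",
    "build_centroid_model",
    "classify_nearest_centroid",
    "combine_subtype_calls",
    "evaluate_binary_predictor",
]


@dataclass
class CentroidModel:
    gene_ids: list[str]
    class_names: list[str]
    centroids: pd.DataFrame  # genes x classes
    metric: str = "euclidean"  # "euclidean" | "spearman"
    tie_class: str | None = None  # class awarded on exact ties (conservative)
    training_provenance: str = ""

    def __post_init__(self) -> None:
        if self.metric not in {"euclidean", "spearman"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if list(self.centroids.index) != list(self.gene_ids) or list(
            self.centroids.columns
        ) != list(self.class_names):
            raise ValueError("centroid matrix does not match gene/class lists")
        if self.tie_class is None:
            # default: the last class is the "others"/negative class
            self.tie_class = self.class_names[-1]

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "class_names": list(self.class_names),
            "centroids": {c: self.centroids[c].tolist() for c in self.class_names},
            "metric": self.metric,
            "tie_class": self.tie_class,
            "training_provenance": self.training_provenance,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path, "rt", encoding="utf-8") as fh:
            p = json.load(fh)
        centroids = pd.DataFrame(
            {c: p["centroids"][c] for c in p["class_names"]}, index=p["gene_ids"]
        )
        return cls(
            gene_ids=p["gene_ids"],
            class_names=p["class_names"],
            centroids=centroids,
            metric=p["metric"],
            tie_class=p.get("tie_class"),
            training_provenance=p.get("training_provenance", ""),
        )


@dataclass
class SubtypeCall:
    sample_id: str
    call: str
    statistics: dict[str, float]  # per-class distance (euclidean) or rho (spearman)
    margin: float  # gap to the runner-up class


def build_centroid_model(
    m: pd.DataFrame,
    labels,
    gene_ids=None,
    metric: str = "euclidean",
    tie_class: str | None = None,
    training_provenance: str = "",
) -> CentroidModel:
    """Per-gene class-mean centroids restricted to ``gene_ids``.

    Missing values are ignored in the means; every class must contribute at
    least one training sample.
    """
    labels = pd.Series(labels).loc[list(m.columns)]
    classes = list(pd.unique(labels))
    genes = list(gene_ids) if gene_ids is not None else list(m.index)
    missing = set(genes) - set(m.index)
    if missing:
        raise ValueError(f"gene_ids not in matrix: {sorted(missing)[:5]}")
    sub = m.loc[genes]
    cols = {}
    for c in classes:
        members = labels.index[labels == c]
        if len(members) == 0:
            raise ValueError(f"class {c!r} has no training samples")
        cols[c] = sub[members].mean(axis=1, skipna=True)
    centroids = pd.DataFrame(cols)[classes]
    return CentroidModel(
        gene_ids=genes,
        class_names=classes,
        centroids=centroids,
        metric=metric,
        tie_class=tie_class,
        training_provenance=training_provenance,
    )


def classify_nearest_centroid(
    model: CentroidModel, m: pd.DataFrame, min_gene_fraction: float = 0.5
) -> list[SubtypeCall]:
    """Assign each sample the class of the nearest centroid.

    Euclidean metric: distances are computed over the model/matrix gene
    intersection; per-sample missing entries are skipped and the distance is
    rescaled by sqrt(n_model_genes / n_used) to stay comparable across
    samples.  Spearman metric: rank correlation to each centroid, argmax
    wins.  Exact ties go to ``model.tie_class`` when it is among the tied
    classes (claudin-low must be a positive finding, never a tie award).
    """
    common = [g for g in model.gene_ids if g in m.index]
    frac = len(common) / len(model.gene_ids)
    if frac < min_gene_fraction:
        absent = [g for g in model.gene_ids if g not in m.index]
        raise ValueError(
            f"only {frac:.0%} of model genes present (need >= {min_gene_fraction:.0%}); "
            f"missing e.g. {absent[:5]}"
        )
    sub = m.loc[common]
    cents = model.centroids.loc[common]
    n_model = len(model.gene_ids)

    calls: list[SubtypeCall] = []
    for sample in sub.columns:
        x = sub[sample].to_numpy(dtype=float)
        ok = np.isfinite(x)
        per_class: dict[str, float] = {}
        for c in model.class_names:
            mu = cents[c].to_numpy(dtype=float)
            use = ok & np.isfinite(mu)
            if use.sum() == 0:
                raise ValueError(f"sample {sample!r}: no usable genes for class {c!r}")
            if model.metric == "euclidean":
                d = float(np.sqrt(np.sum((x[use] - mu[use]) ** 2)))
                per_class[c] = d * np.sqrt(n_model / use.sum())
            else:
                rho = stats.spearmanr(x[use], mu[use]).statistic
                per_class[c] = float(rho)
        vals = np.array([per_class[c] for c in model.class_names])
        best = vals.min() if model.metric == "euclidean" else vals.max()
        tied = [c for c, v in zip(model.class_names, vals) if v == best]
        if len(tied) > 1 and model.tie_class in tied:
            call = model.tie_class
        else:
            call = tied[0]
        rest = np.sort(np.abs(vals - best))
        margin = float(rest[1]) if len(vals) > 1 else np.inf
        calls.append(SubtypeCall(sample_id=sample, call=call, statistics=per_class, margin=margin))
    return calls


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (sample_id index, call, per-class stats, margin)."""
    rows = []
    for c in calls:
        row = {"call": c.call, "margin": c.margin}
        row.update({f"stat_{k}": v for k, v in c.statistics.items()})
        rows.append(pd.Series(row, name=c.sample_id))
    return pd.DataFrame(rows)


def combine_subtype_calls(
    primary_calls: pd.Series, claudinlow_positive: pd.Series, label: str = "ClaudinLow"
) -> pd.Series:
    """Final subtype labels with the claudin-low override.

    Samples flagged by the claudin-low predictor are called claudin-low
    regardless of the primary (PAM50-style) call; all others keep their
    primary label.
    """
    primary = pd.Series(primary_calls)
    flag = pd.Series(claudinlow_positive).astype(bool)
    if set(primary.index) != set(flag.index):
        raise ValueError("primary and claudin-low call sample sets differ")
    flag = flag.loc[primary.index]
    out = primary.copy()
    out[flag] = label
    return out


def evaluate_binary_predictor(predicted, gold) -> dict:
    """Sensitivity, specificity, PPV and NPV of a binary predictor (percent).

    Undefined ratios (zero denominator) are reported as ``None`` rather
    than 0.  Percentages are rounded to one decimal in the ``*_pct`` keys.
    """
    pred = pd.Series(predicted).astype(bool)
    gd = pd.Series(gold).astype(bool)
    if set(pred.index) != set(gd.index):
        raise ValueError("predicted and gold sample sets differ")
    gd = gd.loc[pred.index]
    tp = int((pred & gd).sum())
    fp = int((pred & ~gd).sum())
    fn = int((~pred & gd).sum())
    tn = int((~pred & ~gd).sum())

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    out = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity_pct": None if sens is None else round(sens, 1),
        "specificity_pct": None if spec is None else round(spec, 1),
        "ppv_pct": None if ppv is None else round(ppv, 1),
        "npv_pct": None if npv is None else round(npv, 1),
    }
    return out
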