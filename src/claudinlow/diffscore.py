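"""Mammary differentiation scoring along the MaSC -> pL -> mL axis.

The model is trained on purified mammary epithelial populations — mammary
stem cells (MaSC), luminal progenitors (pL) and mature luminal cells (mL).
Genes are median-centered across the pooled training populations, the pL
centroid becomes the origin, and DWD supplies the directions of greatest
variation MaSC-ward and mL-ward; both directions are unit-normalised
(sum of squares equals 1).

To score a test cohort (which is assumed to cover the range of
differentiation), genes are median-centered within the test set to correct
for platform bias, each sample is shifted so that pL sits at the origin and
scaled to unit length, and its inner products with the MaSC and mL vectors
give two projected positions.  The differentiation score is

    score = proj_mL - proj_MaSC

so that higher scores mean greater (mature-luminal-ward) differentiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwd import DwdConfig, dwd_direction

__all__ = [
    "DifferentiationModel",
    "fit_differentiation_model",
    "compute_differentiation_scores",
    "dichotomize_scores",
]


@dataclass
class DifferentiationModel:
    gene_ids: list[str]
    pl_centroid: np.ndarray  # origin, in training median-centered space
    masc_vector: np.ndarray  # unit vector, pL -> MaSC
    ml_vector: np.ndarray  # unit vector, pL -> mL
    training_medians: np.ndarray  # per-gene training medians

    def __post_init__(self) -> None:
        for name in ("masc_vector", "ml_vector"):
            v = getattr(self, name)
            if not np.isclose(v @ v, 1.0, atol=1e-8):
                raise ValueError(f"{name} is not unit length")

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "pl_centroid": self.pl_centroid.tolist(),
            "masc_vector": self.masc_vector.tolist(),
            "ml_vector": self.ml_vector.tolist(),
            "training_medians": self.training_medians.tolist(),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DifferentiationModel":
        with open(path, "rt", encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            gene_ids=p["gene_ids"],
            pl_centroid=np.asarray(p["pl_centroid"], dtype=float),
            masc_vector=np.asarray(p["masc_vector"], dtype=float),
            ml_vector=np.asarray(p["ml_vector"], dtype=float),
            training_medians=np.asarray(p["training_medians"], dtype=float),
        )


def fit_differentiation_model(
    masc: pd.DataFrame,
    pl: pd.DataFrame,
    ml: pd.DataFrame,
    cfg: DwdConfig | None = None,
) -> DifferentiationModel:
    """Fit the differentiation axis from MaSC, pL and mL expression matrices.

    All three matrices must share a gene space; genes are aligned on the
    intersection (in MaSC order).  The pooled training medians are stored so
    the origin is expressed in median-centered coordinates.
    """
    for name, pop in (("MaSC", masc), ("pL", pl), ("mL", ml)):
        if pop.shape[1] == 0:
            raise ValueError(f"population {name} has no samples")
    genes = [g for g in masc.index if g in pl.index and g in ml.index]
    if not genes:
        raise ValueError("no common genes across the three populations")
    pooled = pd.concat([masc.loc[genes], pl.loc[genes], ml.loc[genes]], axis=1)
    medians = pooled.median(axis=1, skipna=True)
    masc_c = masc.loc[genes].sub(medians, axis=0)
    pl_c = pl.loc[genes].sub(medians, axis=0)
    ml_c = ml.loc[genes].sub(medians, axis=0)

    pl_centroid = pl_c.mean(axis=1, skipna=True).to_numpy(dtype=float)
    masc_vec = dwd_direction(pl_c, masc_c, cfg)  # oriented pL -> MaSC
    ml_vec = dwd_direction(pl_c, ml_c, cfg)  # oriented pL -> mL
    return DifferentiationModel(
        gene_ids=genes,
        pl_centroid=pl_centroid,
        masc_vector=masc_vec,
        ml_vector=ml_vec,
        training_medians=medians.to_numpy(dtype=float),
    )


def compute_differentiation_scores(
    model: DifferentiationModel, m: pd.DataFrame, min_gene_fraction: float = 0.5
) -> pd.DataFrame:
    """Project test samples onto the differentiation axis.

    Per sample: (1) genes median-centered across the test set; (2) pL origin
    subtracted; (3) the sample vector rescaled to unit length (a zero vector
    is left as zero); (4) inner products with the MaSC and mL directions;
    (5) score = proj_ml - proj_masc.  Missing entries are treated as zero
    after centering (that is, they contribute nothing to the projections).

    Returns a DataFrame indexed by sample with proj_masc, proj_ml, score.
    """
    common = [g for g in model.gene_ids if g in m.index]
    frac = len(common) / len(model.gene_ids)
    if frac < min_gene_fraction:
        raise ValueError(
            f"only {frac:.0%} of model genes present (need >= {min_gene_fraction:.0%})"
        )
    idx = [model.gene_ids.index(g) for g in common]
    sub = m.loc[common]
    centered = sub.sub(sub.median(axis=1, skipna=True), axis=0)
    origin = model.pl_centroid[idx]
    masc_v = model.masc_vector[idx]
    ml_v = model.ml_vector[idx]

    rows = {}
    for sample in centered.columns:
        x = centered[sample].to_numpy(dtype=float) - origin
        x = np.where(np.isfinite(x), x, 0.0)
        norm = np.linalg.norm(x)
        if norm > 0:
            x = x / norm
        pm = float(x @ masc_v)
        pl_ = float(x @ ml_v)
        rows[sample] = {"proj_masc": pm, "proj_ml": pl_, "score": pl_ - pm}
    return pd.DataFrame.from_dict(rows, orient="index")


def dichotomize_scores(scores: pd.Series) -> pd.Series:
    """Rank-order samples and split them into two equal groups.

    The lower half is labelled ``"low"`` (low differentiation) and the upper
    half ``"high"``; with an odd sample count the extra sample goes to the
    low group.  Ties are broken by stable input order.
    """
    s = pd.Series(scores)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    order = np.argsort(s.to_numpy(), kind="stable")
    n_low = (len(s) + 1) // 2
    groups = pd.Series("high", index=s.index, name="diff_group")
    groups.iloc[order[:n_low]] = "low"
    return groups
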