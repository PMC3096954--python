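"""Gene-signature scoring and correlation dendrograms.

Signature scores are plain mean expression of the signature's genes per
sample (signed signatures: mean(up) - mean(down)) — the convention used for
immune, stromal and stem-cell signatures in intrinsic-subtype work.

Dendrograms use average-linkage agglomerative clustering on the distance
1 - r, with r the centered Pearson correlation; the "node correlation" of an
internal node is 1 minus its merge height, and gene clusters (e.g. the
proliferation or luminal cluster) are picked as the largest subtree around an
anchor gene whose node correlation exceeds a threshold (the classic
hand-picking rule, node correlation > 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import GeneSignature

__all__ = [
    "Dendrogram",
    "score_signatures",
    "average_linkage_dendrogram",
    "extract_cluster_by_node_correlation",
    "compare_subtype_means",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes or samples.

    ``merges`` follows the scipy linkage convention: row k merges nodes
    ``left`` and ``right`` (ids < n are leaves) into node ``n + k``;
    ``node_correlation`` = 1 - merge height.
    """

    leaf_ids: list[str]
    merges: pd.DataFrame  # columns: node_id, left, right, height, node_correlation

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves must have n-1 internal nodes")

    def leaves_under(self, node_id: int) -> list[str]:
        n = len(self.leaf_ids)
        if node_id < n:
            return [self.leaf_ids[node_id]]
        out: list[str] = []
        stack = [node_id]
        rows = self.merges.set_index("node_id")
        while stack:
            nid = stack.pop()
            if nid < n:
                out.append(self.leaf_ids[nid])
            else:
                row = rows.loc[nid]
                stack.extend([int(row["left"]), int(row["right"])])
        return out

    def to_tsv(self, path) -> None:
        self.merges.to_csv(path, sep="\t", index=False, float_format="%.8g")


def score_signatures(m: pd.DataFrame, sigs: list[GeneSignature]) -> pd.DataFrame:
    """Mean-expression signature scores, samples x signatures.

    Unsigned/up signatures: arithmetic mean of the signature genes present in
    the matrix (non-missing values).  Signed signatures: mean(up genes) -
    mean(down genes).  A signature with no gene in the matrix is an error.
    """
    out = {}
    for sig in sigs:
        up = [g for g in sig.gene_ids if g in m.index]
        if not up:
            raise ValueError(f"signature {sig.name!r} has no genes in the matrix")
        score = m.loc[up].mean(axis=0, skipna=True)
        if sig.direction in ("signed", "down") or sig.down_gene_ids:
            down = [g for g in sig.down_gene_ids if g in m.index]
            if sig.down_gene_ids and not down:
                raise ValueError(
                    f"signature {sig.name!r}: no down-genes in the matrix"
                )
            if down:
                score = score - m.loc[down].mean(axis=0, skipna=True)
            if sig.direction == "down" and not sig.down_gene_ids:
                score = -score
        out[sig.name] = score
    return pd.DataFrame(out)


def average_linkage_dendrogram(m: pd.DataFrame, over: str = "genes") -> Dendrogram:
    """Average-linkage dendrogram on 1 - Pearson correlation.

    ``over="genes"`` clusters rows, ``over="samples"`` clusters columns.
    Constant items (undefined correlation) raise an error listing them.
    """
    data = m if over == "genes" else m.T
    if over not in {"genes", "samples"}:
        raise ValueError(f"over must be 'genes' or 'samples', got {over!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = [str(i) for i, s in zip(data.index, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise ValueError(f"constant rows have undefined correlation: {constant[:10]}")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    n = data.shape[0]
    merges = pd.DataFrame(
        {
            "node_id": np.arange(n, n + len(Z)),
            "left": Z[:, 0].astype(int),
            "right": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "node_correlation": 1.0 - Z[:, 2],
        }
    )
    return Dendrogram(leaf_ids=[str(i) for i in data.index], merges=merges)


def extract_cluster_by_node_correlation(
    d: Dendrogram, anchor: str, min_corr: float = 0.75
) -> set[str]:
    """Largest subtree containing ``anchor`` whose node correlation > ``min_corr``.

    Returns the subtree's leaf set; if no internal node above the threshold
    contains the anchor, the singleton {anchor} is returned.
    """
    if anchor not in d.leaf_ids:
        raise ValueError(f"anchor {anchor!r} is not a leaf of the dendrogram")
    leaf_idx = d.leaf_ids.index(anchor)
    best: set[str] = {anchor}
    # walk up from the leaf through its ancestors
    parent: dict[int, int] = {}
    for _, row in d.merges.iterrows():
        parent[int(row["left"])] = int(row["node_id"])
        parent[int(row["right"])] = int(row["node_id"])
    corr = dict(zip(d.merges["node_id"].astype(int), d.merges["node_correlation"]))
    node = leaf_idx
    while node in parent:
        node = parent[node]
        if corr[node] > min_corr:
            best = set(d.leaves_under(node))
    return best


def compare_subtype_means(
    scores: pd.Series, groups: pd.Series, test: str = "auto"
) -> tuple[float, float]:
    """Compare score means across groups: Welch t (2 groups) or one-way ANOVA.

    ``test="t"`` forces the two-sided unequal-variance t-test,
    ``test="anova"`` the F-test, ``"auto"`` picks by group count.  A pooled
    -variance t is available as ``test="t_pooled"``.
    """
    s = pd.Series(scores)
    g = pd.Series(groups).loc[s.index]
    arrays = [s[g == lev].to_numpy(dtype=float) for lev in pd.unique(g)]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 samples")
    if test == "auto":
        test = "t" if len(arrays) == 2 else "anova"
    if test in ("t", "t_pooled"):
        if len(arrays) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=(test == "t_pooled"))
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        res = stats.f_oneway(*arrays)
        stat = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(stat):  # zero between-group variance
            stat, p = 0.0, 1.0
        return stat, p
    raise ValueError(f"unknown test {test!r}")
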