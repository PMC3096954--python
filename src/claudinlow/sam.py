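"""Significance analysis of microarrays (SAM), two-class unpaired and paired.

Per gene i the modified t statistic is

    d_i = (mean_class1 - mean_class2) / (s_i + s0)

with ``s_i`` the pooled-variance standard error of the mean difference
(unpaired) or the standard error of the within-pair mean difference (paired),
and ``s0`` a small "fudge factor" that stabilises genes with tiny variance.
``s0`` is chosen automatically as the percentile of {s_i} minimising the
coefficient of variation of the spread of d across bins of s (the classic
procedure), with median(s) as fallback.

The false discovery rate of a symmetric threshold |d| >= delta is estimated
by permuting the class labels (sign-flipping pairs in the paired design):
FDR(delta) = median over permutations of the false count / observed count,
made non-increasing in delta by a step-down pass.  Gene selection returns the
largest gene set whose estimated FDR is at or below the target.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SamResult", "sam_statistics", "sam_fdr_select"]


@dataclass
class SamResult:
    """Outcome of a SAM selection run."""

    d: pd.Series
    s: pd.Series
    s0: float
    delta: float
    fdr_table: pd.DataFrame  # columns: delta, median_false, n_selected, fdr
    up_genes: list[str]
    down_genes: list[str]
    n_permutations: int
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "s0": self.s0,
            "delta": self.delta,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "d": {g: float(v) for g, v in self.d.items()},
            "s": {g: float(v) for g, v in self.s.items()},
            "fdr_table": self.fdr_table.to_dict(orient="list"),
            "up_genes": list(self.up_genes),
            "down_genes": list(self.down_genes),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SamResult":
        with open(path, "rt", encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            d=pd.Series(p["d"]),
            s=pd.Series(p["s"]),
            s0=p["s0"],
            delta=p["delta"],
            fdr_table=pd.DataFrame(p["fdr_table"]),
            up_genes=p["up_genes"],
            down_genes=p["down_genes"],
            n_permutations=p["n_permutations"],
            seed=p["seed"],
        )


def _as_binary(labels, columns) -> np.ndarray:
    y = pd.Series(labels)
    if not y.index.equals(pd.Index(range(len(y)))) and set(columns) <= set(y.index):
        y = y.loc[list(columns)]
    vals = np.asarray(y)
    uniq = pd.unique(vals)
    if len(uniq) != 2:
        raise ValueError(f"labels must have exactly 2 classes, got {list(uniq)}")
    if set(uniq) == {0, 1} or set(uniq) == {False, True}:
        return vals.astype(bool)
    # two arbitrary labels: class1 = the lexicographically larger one
    pos = max(uniq)
    return vals == pos


def _unpaired_num_se(X, mask, y):
    """Vectorized per-gene mean difference and pooled SE for one label vector."""
    Xz = np.where(mask, X, 0.0)
    Xsq = np.where(mask, X * X, 0.0)
    y1 = y.astype(float)
    y0 = (~y).astype(float)
    n1 = mask @ y1
    n0 = mask @ y0
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (Xz @ y1) / n1
        m0 = (Xz @ y0) / n0
        ss1 = (Xsq @ y1) - n1 * m1**2
        ss0 = (Xsq @ y0) - n0 * m0**2
        pooled = (ss1 + ss0) / (n1 + n0 - 2)
        pooled = np.clip(pooled, 0.0, None)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    num = m1 - m0
    return num, se


def _paired_diffs(X, mask, y, pairs):
    pairs = np.asarray(pairs)
    uniq = pd.unique(pairs)
    if len(uniq) == 0:
        raise ValueError("paired design with zero pairs")
    D = np.full((X.shape[0], len(uniq)), np.nan)
    for j, p in enumerate(uniq):
        i1 = np.where((pairs == p) & y)[0]
        i0 = np.where((pairs == p) & ~y)[0]
        if len(i1) != 1 or len(i0) != 1:
            raise ValueError(f"pair {p!r} does not have exactly one sample per class")
        D[:, j] = X[:, i1[0]] - X[:, i0[0]]
    return D


def _paired_num_se(D, mask, signs):
    Dz = np.where(mask, D, 0.0)
    Dsq = np.where(mask, D * D, 0.0)
    n = mask.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (Dz @ signs) / n
        ss = Dsq.sum(axis=1) - n * mean**2
        sd = np.sqrt(np.clip(ss, 0.0, None) / (n - 1))
        se = sd / np.sqrt(n)
    return mean, se


def _auto_s0(num: np.ndarray, s: np.ndarray) -> float:
    """Classic s0 rule: percentile of s minimising the CV of spread(d) over s-bins."""
    ok = np.isfinite(num) & np.isfinite(s)
    num, s = num[ok], s[ok]
    if len(s) == 0:
        return 0.0
    n_bins = int(np.clip(len(s) // 10, 3, 100))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(np.median(s)), np.inf
    for s0 in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / (s + s0)
        spreads = []
        for b in bins:
            db = d[b]
            db = db[np.isfinite(db)]
            if len(db) < 2:
                continue
            spreads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        spreads = np.asarray(spreads)
        if len(spreads) < 2 or np.mean(spreads) == 0:
            continue
        cv = np.std(spreads) / np.mean(spreads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistics(
    m: pd.DataFrame,
    labels,
    design: str = "unpaired",
    s0: float | str = "auto",
    pairs=None,
) -> tuple[pd.Series, pd.Series, float]:
    """Per-gene SAM statistics ``(d, s, s0)``.

    ``labels`` marks class membership per sample (class 1 = truthy value);
    for ``design="paired"``, ``pairs`` gives a pair identifier per sample and
    each pair must contain exactly one sample of each class.
    """
    X = m.to_numpy(dtype=float)
    mask = np.isfinite(X)
    y = _as_binary(labels, m.columns)

    if design == "unpaired":
        if y.sum() < 2 or (~y).sum() < 2:
            raise ValueError("unpaired design needs >= 2 samples per class")
        num, se = _unpaired_num_se(X, mask, y)
    elif design == "paired":
        if pairs is None:
            raise ValueError("paired design requires a pairs vector")
        D = _paired_diffs(X, mask, y, pairs)
        num, se = _paired_num_se(D, np.isfinite(D), np.ones(D.shape[1]))
    else:
        raise ValueError(f"unknown design {design!r}")

    s0_val = _auto_s0(num, se) if s0 == "auto" else float(s0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (se + s0_val)
    d = np.where((se + s0_val) == 0, 0.0, d)  # all-constant gene convention
    d = np.where(np.isfinite(d), d, 0.0)
    return (
        pd.Series(d, index=m.index, name="d"),
        pd.Series(se, index=m.index, name="s"),
        s0_val,
    )


def sam_fdr_select(
    m: pd.DataFrame,
    labels,
    design: str = "unpaired",
    fdr_target: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    pairs=None,
    n_delta: int = 200,
) -> SamResult:
    """Select differential genes at a permutation-estimated FDR target.

    Labels are permuted uniformly at random ``n_permutations`` times (paired
    design: random sign flips of the within-pair differences); for each delta
    on a grid over the observed |d| range, FDR = median permutation false
    count / observed count (step-down monotonised).  Returns the largest gene
    set with estimated FDR <= ``fdr_target``, split by sign of d.
    """
    if not 0.0 <= fdr_target <= 1.0:
        raise ValueError("fdr_target must be in [0, 1]")
    d_obs, s_obs, s0 = sam_statistics(m, labels, design=design, s0="auto", pairs=pairs)
    X = m.to_numpy(dtype=float)
    mask = np.isfinite(X)
    y = _as_binary(labels, m.columns)
    rng = np.random.default_rng(seed)

    abs_obs = np.abs(d_obs.to_numpy())
    dmax = float(abs_obs.max()) if len(abs_obs) else 0.0
    grid = np.linspace(dmax / n_delta, dmax, n_delta) if dmax > 0 else np.array([0.0])

    obs_sorted = np.sort(abs_obs)
    n_genes = len(abs_obs)
    observed_counts = n_genes - np.searchsorted(obs_sorted, grid, side="left")

    false_counts = np.empty((n_permutations, len(grid)), dtype=float)
    if design == "unpaired":
        for p in range(n_permutations):
            yp = rng.permutation(y)
            num, se = _unpaired_num_se(X, mask, yp)
            with np.errstate(invalid="ignore", divide="ignore"):
                dp = num / (se + s0)
            dp = np.where(np.isfinite(dp), dp, 0.0)
            sorted_abs = np.sort(np.abs(dp))
            false_counts[p] = n_genes - np.searchsorted(sorted_abs, grid, side="left")
    else:
        D = _paired_diffs(X, mask, y, pairs)
        Dmask = np.isfinite(D)
        for p in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=D.shape[1])
            num, se = _paired_num_se(D, Dmask, signs)
            with np.errstate(invalid="ignore", divide="ignore"):
                dp = num / (se + s0)
            dp = np.where(np.isfinite(dp), dp, 0.0)
            sorted_abs = np.sort(np.abs(dp))
            false_counts[p] = n_genes - np.searchsorted(sorted_abs, grid, side="left")

    median_false = np.median(false_counts, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr_raw = np.where(observed_counts > 0, median_false / observed_counts, 0.0)
    fdr_raw = np.clip(fdr_raw, 0.0, 1.0)
    # conservative step-down: FDR non-increasing as delta grows
    fdr = np.maximum.accumulate(fdr_raw[::-1])[::-1]

    table = pd.DataFrame(
        {
            "delta": grid,
            "median_false": median_false,
            "n_selected": observed_counts,
            "fdr": fdr,
        }
    )
    qualifying = np.where(fdr <= fdr_target)[0]
    if len(qualifying) == 0 or observed_counts[qualifying[0]] == 0:
        warnings.warn(
            f"no delta reaches FDR target {fdr_target}; returning empty gene lists",
            stacklevel=2,
        )
        delta_sel = float(grid[-1])
        up, down = [], []
    else:
        i = qualifying[0]
        delta_sel = float(grid[i])
        selected = np.abs(d_obs.to_numpy()) >= delta_sel
        dv = d_obs.to_numpy()
        up = list(m.index[selected & (dv > 0)])
        down = list(m.index[selected & (dv < 0)])

    return SamResult(
        d=d_obs,
        s=s_obs,
        s0=s0,
        delta=delta_sel,
        fdr_table=table,
        up_genes=up,
        down_genes=down,
        n_permutations=n_permutations,
        seed=seed,
    )
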