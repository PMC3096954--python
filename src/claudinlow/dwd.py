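"""Distance-weighted discrimination (DWD) separating directions.

DWD is a linear classifier for high-dimension / low-sample-size data that,
unlike the SVM, lets *every* training point pull on the separating
hyperplane: it minimises the sum of inverse residuals

    min_{w, b, xi}  sum_i 1 / r_i  +  C * sum_i xi_i
    s.t.            r_i = y_i (w . x_i + b) + xi_i,  r_i > 0,  xi_i >= 0,
                    ||w|| <= 1.

Eliminating the slacks gives the equivalent smooth convex problem

    min_{w, b}  sum_i V(y_i (w . x_i + b))   s.t. ||w|| <= 1,

with V(r) = 1/r for r >= 1/sqrt(C) and V(r) = 2 sqrt(C) - C r otherwise
(continuously differentiable).  Because the objective depends on w only
through the inner products with the training points, the optimum lies in the
span of the data; we optimise in that span (dimension <= n_samples) with a
projected-Lagrangian solver (SLSQP) and analytic gradients.  The returned
normal vector has unit Euclidean norm and is oriented from class A toward
class B.

The default penalty is the customary C = 100 / (median pairwise
between-class distance)^2, which makes the solution scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = ["DwdConfig", "dwd_direction", "mean_difference_direction"]


@dataclass
class DwdConfig:
    """DWD solver settings.

    penalty: the DWD penalty C; ``None`` selects 100 / d~^2 with d~ the
    median pairwise distance between the two classes.  tol / maxiter control
    the SLSQP solve.  ``use_mean_difference=True`` swaps in the naive
    mean-difference direction (no solver) — a degraded fallback, never the
    default.
    """

    penalty: float | None = None
    tol: float = 1e-10
    maxiter: int = 500
    use_mean_difference: bool = False

    def __post_init__(self) -> None:
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError("penalty must be > 0")


def _as_samples(m) -> np.ndarray:
    """genes x samples DataFrame (or array) -> samples x genes array."""
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float).T
    a = np.asarray(m, dtype=float)
    return a


def mean_difference_direction(class_a, class_b) -> np.ndarray:
    """Unit vector along mean(B) - mean(A)."""
    A, B = _as_samples(class_a), _as_samples(class_b)
    v = B.mean(axis=0) - A.mean(axis=0)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("class means coincide; direction undefined")
    return v / n


def dwd_direction(class_a, class_b, cfg: DwdConfig | None = None) -> np.ndarray:
    """Unit-norm DWD separating direction, oriented from class A to class B.

    Inputs are genes x samples DataFrames (or samples x genes arrays) over a
    common gene space.  Raises on solver non-convergence with the residual
    report in the message.
    """
    cfg = cfg or DwdConfig()
    A, B = _as_samples(class_a), _as_samples(class_b)
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("each class needs at least one sample")
    if A.shape[1] != B.shape[1]:
        raise ValueError("classes live in different gene spaces")
    if cfg.use_mean_difference:
        return mean_difference_direction(class_a, class_b)

    X = np.vstack([A, B])
    y = np.concatenate([-np.ones(len(A)), np.ones(len(B))])

    if cfg.penalty is None:
        d_med = float(np.median(cdist(A, B)))
        if d_med == 0:
            d_med = 1.0
        C = 100.0 / d_med**2
    else:
        C = float(cfg.penalty)
    thresh = 1.0 / np.sqrt(C)

    # optimise in the span of the training samples
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) and S[0] > 0 else 0
    if rank == 0:
        raise ValueError("all samples identical; no separating direction")
    basis = Vt[:rank]  # rank x genes, orthonormal rows
    M = X @ basis.T  # samples x rank coordinates

    def loss_grad(theta):
        alpha, b = theta[:-1], theta[-1]
        r = y * (M @ alpha + b)
        rs = np.maximum(r, thresh)  # safe denominator; linear branch used below it
        v = np.where(r >= thresh, 1.0 / rs, 2.0 * np.sqrt(C) - C * r)
        dv = np.where(r >= thresh, -1.0 / rs**2, -C)
        g_alpha = M.T @ (dv * y)
        g_b = float(np.sum(dv * y))
        return float(np.sum(v)), np.concatenate([g_alpha, [g_b]])

    # init: normalised mean-difference direction, midpoint on the plane
    w0 = B.mean(axis=0) - A.mean(axis=0)
    a0 = basis @ w0
    n0 = np.linalg.norm(a0)
    a0 = a0 / n0 if n0 > 0 else np.ones(rank) / np.sqrt(rank)
    mid = 0.5 * (A.mean(axis=0) + B.mean(axis=0))
    b0 = -float(a0 @ (basis @ mid))

    res = minimize(
        loss_grad,
        np.concatenate([a0, [b0]]),
        jac=True,
        method="SLSQP",
        constraints=[
            {
                "type": "ineq",
                "fun": lambda t: 1.0 - float(t[:-1] @ t[:-1]),
                "jac": lambda t: np.concatenate([-2.0 * t[:-1], [0.0]]),
            }
        ],
        options={"maxiter": cfg.maxiter, "ftol": cfg.tol},
    )
    if not res.success:
        r = y * (M @ res.x[:-1] + res.x[-1])
        raise RuntimeError(
            f"DWD solver failed: {res.message}; residual range "
            f"[{r.min():.3g}, {r.max():.3g}]"
        )
    alpha = res.x[:-1]
    w = basis.T @ alpha
    norm = np.linalg.norm(w)
    if norm == 0:
        raise RuntimeError("DWD solver returned the zero direction")
    w = w / norm
    if w @ (B.mean(axis=0) - A.mean(axis=0)) < 0:
        w = -w
    return w
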