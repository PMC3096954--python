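"""Association and survival statistics for clinical subtype comparisons.

2x2 contingency tables are tested with the Pearson chi-square (df = 1,
no continuity correction by default — the convention that reproduces
uncorrected published values; a correction flag exists) or the two-sided
Fisher exact test (probability-mass rule).  Survival uses the Kaplan-Meier
product-limit estimator with Greenwood variance, the log-rank test across
groups, and Cox proportional-hazards regression (Breslow tie handling by
default, Efron behind a flag, optional stratification).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = ["chi2_2x2", "fisher_exact_2x2", "km_logrank", "cox_ph"]


def _check_table(t) -> np.ndarray:
    a = np.asarray(t, dtype=float)
    if a.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (a < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() == 0:
        raise ValueError("empty table")
    return a


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (df=1), p from the survival function.

    Continuity correction is OFF by default; zero row/column margins raise.
    """
    a = _check_table(table)
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(a, correction=correction)
    return float(chi2), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric masses <= observed)."""
    a = _check_table(table)
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(a.astype(int), alternative="two-sided")
    return float(p)


def km_logrank(
    time, event, group
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the log-rank comparison.

    Returns ``(curves, chi2, p)``; each curve is a DataFrame with columns
    ``survival`` and ``greenwood_var`` indexed by time.  With no events
    anywhere the curves are flat at 1 and the test p is 1 (with a warning).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time <= 0).any():
        raise ValueError("times must be > 0")
    curves: dict[str, pd.DataFrame] = {}
    for g in pd.unique(group):
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        et = kmf.event_table
        # Greenwood: var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = et["observed"] / (et["at_risk"] * (et["at_risk"] - et["observed"]))
        cumsum = terms.replace([np.inf, -np.inf], np.nan).fillna(0.0).cumsum()
        var = cumsum.reindex(surv.index).ffill().fillna(0.0) * surv**2
        curves[str(g)] = pd.DataFrame({"survival": surv, "greenwood_var": var})
    if event.sum() == 0:
        warnings.warn("no events in any group; log-rank p set to 1", stacklevel=2)
        return curves, 0.0, 1.0
    res = multivariate_logrank_test(time, group, event)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_ph(
    time,
    event,
    covariates: pd.DataFrame,
    strata=None,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Cox proportional-hazards fit via the partial likelihood.

    Returns a DataFrame indexed by covariate with columns ``coef``, ``hr``,
    ``hr_lower``, ``hr_upper`` (95% Wald CI) and ``p``.  Breslow tie handling
    by default (``ties="efron"`` for Efron); ``strata`` stratifies the
    partial likelihood.  Collinear covariates (e.g. a duplicated column) are
    rejected rather than fitted.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = pd.DataFrame(covariates)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("covariates must be finite")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient (collinear covariates)")
    if ties not in {"breslow", "efron"}:
        raise ValueError(f"unknown tie method {ties!r}")

    model = PHReg(
        time,
        X.to_numpy(dtype=float),
        status=event,
        strata=None if strata is None else np.asarray(strata),
        ties=ties,
    )
    try:
        fit = model.fit(disp=False)
    except Exception as exc:  # singular information, monotone likelihood
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    if not np.isfinite(coef).all() or not np.isfinite(se).all():
        raise RuntimeError("Cox fit did not converge (non-finite estimates)")
    z = 1.959963984540054
    out = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "hr_lower": np.exp(coef - z * se),
            "hr_upper": np.exp(coef + z * se),
            "p": 2.0 * stats.norm.sf(np.abs(coef / se)),
        },
        index=list(X.columns),
    )
    return out
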