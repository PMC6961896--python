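"""Discrimination and cohort-comparison statistics.

AUC is computed through the Mann-Whitney identity with midranks (so it
equals U / (n1*n0) under ties), its 95% CI by the DeLong variance
estimator (a percentile bootstrap is available by config).  Group
comparisons use the Mann-Whitney U test for continuous variables and
the chi-square test for categorical ones, two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "CohortComparison",
    "auc_mann_whitney",
    "roc_auc",
    "roc_curve_points",
    "mann_whitney",
    "chi_square",
    "cohort_summary",
]


@dataclass(frozen=True)
class RocResult:
    """AUC with a 95% confidence interval and the underlying data."""

    auc: float
    ci_lower: float
    ci_upper: float
    scores: np.ndarray
    labels: np.ndarray
    cohort: str = ""
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (self.ci_lower - 1e-12 <= self.auc <= self.ci_upper + 1e-12):
            raise ValueError("CI does not bracket the AUC")


@dataclass(frozen=True)
class CohortComparison:
    """One row of a Table-1-style group comparison."""

    variable: str
    kind: str                      # "continuous" | "categorical"
    summaries: dict[str, str]      # group -> formatted summary
    test: str
    p_value: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (R1 - n1(n1+1)/2) / (n1*n0) with midranks (tie-aware)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = _midranks(scores)
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong's placement-value estimate of AUC and its variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    # placement values: V10[i] = P(neg < pos_i) + 0.5 P(neg = pos_i)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    cohort: str = "",
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """AUC with a two-sided (1-alpha) confidence interval.

    ``method`` is "delong" (default, Wald interval on the DeLong
    variance) or "bootstrap" (percentile over stratified resamples).
    The midrank AUC and the DeLong placement-value AUC agree to
    numerical precision; this duality is asserted on every call.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_mann_whitney(scores, labels)
    auc_d, var = _delong_variance(scores, labels)
    assert abs(auc - auc_d) < 1e-12, "midrank/placement AUC mismatch"
    z = sps.norm.ppf(1 - alpha / 2)
    if method == "delong":
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            sp_ = rng.choice(pos, len(pos))
            sn_ = rng.choice(neg, len(neg))
            s = np.concatenate([sp_, sn_])
            l = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
            reps[b] = auc_mann_whitney(s, l)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError("method must be 'delong' or 'bootstrap'")
    return RocResult(auc, max(0.0, lo), min(1.0, hi), scores, labels, cohort, method)


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Full ROC curve as a (threshold, fpr, tpr) table."""
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thr = _sk_roc(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration for small samples (n1+n2 <= 10, no ties),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=not small)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square(
    table: np.ndarray, correction: bool | None = None
) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, p, df).  ``correction=None`` applies the Yates
    continuity correction on 2x2 tables only, mirroring base R's
    ``chisq.test`` default; pass False for the uncorrected statistic.
    """
    table = np.asarray(table, dtype=float)
    if correction is None:
        correction = table.shape == (2, 2)
    res = sps.chi2_contingency(table, correction=correction)
    if (res.expected_freq <= 0).any():
        raise ValueError("zero expected cell count")
    return float(res.statistic), float(res.pvalue), int(res.dof)


def _fmt_median(v: pd.Series) -> str:
    q1, med, q3 = np.percentile(v.dropna(), [25, 50, 75])
    return f"{med:g} ({q1:g}, {q3:g})"


def cohort_summary(
    table: pd.DataFrame,
    group_col: str,
    continuous: tuple[str, ...] = ("age", "tumor_size_mm"),
    categorical: tuple[str, ...] = ("sex", "central_lnm", "label"),
) -> list[CohortComparison]:
    """Table-1-style group comparison of clinical variables.

    Continuous variables are summarized as median (Q1, Q3) and compared
    with Mann-Whitney; categorical variables as n (%) per level with a
    chi-square test.  With a single patient per group (or a single
    group) no test is run and p is NaN.
    """
    groups = list(pd.unique(table[group_col]))
    out: list[CohortComparison] = []
    for var in continuous:
        if var not in table.columns:
            raise KeyError(f"missing covariate column {var!r}")
        vals = [table.loc[table[group_col] == g, var].dropna() for g in groups]
        summaries = {str(g): _fmt_median(v) for g, v in zip(groups, vals)}
        if len(groups) == 2 and all(len(v) > 1 for v in vals):
            _, p = mann_whitney(vals[0].to_numpy(), vals[1].to_numpy())
        else:
            p = float("nan")
        out.append(CohortComparison(var, "continuous", summaries, "Mann-Whitney U", p))
    for var in categorical:
        if var not in table.columns:
            raise KeyError(f"missing covariate column {var!r}")
        ct = pd.crosstab(table[var], table[group_col])
        summaries = {}
        for g in groups:
            n_g = ct[g].sum()
            parts = [f"{lvl}: {ct.loc[lvl, g]} ({100 * ct.loc[lvl, g] / n_g:.1f}%)" for lvl in ct.index]
            summaries[str(g)] = "; ".join(parts)
        if ct.shape[1] == 2 and ct.shape[0] >= 2 and (ct.to_numpy() >= 0).all() and len(table) > 1:
            try:
                _, p, _ = chi_square(ct.to_numpy())
            except ValueError:
                p = float("nan")
        else:
            p = float("nan")
        out.append(CohortComparison(var, "categorical", summaries, "Chi-square", p))
    return out


def summary_to_frame(comparisons: list[CohortComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "test": c.test, "p_value": c.p_value}
        row.update(c.summaries)
        rows.append(row)
    return pd.DataFrame(rows)
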