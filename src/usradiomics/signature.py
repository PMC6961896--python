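"""LASSO-selected radiomics signature and the per-patient Rad-score.

The model is L1-penalized logistic regression of the binary lateral
lymph-node-metastasis label on standardized radiomic features,

    minimize  (1/n) * sum_i log(1 + exp(-y_i (b0 + x_i' b))) + lambda ||b||_1

with the intercept unpenalized.  The penalty weight lambda is tuned by
stratified 10-fold cross-validation over a descending log-spaced grid;
the default selection metric is the cross-validated AUC ("minimum
criterion": the lambda attaining the optimum, ties broken toward the
sparser model).  The fitted signature stores the intercept, the sparse
coefficients and the training standardization constants, which together
define the Rad-score

    Rad-score = b0 + sum_i b_i * (x_i - mu_i) / sigma_i .

The convex optimization itself is done by the package's glmnet-style
coordinate-descent path solver (see ``usradiomics._cd``); this module
owns the grid, folds, metric, tie-breaks and serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._cd import lasso_logistic_path
from .stats import auc_mann_whitney

__all__ = [
    "CohortTable",
    "LassoPath",
    "RadiomicsSignature",
    "RadScore",
    "drop_degenerate_features",
    "standardize",
    "fit_lasso_cv",
    "build_signature",
    "rad_score",
]

COVARIATE_COLUMNS = ("age", "sex", "tumor_size_mm", "central_lnm")


@dataclass
class CohortTable:
    """Per-patient feature matrix, covariates and binary outcome.

    ``features`` is a DataFrame indexed by patient_id whose columns are
    registry feature names; ``labels`` the lateral-LNM indicator (0/1);
    ``covariates`` the clinical table (age, sex, tumor size, central
    LNM).  ``tag`` marks the cohort role (training/validation).
    """

    features: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame | None = None
    tag: str = "training"

    def __post_init__(self) -> None:
        if self.features.index.duplicated().any():
            raise ValueError("duplicate patient_id in cohort")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels index mismatch")
        lab = set(pd.unique(self.labels))
        if not lab <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(lab)}")

    @property
    def n(self) -> int:
        return len(self.features)

    def with_features(self, features: pd.DataFrame) -> "CohortTable":
        return CohortTable(features, self.labels, self.covariates, self.tag)


@dataclass(frozen=True)
class LassoPath:
    """CV results along a descending lambda grid."""

    lambdas: np.ndarray            # descending
    coefs: np.ndarray              # n_lambda x p, full-data refit
    intercepts: np.ndarray         # n_lambda
    cv_mean: np.ndarray            # mean CV metric per lambda
    cv_se: np.ndarray              # standard error over folds
    metric: str                    # "auc" or "deviance"
    lambda_min: float
    feature_names: tuple[str, ...]

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=1)

    @property
    def idx_min(self) -> int:
        return int(np.flatnonzero(self.lambdas == self.lambda_min)[0])


@dataclass(frozen=True)
class RadiomicsSignature:
    """Serialized Rad-score formula.

    Coefficients are on the standardized-feature scale; ``mu``/``sigma``
    are the training-cohort standardization constants of the selected
    features, so the signature can score raw (unstandardized) feature
    vectors.
    """

    intercept: float
    coefficients: dict[str, float]     # nonzero only, insertion-ordered
    mu: dict[str, float]
    sigma: dict[str, float]
    lambda_: float
    metric: str = "auc"

    def score_frame(self, features: pd.DataFrame) -> pd.Series:
        """Rad-score for every row of a raw feature table."""
        missing = [f for f in self.coefficients if f not in features.columns]
        if missing:
            raise KeyError(f"feature(s) absent from input: {missing}")
        s = pd.Series(self.intercept, index=features.index, dtype=float, name="rad_score")
        for name, beta in self.coefficients.items():
            z = (features[name].astype(float) - self.mu[name]) / self.sigma[name]
            s = s + beta * z
        return s

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lambda": self.lambda_,
            "metric": self.metric,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standardization": {k: [self.mu[k], self.sigma[k]] for k in self.coefficients},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "RadiomicsSignature":
        d = json.loads(Path(path).read_text())
        std = d["standardization"]
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            mu={k: v[0] for k, v in std.items()},
            sigma={k: v[1] for k, v in std.items()},
            lambda_=d["lambda"],
            metric=d.get("metric", "auc"),
        )


@dataclass(frozen=True)
class RadScore:
    patient_id: str
    score: float


def drop_degenerate_features(cohort: CohortTable) -> tuple[CohortTable, pd.DataFrame]:
    """Remove features that are constant or non-finite across the cohort.

    Returns the reduced cohort and a report with one row per removed
    feature (columns: feature, reason).
    """
    X = cohort.features
    bad: list[tuple[str, str]] = []
    finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=0)
    for col, ok in zip(X.columns, finite):
        if not ok:
            bad.append((col, "non-finite"))
    values = X.to_numpy(dtype=float)
    const = np.nanmax(values, axis=0) == np.nanmin(values, axis=0)
    for col, c, ok in zip(X.columns, const, finite):
        if ok and c:
            bad.append((col, "zero variance"))
    report = pd.DataFrame(bad, columns=["feature", "reason"])
    keep = [c for c in X.columns if c not in set(report["feature"])]
    return cohort.with_features(X[keep]), report


def standardize(
    train: CohortTable, apply_to: CohortTable | None = None
) -> tuple[CohortTable, CohortTable | None, pd.DataFrame]:
    """z-score features with training-cohort constants only.

    Returns (standardized training cohort, standardized second cohort or
    None, constants DataFrame indexed by feature with columns mu/sigma).
    Validation data never contribute to mu or sigma.
    """
    X = train.features
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    if (sigma == 0).any():
        zero = sigma.index[sigma == 0].tolist()
        raise ValueError(f"zero-variance features must be dropped first: {zero}")
    constants = pd.DataFrame({"mu": mu, "sigma": sigma})
    out_train = train.with_features((X - mu) / sigma)
    out_other = None
    if apply_to is not None:
        Xo = apply_to.features[X.columns]
        out_other = apply_to.with_features((Xo - mu) / sigma)
    return out_train, out_other, constants


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to ratio*lambda_max.

    lambda_max = max_j |x_j'(y - ybar)| / n is the smallest penalty at
    which the null (intercept-only) model is optimal.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float, max_irls: int = 50
) -> tuple[np.ndarray, np.ndarray, int]:
    """Warm-started L1 logistic fits along a descending lambda grid."""
    return lasso_logistic_path(X, y, lambdas, tol=tol, max_irls=max_irls)


def fit_lasso_cv(
    train: CohortTable,
    n_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    metric: str = "auc",
    tol: float = 1e-7,
    max_irls: int = 50,
) -> LassoPath:
    """Cross-validated LASSO logistic regression on a standardized cohort.

    Stratified ``n_folds``-fold CV scores every lambda on the held-out
    folds; ``metric`` is "auc" (higher better, the default) or
    "deviance" (mean binomial deviance, lower better).  lambda_min is
    the grid point attaining the optimal mean CV metric; when several
    tie, the largest (sparsest) lambda wins.  Deterministic given
    (data, seed, grid).
    """
    X = train.features.to_numpy(dtype=float)
    y = train.labels.to_numpy(dtype=int)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")
    if metric not in ("auc", "deviance"):
        raise ValueError("metric must be 'auc' or 'deviance'")
    if lambdas is None:
        lambdas = lambda_grid(X, y, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_scores = np.zeros((n_folds, len(lambdas)))
    k_min = len(lambdas)  # grid points fit by every fold (early stopping)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a CV fold lost one class; cohort too small/unbalanced")
        coefs, icepts, k_stop = _fit_path(X[tr], y[tr], lambdas, tol, max_irls)
        k_min = min(k_min, k_stop)
        scores = X[te] @ coefs.T + icepts  # n_te x n_lambda linear predictors
        for k in range(k_stop):
            if metric == "auc":
                fold_scores[f, k] = auc_mann_whitney(scores[:, k], y[te])
            else:
                eta = np.clip(scores[:, k], -30, 30)
                phat = 1.0 / (1.0 + np.exp(-eta))
                eps = 1e-12
                fold_scores[f, k] = -2.0 * np.mean(
                    y[te] * np.log(phat + eps) + (1 - y[te]) * np.log(1 - phat + eps)
                )
    coefs, icepts, k_stop = _fit_path(X, y, lambdas, tol, max_irls)
    # evaluate only the lambdas every fold (and the refit) reached
    k_use = min(k_min, k_stop)
    lambdas = lambdas[:k_use]
    coefs, icepts = coefs[:k_use], icepts[:k_use]
    fold_scores = fold_scores[:, :k_use]

    cv_mean = fold_scores.mean(axis=0)
    cv_se = fold_scores.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = cv_mean.max() if metric == "auc" else cv_mean.min()
    ties = np.flatnonzero(cv_mean == best)
    idx_min = int(ties[0])  # grid is descending: first index = largest lambda

    return LassoPath(
        lambdas=lambdas,
        coefs=coefs,
        intercepts=icepts,
        cv_mean=cv_mean,
        cv_se=cv_se,
        metric=metric,
        lambda_min=float(lambdas[idx_min]),
        feature_names=tuple(train.features.columns),
    )


def fit_lasso_fixed(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-10
) -> tuple[float, np.ndarray]:
    """Single L1-logistic fit at a fixed penalty; returns (intercept, coefs)."""
    coefs, icepts, _ = lasso_logistic_path(
        np.asarray(X, float), np.asarray(y, int), np.array([lam]),
        tol=tol, fdev=0.0, devmax=1.0,
    )
    return float(icepts[0]), coefs[0]


def build_signature(
    path: LassoPath, constants: pd.DataFrame, lam: float | None = None
) -> RadiomicsSignature:
    """Freeze the Rad-score formula at lambda_min (or a given lambda).

    Keeps exactly the nonzero-coefficient features, paired with their
    training standardization constants.  A fully shrunk model yields an
    intercept-only signature (with a warning upstream).
    """
    lam = path.lambda_min if lam is None else lam
    idx = int(np.argmin(np.abs(path.lambdas - lam)))
    beta = path.coefs[idx]
    nz = np.flatnonzero(beta)
    names = [path.feature_names[j] for j in nz]
    return RadiomicsSignature(
        intercept=float(path.intercepts[idx]),
        coefficients={nm: float(beta[j]) for nm, j in zip(names, nz)},
        mu={nm: float(constants.loc[nm, "mu"]) for nm in names},
        sigma={nm: float(constants.loc[nm, "sigma"]) for nm in names},
        lambda_=float(path.lambdas[idx]),
        metric=path.metric,
    )


def rad_score(sig: RadiomicsSignature, features) -> RadScore:
    """Rad-score of a single raw feature vector.

    Accepts a FeatureVector, a pandas Series or a plain mapping; raises
    KeyError when a signature feature is missing — no silent imputation.
    """
    patient_id = getattr(features, "patient_id", "")
    if hasattr(features, "as_dict"):  # FeatureVector
        features = pd.Series(features.as_dict())
    elif isinstance(features, dict):
        features = pd.Series(features)
    score = sig.intercept
    for name, beta in sig.coefficients.items():
        if name not in features.index:
            raise KeyError(f"feature {name!r} missing from input vector")
        score += beta * (float(features[name]) - sig.mu[name]) / sig.sigma[name]
    return RadScore(patient_id=str(patient_id), score=float(score))
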