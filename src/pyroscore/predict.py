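"""Sparse predictive modelling of case status from hub-gene expression and
pathway/infiltration scores.

The derivation-cohort model is an L1-penalised logistic regression fitted
along a geometric lambda path by cyclic coordinate descent inside an IRLS
outer loop (the glmnet formulation: mean binomial deviance plus
lambda * ||beta||_1, intercept unpenalised, features standardised
internally with coefficients reported on the original scale). The penalty
is chosen as lambda.min — the minimiser of stratified k-fold
cross-validated deviance — and reported together with its natural log. The
selected variables are re-fitted on a validation cohort with an
L2-penalised (ridge) logistic model, and discrimination is summarised by
the ROC curve and its trapezoid AUC (identical to the Mann-Whitney
U statistic divided by n1*n2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import ExpressionMatrix

logger = logging.getLogger(__name__)

_P_CLIP = 1e-9


@dataclass
class FeatureTable:
    """Samples x named features with a binary case/control outcome."""

    X: pd.DataFrame
    y: pd.Series  # 1 = case, 0 = control

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            dups = self.X.columns[self.X.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature names: {dups}")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and outcome are misaligned")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not set(self.y.unique()) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")


@dataclass
class LassoFit:
    lambdas: np.ndarray
    coef_path: pd.DataFrame        # features x lambdas, original scale
    intercept_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    coefficients: pd.Series        # original scale, at lambda.min
    intercept: float

    @property
    def ln_lambda_min(self) -> float:
        return math.log(self.lambda_min)

    @property
    def selected(self) -> list[str]:
        return self.coefficients.index[self.coefficients != 0].tolist()

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        eta = self.intercept + X[self.coefficients.index].to_numpy() @ \
            self.coefficients.to_numpy()
        return pd.Series(eta, index=X.index)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def build_features(expr: ExpressionMatrix, scores: pd.DataFrame,
                   hub_genes: list[str]) -> FeatureTable:
    """Assemble hub-gene expression plus per-sample scores into one table.

    Hub genes absent from the matrix are dropped with a warning; score
    columns must be aligned to the matrix samples.
    """
    if not scores.index.sort_values().equals(pd.Index(expr.samples).sort_values()):
        raise ValueError("score rows do not match the expression samples")
    present = [g for g in hub_genes if g in expr.values.index]
    missing = [g for g in hub_genes if g not in expr.values.index]
    if missing:
        logger.warning("hub genes absent from the matrix, dropped: %s", missing)
    gene_part = expr.values.loc[present].T
    X = pd.concat([gene_part, scores.loc[gene_part.index]], axis=1)
    y = (expr.groups.loc[X.index] == "case").astype(int)
    return FeatureTable(X=X, y=y)


# ---------------------------------------------------------------------------
# coordinate-descent lasso path


def _soft(x: float, t: float) -> float:
    # tiny relative slack so the KKT boundary |x| = t maps to exactly zero
    # despite float noise in the accumulated gradient
    a = abs(x) - t
    if a <= 1e-12 * max(t, 1.0):
        return 0.0
    return math.copysign(a, x)


def _cd_weighted_ls(X, w, z, beta, b0, lam, tol, max_sweeps=1000):
    """Cyclic coordinate descent on the penalised weighted least squares
    problem (1/2n) sum w (z - b0 - X beta)^2 + lam ||beta||_1.

    Full sweeps alternate with sweeps over the active (nonzero) set until
    a full sweep changes no coefficient by more than ``tol``.
    """
    n, p = X.shape
    wsum = w.sum()
    Wx = w[:, None] * X           # reused across sweeps within one call
    v = (Wx * X).sum(axis=0) / n  # per-coordinate curvature
    r = z - b0 - X @ beta

    def sweep(indices):
        nonlocal b0, r
        delta = 0.0
        b0_new = b0 + (w * r).sum() / wsum
        r -= b0_new - b0
        delta = max(delta, abs(b0_new - b0))
        b0 = b0_new
        for j in indices:
            if v[j] == 0:
                continue
            num = Wx[:, j] @ r / n + v[j] * beta[j]
            bj = _soft(num, lam) / v[j]
            if bj != beta[j]:
                r -= X[:, j] * (bj - beta[j])
                delta = max(delta, abs(bj - beta[j]))
                beta[j] = bj
        return delta

    all_idx = range(p)
    for _ in range(max_sweeps):
        if sweep(all_idx) < tol:
            break
        active = np.flatnonzero(beta)
        for _ in range(max_sweeps):
            if len(active) == 0 or sweep(active) < tol:
                break
    return beta, b0, r


def _lasso_path(X, y, lambdas, family="binomial", tol=1e-7, max_irls=50):
    """Solve the penalised problem along a decreasing lambda grid with warm
    starts. ``X`` must already be standardised. Returns (coefs, intercepts)
    with coefs of shape (p, n_lambda)."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if family == "binomial":
        b0 = math.log(ybar / (1 - ybar))
    else:
        b0 = ybar
    coefs = np.zeros((p, len(lambdas)))
    b0s = np.zeros(len(lambdas))
    for li, lam in enumerate(lambdas):
        if family == "gaussian":
            beta, b0, _ = _cd_weighted_ls(X, np.ones(n), y.astype(float),
                                          beta, b0, lam, tol)
        else:
            for _ in range(max_irls):
                eta = b0 + X @ beta
                prob = 1.0 / (1.0 + np.exp(-eta))
                prob = np.clip(prob, 1e-5, 1 - 1e-5)
                w = prob * (1 - prob)
                z = eta + (y - prob) / w
                old = beta.copy()
                old_b0 = b0
                beta, b0, _ = _cd_weighted_ls(X, w, z, beta, b0, lam, tol)
                if max(np.max(np.abs(beta - old)), abs(b0 - old_b0)) < tol:
                    break
        coefs[:, li] = beta
        b0s[li] = b0
    return coefs, b0s


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def lambda_grid(X_std: np.ndarray, y: np.ndarray, n_lambda: int,
                lambda_min_ratio: float) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X_std.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def lasso_cv(features: FeatureTable, n_lambda: int = 100,
             lambda_min_ratio: float = 0.01, k_folds: int = 10,
             seed: int = 0, family: str = "binomial",
             tol: float = 1e-7) -> LassoFit:
    """L1-penalised logistic regression with cross-validated penalty.

    The lambda grid runs geometrically from lambda_max (the smallest penalty
    at which every slope is zero, max_j |x_j'(y - ybar)| / n on standardised
    features) down by ``lambda_min_ratio``. Stratified k-fold CV scores each
    lambda by mean binomial deviance; lambda.min minimises the CV mean and
    the final model is refit on all samples at that penalty. Coefficients
    are reported on the original feature scale.
    """
    X_raw = features.X.to_numpy(dtype=float)
    y = features.y.to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    X_std, mu, sd = _standardize(X_raw)
    lambdas = lambda_grid(X_std, y, n_lambda, lambda_min_ratio)

    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    dev = np.zeros((k_folds, len(lambdas)))
    for f, (tr, te) in enumerate(cv.split(X_raw, y)):
        if min((y[tr] == 1).sum(), (y[tr] == 0).sum()) < 2 or \
           min((y[te] == 1).sum(), (y[te] == 0).sum()) < 1:
            raise ValueError("a CV fold has too few samples of one class")
        Xtr, mtr, str_ = _standardize(X_raw[tr])
        Xte = (X_raw[te] - mtr) / str_
        coefs, b0s = _lasso_path(Xtr, y[tr], lambdas, family=family, tol=tol)
        eta = Xte @ coefs + b0s
        prob = 1.0 / (1.0 + np.exp(-eta))
        for li in range(len(lambdas)):
            dev[f, li] = binomial_deviance(y[te], prob[:, li])
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / math.sqrt(k_folds)
    best = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[best])

    coefs, b0s = _lasso_path(X_std, y, lambdas, family=family, tol=tol)
    coef_orig = coefs / sd[:, None]
    b0_orig = b0s - (coefs * (mu / sd)[:, None]).sum(axis=0)
    names = features.X.columns
    return LassoFit(
        lambdas=lambdas,
        coef_path=pd.DataFrame(coef_orig, index=names,
                               columns=[f"lambda_{i}" for i in range(len(lambdas))]),
        intercept_path=b0_orig,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        coefficients=pd.Series(coef_orig[:, best], index=names),
        intercept=float(b0_orig[best]),
    )


def ridge_fit(features: FeatureTable, variables: list[str],
              lambda2_grid: np.ndarray | None = None, k_folds: int = 10,
              seed: int = 0):
    """L2-penalised logistic re-fit of the selected variables.

    The ridge penalty is chosen by stratified k-fold CV deviance over a
    geometric grid; the final model is refit on all samples and scored by
    its in-sample ROC AUC. Returns (coefficients Series incl. intercept,
    chosen lambda2, RocCurve).
    """
    if not variables:
        raise ValueError("empty variable list")
    missing = [v for v in variables if v not in features.X.columns]
    if missing:
        raise ValueError(f"variables not in the feature table: {missing}")
    X = features.X[variables].to_numpy(dtype=float)
    y = features.y.to_numpy(dtype=int)
    n = len(y)
    if lambda2_grid is None:
        lambda2_grid = np.geomspace(1e2, 1e-4, 40)

    def fit(Xtr, ytr, lam2):
        C = 1.0 / (n * lam2) if lam2 > 0 else 1e12
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
        model.fit(Xtr, ytr)
        return model

    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    dev = np.zeros((k_folds, len(lambda2_grid)))
    for f, (tr, te) in enumerate(cv.split(X, y)):
        for li, lam2 in enumerate(lambda2_grid):
            model = fit(X[tr], y[tr], lam2)
            prob = model.predict_proba(X[te])[:, 1]
            dev[f, li] = binomial_deviance(y[te], prob)
    best = int(np.argmin(dev.mean(axis=0)))
    lam2 = float(lambda2_grid[best])
    model = fit(X, y, lam2)
    eta = model.decision_function(X)
    roc = roc_auc(eta, y)
    coef = pd.Series(model.coef_[0], index=variables)
    coef["(intercept)"] = float(model.intercept_[0])
    return coef, lam2, roc


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve by threshold sweep and trapezoid AUC.

    Ties contribute diagonal segments, so the AUC equals the Mann-Whitney
    U statistic divided by n1 * n2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
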