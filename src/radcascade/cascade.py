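"""Two-stage LASSO cascade: GN vs non-GN, then GNB vs NB.

Each stage is a least-squares linear model on a 0/1 response with an L1
penalty, solved by cyclic coordinate descent with soft-thresholding along a
descending lambda path (warm starts).  Lambda is chosen to minimize the mean
squared error pooled over the held-out parts of 5 stratified
cross-validation folds.  The linear (not logistic) link follows the
least-squares-coefficients / cross-validated-MSE formulation of the study
this package reproduces; most radiomics pipelines use logistic LASSO, so the
divergence is deliberate.

Feature normalization is a two-pass robust z-score learned on the stage's
training subjects only: mean/SD are computed, training points with |z| > 3
are excluded, and mean/SD are recomputed on the retained set.  Validation
data are always transformed with training parameters (no leakage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import CLINICAL_FEATURES

__all__ = [
    "RobustScaler",
    "LassoStageModel",
    "CascadeModel",
    "lasso_coordinate_descent",
    "lasso_path",
    "make_lambda_grid",
    "stratified_folds",
    "cv_lasso",
    "youden_threshold",
    "fit_cascade",
    "predict_cascade",
]


# ---------------------------------------------------------------------------
# Robust normalization


@dataclass
class RobustScaler:
    """Per-feature two-pass z-score with |z| > 3 outlier exclusion."""

    center: np.ndarray = None
    scale: np.ndarray = None

    def fit(self, X: np.ndarray) -> "RobustScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 3:
            raise ValueError("robust normalization needs >= 3 training values")
        centers, scales = [], []
        for j in range(X.shape[1]):
            col = X[:, j]
            mu = col.mean()
            sd = col.std(ddof=1)
            if sd <= 1e-10 * max(1.0, abs(mu)):  # numerically constant
                sd = 0.0
            if sd > 0:
                keep = np.abs((col - mu) / sd) <= 3.0
                kept = col[keep]
                mu = kept.mean()
                sd = kept.std(ddof=1) if kept.size > 1 else 0.0
                if sd <= 1e-10 * max(1.0, abs(mu)):
                    sd = 0.0
            centers.append(mu)
            scales.append(sd)
        self.center = np.asarray(centers)
        self.scale = np.asarray(scales)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        safe = np.where(self.scale > 0, self.scale, 1.0)
        Z = (X - self.center) / safe
        Z[:, self.scale == 0] = 0.0
        return Z[:, 0] if one_d else Z


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba ships with the environment
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap


@_njit(cache=False)
def _cd_gram(G, c, lam, beta, tol, max_iter):
    """Cyclic coordinate descent in Gram form.

    G = Xc^T Xc / n, c = Xc^T yc / n (centered data); update
    beta_j <- S(c_j - sum_k G_jk beta_k + G_jj beta_j, lam) / G_jj.
    """
    p = c.shape[0]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj == 0.0:
                continue
            old = beta[j]
            rho = c[j] + gjj * old
            for k in range(p):
                rho -= G[j, k] * beta[k]
            if rho > lam:
                new = (rho - lam) / gjj
            elif rho < -lam:
                new = (rho + lam) / gjj
            else:
                new = 0.0
            if new != old:
                beta[j] = new
                delta = abs(new - old)
                if delta > max_delta:
                    max_delta = delta
        if max_delta < tol:
            break
    return beta


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Minimize ``(1/2n)||y - b0 - X beta||^2 + lam * ||beta||_1``.

    Cyclic coordinate descent with soft-thresholding on the Gram matrix of
    the centered design (the intercept is unpenalized and recovered from the
    means).  Converged when the largest coefficient change in a sweep is
    below ``tol``.  Returns ``(beta, intercept)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = np.ascontiguousarray(X - x_mean)
    yc = y - y_mean
    G = Xc.T @ Xc / n
    # per-column dots match make_lambda_grid bit-for-bit, so the all-zero
    # solution at lambda >= lambda_max is exact
    c = np.array([float(Xc[:, j] @ yc) for j in range(p)]) / n

    beta = np.zeros(p) if beta_init is None else beta_init.astype(np.float64).copy()
    beta = _cd_gram(G, c, float(lam), beta, float(tol), max_iter)
    intercept = y_mean - x_mean @ beta
    return beta, float(intercept)


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero solution) down."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n = len(y)
    # per-column dot products match coordinate descent's gradient computation
    # bit-for-bit, so the largest grid lambda yields exactly zero coefficients
    lam_max = max(
        (abs(float(Xc[:, j] @ yc)) / n for j in range(X.shape[1])), default=0.0
    )
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts along a descending lambda path (warm starts)."""
    p = X.shape[1]
    betas = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta, b0 = lasso_coordinate_descent(X, y, lam, beta_init=beta, tol=tol)
        betas[i] = beta
        intercepts[i] = b0
    return betas, intercepts


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Fold index arrays with each class dealt round-robin after a seeded shuffle."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


@dataclass
class LassoStageModel:
    """One fitted cascade stage (binary 0/1 response)."""

    feature_names: list[str]
    scaler: RobustScaler
    coefficients: np.ndarray
    intercept: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray
    lambda_selected: float
    threshold: float = 0.5
    positive_label: str = ""

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise KeyError(f"missing model feature(s): {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.scaler.transform(X) @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "center": self.scaler.center.tolist(),
            "scale": self.scaler.scale.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_mse": self.cv_mse.tolist(),
            "lambda_selected": self.lambda_selected,
            "threshold": self.threshold,
            "positive_label": self.positive_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LassoStageModel":
        scaler = RobustScaler(
            center=np.asarray(d["center"]), scale=np.asarray(d["scale"])
        )
        return cls(
            feature_names=list(d["feature_names"]),
            scaler=scaler,
            coefficients=np.asarray(d["coefficients"]),
            intercept=float(d["intercept"]),
            lambda_grid=np.asarray(d["lambda_grid"]),
            cv_mse=np.asarray(d["cv_mse"]),
            lambda_selected=float(d["lambda_selected"]),
            threshold=float(d["threshold"]),
            positive_label=d.get("positive_label", ""),
        )


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
    folds: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Select lambda by minimum cross-validated MSE over stratified folds.

    Returns ``(coefficients, intercept, lambda_grid, cv_mse)`` with the final
    model refit on all rows at the selected lambda.  Ties on the MSE curve
    resolve to the largest (most parsimonious) lambda.  ``folds`` may supply
    explicit held-out index arrays (overriding the seeded stratified split).
    """
    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("response has a single class; cannot fit a stage model")
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} subjects; need >= {n_folds} "
            f"for {n_folds}-fold stratified CV"
        )
    grid = make_lambda_grid(X, y, n_lambdas=n_lambdas, min_ratio=min_ratio)
    if folds is None:
        folds = stratified_folds(y, n_folds, seed)
    sq_err = np.zeros(len(grid))
    for held_out in folds:
        tr = np.setdiff1d(np.arange(len(y)), held_out)
        betas, b0s = lasso_path(X[tr], y[tr], grid)
        preds = X[held_out] @ betas.T + b0s[None, :]
        sq_err += ((preds - y[held_out, None]) ** 2).sum(axis=0)
    cv_mse = sq_err / len(y)
    best = int(np.argmin(cv_mse))  # first minimum = largest lambda on ties
    betas, b0s = lasso_path(X, y, grid)
    return betas[best], float(b0s[best]), grid, cv_mse


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold on the training ROC maximizing Youden's J = sens + spec - 1.

    Ties resolve to the largest threshold (most specific operating point).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / max(1, int((y == 1).sum()))
        spec = tn / max(1, int((y == 0).sum()))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class CascadeModel:
    """Two-stage classifier: stage1 GN vs non-GN, stage2 GNB vs NB."""

    stage1: LassoStageModel
    stage2: LassoStageModel
    feature_set_tag: str = "clinical_radiomic"

    def to_dict(self) -> dict:
        return {
            "feature_set_tag": self.feature_set_tag,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeModel":
        return cls(
            stage1=LassoStageModel.from_dict(d["stage1"]),
            stage2=LassoStageModel.from_dict(d["stage2"]),
            feature_set_tag=d.get("feature_set_tag", "clinical_radiomic"),
        )

    @classmethod
    def from_json(cls, path) -> "CascadeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_stage(
    table: pd.DataFrame,
    features: list[str],
    y: np.ndarray,
    positive_label: str,
    seed: int,
    n_folds: int,
    n_lambdas: int,
    min_ratio: float,
    threshold_rule: str,
) -> LassoStageModel:
    scaler = RobustScaler().fit(table[features].to_numpy(dtype=float))
    X = scaler.transform(table[features].to_numpy(dtype=float))
    coef, b0, grid, cv_mse = cv_lasso(
        X, y, n_folds=n_folds, seed=seed, n_lambdas=n_lambdas, min_ratio=min_ratio
    )
    model = LassoStageModel(
        feature_names=list(features),
        scaler=scaler,
        coefficients=coef,
        intercept=b0,
        lambda_grid=grid,
        cv_mse=cv_mse,
        lambda_selected=float(grid[int(np.argmin(cv_mse))]),
        positive_label=positive_label,
    )
    scores = model.score(table)
    if threshold_rule == "youden":
        model.threshold = youden_threshold(scores, y)
    elif threshold_rule == "half":
        model.threshold = 0.5
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return model


def fit_cascade(
    train: pd.DataFrame,
    feature_set: str,
    ranked_features: list[str] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
    threshold_rule: str = "youden",
) -> CascadeModel:
    """Fit both cascade stages on training rows.

    ``feature_set`` is ``"clinical"`` (age + gender only) or
    ``"clinical_radiomic"`` (the mRMR-ranked feature list, which already
    includes any selected clinical covariates).  Stage 2 is trained only on
    the GNB/NB training subjects; each stage learns its own normalization and
    decision threshold on its own training subset.
    """
    if feature_set == "clinical":
        features = list(CLINICAL_FEATURES)
    elif feature_set == "clinical_radiomic":
        if not ranked_features:
            raise ValueError("clinical_radiomic feature set requires ranked_features")
        features = list(ranked_features)
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")

    y1 = (train["label"] == "GN").to_numpy(dtype=float)
    stage1 = _fit_stage(
        train, features, y1, "GN", seed, n_folds, n_lambdas, min_ratio, threshold_rule
    )
    sub = train[train["label"].isin(["GNB", "NB"])]
    y2 = (sub["label"] == "GNB").to_numpy(dtype=float)
    stage2 = _fit_stage(
        sub, features, y2, "GNB", seed + 1, n_folds, n_lambdas, min_ratio, threshold_rule
    )
    return CascadeModel(stage1=stage1, stage2=stage2, feature_set_tag=feature_set)


def predict_cascade(model: CascadeModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cascade prediction.

    Stage-1 score >= threshold -> GN (stage 2 short-circuited, its score
    reported as NaN for the class decision but still computed for ROC use).
    Otherwise stage-2 score >= threshold -> GNB, else NB.
    """
    s1 = model.stage1.score(table)
    s2_all = model.stage2.score(table)
    pred = np.where(
        s1 >= model.stage1.threshold,
        "GN",
        np.where(s2_all >= model.stage2.threshold, "GNB", "NB"),
    )
    s2 = np.where(s1 >= model.stage1.threshold, np.nan, s2_all)
    return pd.DataFrame(
        {
            "predicted": pred,
            "stage1_score": s1,
            "stage2_score": s2,
            "stage2_score_full": s2_all,
        },
        index=table.index,
    )
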