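"""Cross-validated county mortality prediction.

The prediction stack is: low-variance feature removal, z-scoring, PCA
retaining a configured fraction of variance, and ridge regression with the
penalty chosen by nested (inner) cross-validation — evaluated by k-fold
out-of-sample prediction.  The headline metric is the *pooled* Pearson r
between concatenated held-out predictions and the observed rates; per-fold r
with its standard error is reported alongside.  Fused models concatenate the
PCA-reduced language block with raw z-scored covariates (covariates bypass
PCA).  All preprocessing and selection steps are fit on training folds only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.compose import ColumnTransformer
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = (1.0, 10.0, 100.0, 1e3, 1e4, 1e5)


@dataclass
class PipelineConfig:
    """Knobs of the prediction stack."""

    variance_floor: float = 1e-8
    pca_variance_retained: float = 0.95
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    k_folds: int = 10
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance_floor < 0:
            raise ValueError("variance_floor must be >= 0")
        if not (0 < self.pca_variance_retained <= 1):
            raise ValueError("pca_variance_retained must lie in (0, 1]")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class CVResult:
    """Out-of-sample predictions plus fold-level bookkeeping."""

    fold_assignment: pd.Series          # county -> fold index
    oos_predictions: pd.Series          # county -> held-out prediction
    y: pd.Series
    pooled_r: float
    spearman_rho: float
    fold_r: list[float]
    fold_se: float
    mae: float
    mse: float
    chosen_lambda: list[float | None]

    def to_dict(self) -> dict:
        return {
            "pooled_r": self.pooled_r,
            "spearman_rho": self.spearman_rho,
            "fold_r": self.fold_r,
            "fold_se": self.fold_se,
            "mae": self.mae,
            "mse": self.mse,
            "chosen_lambda": self.chosen_lambda,
            "fold_assignment": {str(k): int(v) for k, v in self.fold_assignment.items()},
            "oos_predictions": {str(k): float(v) for k, v in self.oos_predictions.items()},
        }


# ---------------------------------------------------------------------------
# pipeline building blocks
# ---------------------------------------------------------------------------


def remove_low_variance(X: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop features whose *sample* variance (ddof=1) is <= floor.

    Returns the reduced matrix and the kept-column index, which callers use to
    transform held-out data with training-set decisions only.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    kept = np.flatnonzero(var > floor)
    if kept.size == 0:
        raise ValueError(f"all {X.shape[1]} features fall at or below variance floor {floor}")
    return X[:, kept], kept


class LowVarianceFilter(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over :func:`remove_low_variance`."""

    def __init__(self, floor: float = 1e-8):
        self.floor = floor

    def fit(self, X, y=None):
        _, self.kept_ = remove_low_variance(np.asarray(X), self.floor)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.kept_]


class VarianceRetainedPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the smallest component set reaching a variance fraction.

    ``variance_retained=1.0`` keeps min(rows-1, cols) components (the rank cap
    of mean-centered data).
    """

    def __init__(self, variance_retained: float = 0.95):
        self.variance_retained = variance_retained

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA requires at least 2 rows")
        if np.allclose(X.var(axis=0), 0.0):
            raise ValueError("PCA input is degenerate: all features constant")
        cap = min(X.shape[0] - 1, X.shape[1])
        if self.variance_retained >= 1.0:
            self.pca_ = PCA(n_components=cap, svd_solver="full")
        else:
            self.pca_ = PCA(n_components=self.variance_retained, svd_solver="full")
        self.pca_.fit(X)
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X, dtype=float))

    @property
    def n_components_(self) -> int:
        return self.pca_.n_components_

    @property
    def explained_variance_(self) -> np.ndarray:
        return self.pca_.explained_variance_


def fit_transform_pca(
    X_train: np.ndarray, variance_retained: float = 0.95
) -> tuple[VarianceRetainedPCA, np.ndarray]:
    """Fit PCA on training rows; return the fitted transform and scores."""
    pca = VarianceRetainedPCA(variance_retained)
    pca.fit(X_train)
    return pca, pca.transform(X_train)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """l2-penalized linear regression with an unpenalized intercept.

    Minimizes ||y - X beta - b||^2 + lam ||beta||^2; lam=0 is OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ridge inputs")
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    model = Ridge(alpha=lam, fit_intercept=True, solver="svd")
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def _make_estimator(
    n_lang: int, n_cov: int, config: PipelineConfig, estimator: str
):
    """Assemble the per-fold model: preprocessing + (ridge | OLS).

    Ridge models wrap the whole pipeline in an inner grid search over the
    penalty so that preprocessing is refit within every inner split.
    """
    transformers = []
    if n_lang:
        transformers.append(
            (
                "lang",
                Pipeline(
                    [
                        ("var", LowVarianceFilter(config.variance_floor)),
                        ("scale", StandardScaler()),
                        ("pca", VarianceRetainedPCA(config.pca_variance_retained)),
                    ]
                ),
                list(range(n_lang)),
            )
        )
    if n_cov:
        transformers.append(("cov", StandardScaler(), list(range(n_lang, n_lang + n_cov))))
    pre = ColumnTransformer(transformers)
    if estimator == "ols":
        return Pipeline([("pre", pre), ("model", LinearRegression())])
    if estimator != "ridge":
        raise ValueError(f"unknown estimator {estimator!r}")
    pipe = Pipeline([("pre", pre), ("model", Ridge(solver="svd"))])
    if len(config.lambda_grid) == 1:
        pipe.set_params(model__alpha=config.lambda_grid[0])
        return pipe
    return GridSearchCV(
        pipe,
        param_grid={"model__alpha": list(config.lambda_grid)},
        cv=KFold(config.inner_folds, shuffle=True, random_state=config.seed),
        scoring="neg_mean_squared_error",
        n_jobs=None,
    )


def cross_validate(
    features: pd.DataFrame | None,
    y: pd.Series,
    config: PipelineConfig | None = None,
    covariates: pd.DataFrame | None = None,
    estimator: str = "ridge",
) -> CVResult:
    """k-fold out-of-sample evaluation of the prediction stack.

    ``features`` is the language block (goes through filter/scale/PCA);
    ``covariates`` bypass PCA and are only z-scored.  Either may be omitted.
    Filtering, scaling, PCA and penalty selection are all fit inside the
    training folds only.
    """
    config = config or PipelineConfig()
    if features is None and covariates is None:
        raise ValueError("need at least one of features / covariates")
    index = y.index
    blocks = []
    n_lang = n_cov = 0
    if features is not None:
        features = features.loc[index]
        n_lang = features.shape[1]
        blocks.append(features.to_numpy(dtype=float))
    if covariates is not None:
        covariates = covariates.loc[index]
        n_cov = covariates.shape[1]
        blocks.append(covariates.to_numpy(dtype=float))
    X = np.hstack(blocks)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n // config.k_folds < 2:
        raise ValueError(
            f"{n} counties over {config.k_folds} folds leaves folds with < 2 counties"
        )

    kf = KFold(config.k_folds, shuffle=True, random_state=config.seed)
    fold_assignment = np.empty(n, dtype=int)
    oos = np.empty(n)
    fold_r: list[float] = []
    chosen: list[float | None] = []
    for fold, (tr, te) in enumerate(kf.split(X)):
        fold_assignment[te] = fold
        model = _make_estimator(n_lang, n_cov, config, estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], yv[tr])
        pred = model.predict(X[te])
        oos[te] = pred
        fold_r.append(_safe_pearson(pred, yv[te]))
        if isinstance(model, GridSearchCV):
            chosen.append(float(model.best_params_["model__alpha"]))
        elif estimator == "ridge":
            chosen.append(float(config.lambda_grid[0]))
        else:
            chosen.append(None)

    metrics = evaluate(oos, yv)
    fr = np.asarray(fold_r, dtype=float)
    fold_se = float(np.nanstd(fr, ddof=1) / np.sqrt(np.sum(np.isfinite(fr))))
    return CVResult(
        fold_assignment=pd.Series(fold_assignment, index=index),
        oos_predictions=pd.Series(oos, index=index),
        y=y.astype(float),
        pooled_r=metrics["pearson_r"],
        spearman_rho=metrics["spearman_rho"],
        fold_r=[float(v) for v in fold_r],
        fold_se=fold_se,
        mae=metrics["mae"],
        mse=metrics["mse"],
        chosen_lambda=chosen,
    )


# ---------------------------------------------------------------------------
# evaluation and model comparison
# ---------------------------------------------------------------------------


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def evaluate(pred, y) -> dict:
    """Standard out-of-sample metrics.

    Degenerate (zero-variance) predictions yield NaN correlations with
    ``degenerate=True`` rather than an exception.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(pred) != len(y) or len(y) < 3:
        raise ValueError("evaluate needs aligned vectors of length >= 3")
    err = pred - y
    out = {
        "mae": float(np.mean(np.abs(err))),
        "mse": float(np.mean(err**2)),
        "degenerate": False,
    }
    if np.std(pred) == 0 or np.std(y) == 0:
        logger.warning("zero-variance vector: correlations undefined")
        out.update(pearson_r=float("nan"), spearman_rho=float("nan"), degenerate=True)
        return out
    out["pearson_r"] = float(stats.pearsonr(pred, y)[0])
    out["spearman_rho"] = float(stats.spearmanr(pred, y)[0])
    return out


def compare_models(pred_a, pred_b, y) -> tuple[float, float]:
    """Paired t-test on the two models' absolute out-of-sample errors.

    Accepts :class:`CVResult` or aligned Series.  Negative t means model A has
    the smaller errors.  If the error difference has zero variance, returns
    (+/-inf, 0.0) for a nonzero mean difference and (0.0, 1.0) when the errors
    are identical.
    """
    fold_a = fold_b = None
    if isinstance(pred_a, CVResult):
        fold_a, pred_a = pred_a.fold_assignment, pred_a.oos_predictions
    if isinstance(pred_b, CVResult):
        fold_b, pred_b = pred_b.fold_assignment, pred_b.oos_predictions
    pred_a, pred_b, y = pd.Series(pred_a), pd.Series(pred_b), pd.Series(y)
    if not pred_a.index.sort_values().equals(pred_b.index.sort_values()):
        raise ValueError("models were evaluated on different county sets")
    if fold_a is not None and fold_b is not None and not fold_a.sort_index().equals(
        fold_b.sort_index()
    ):
        raise ValueError("models use different fold assignments")
    pred_b = pred_b.loc[pred_a.index]
    y = y.loc[pred_a.index]
    diff = (pred_a - y).abs() - (pred_b - y).abs()
    d = diff.to_numpy(dtype=float)
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0
        logger.warning("zero-variance paired differences: degenerate t-test")
        return float(np.sign(np.mean(d)) * np.inf), 0.0
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)
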