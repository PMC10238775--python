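"""Univariate and category-level covariate baselines.

These are the non-language reference analyses: per-variable Pearson/Spearman
correlations with the mortality rate under BH correction, category-level
multiple-regression cross-validation (the out-of-sample accuracy of e.g.
"demographics" as a block), confound-controlled partial associations, and
Fisher-z confidence intervals for correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dla import bh_correct, standardize
from .predict import CVResult, PipelineConfig, cross_validate

logger = logging.getLogger(__name__)

CATEGORIES = (
    "demographics",
    "socioeconomics",
    "access_to_healthcare",
    "subjective_wellbeing",
    "depression",
    "pain",
    "other",
)


@dataclass
class VariableCatalog:
    """Maps modeled variables to their category (and optional transforms)."""

    categories: dict[str, str]
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v: c for v, c in self.categories.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    def variables(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.categories)
        return [v for v, c in self.categories.items() if c == category]

    @classmethod
    def from_specs(cls, specs) -> "VariableCatalog":
        return cls(categories={s.name: s.category for s in specs})


def significance_stars(p: float) -> str:
    """*** p<0.001, ** p<0.01, * p<0.05 (two-sided)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    if abs(r) >= 1:
        logger.warning("|r| = 1: degenerate interval")
        return float(r), float(r)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def univariate_correlations(
    table: pd.DataFrame,
    outcome: str,
    catalog: VariableCatalog,
    q_star: float = 0.05,
) -> pd.DataFrame:
    """Per-variable Pearson and Spearman correlations with the outcome,
    BH-corrected across the whole variable family (one family).

    Constant variables are excluded from the family with a warning.  Rows are
    ordered by category, then ascending |pearson_r| within category.
    """
    y = table[outcome].to_numpy(dtype=float)
    if len(y) < 4:
        raise ValueError("need n >= 4")
    rows = []
    for var in catalog.variables():
        x = table[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.warning("excluding constant variable %r", var)
            continue
        pr, pp = stats.pearsonr(x, y)
        sr, sp_ = stats.spearmanr(x, y)
        rows.append(
            {
                "variable": var,
                "category": catalog.categories[var],
                "pearson_r": float(pr),
                "pearson_p": float(pp),
                "spearman_rho": float(sr),
                "spearman_p": float(sp_),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    q, reject = bh_correct(out["pearson_p"].to_numpy(), q_star)
    out["q"] = q
    out["significant"] = reject
    out["stars"] = out["pearson_p"].map(significance_stars)
    out["category"] = pd.Categorical(out["category"], categories=CATEGORIES, ordered=True)
    out = out.sort_values(
        ["category", "pearson_r"],
        key=lambda s: s.abs() if s.name == "pearson_r" else s,
    ).reset_index(drop=True)
    return out


def category_cv(
    table: pd.DataFrame,
    outcome: str,
    catalog: VariableCatalog,
    category: str,
    config: PipelineConfig | None = None,
) -> CVResult:
    """Out-of-sample accuracy of one category's variables as a block.

    The per-fold model is an unregularized multiple regression on the
    category's z-scored variables; ``category="all"`` pools every cataloged
    variable.  Raises if a training fold would have fewer rows than model
    parameters (ridge is the suggested fallback).
    """
    config = config or PipelineConfig()
    variables = (
        catalog.variables() if category == "all" else catalog.variables(category)
    )
    if not variables:
        raise ValueError(f"category {category!r} has no variables")
    n_train = len(table) - len(table) // config.k_folds
    if len(variables) >= n_train:
        raise ValueError(
            f"{len(variables)} variables >= {n_train} training rows; use ridge instead"
        )
    y = table[outcome].astype(float)
    return cross_validate(
        features=None,
        y=y,
        config=config,
        covariates=table[variables],
        estimator="ols",
    )


def controlled_association(
    variable: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    controls: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Standardized coefficient of ``variable`` controlling for ``controls``.

    With no controls this equals the Pearson correlation.  All inputs are
    standardized internally (sample-SD convention); a rank-deficient control
    design raises.
    """
    import statsmodels.api as sm

    x = standardize(variable)
    y = standardize(outcome)
    if x is None or y is None:
        raise ValueError("variable and outcome must have nonzero variance")
    cols = [x]
    if controls is not None:
        C = np.asarray(controls, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for j in range(C.shape[1]):
            zc = standardize(C[:, j])
            if zc is None:
                raise ValueError(f"control column {j} has zero variance")
            cols.append(zc)
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank-deficient: variable collinear with controls")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
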