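"""Differential language analysis (DLA).

Mass covariate-adjusted regression: for every topic, an OLS of the (z-scored)
mortality rate on the (z-scored) topic loading plus socio-demographic
covariates; the topic's standardized coefficient, its two-sided p-value, and
Benjamini-Hochberg FDR control across the topic family.  Standardization uses
the full analysis sample and the sample-SD (n-1) convention — this module is
inferential, not predictive, so there are no train/test splits.

The per-topic regressions are computed by Frisch-Waugh residualization
(projecting the covariate block out of both outcome and loading), which is
algebraically identical to the joint OLS fit and vectorizes over thousands of
topics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lexicon import TopicLexicon

logger = logging.getLogger(__name__)


def standardize(v: np.ndarray | pd.Series) -> np.ndarray | None:
    """z-score with the sample-SD (ddof=1) convention.

    Returns ``None`` (a sentinel) for zero-variance input; callers exclude
    such variables with a warning rather than dividing by zero.
    """
    arr = np.asarray(v, dtype=float)
    if arr.size < 2:
        raise ValueError("standardize needs length >= 2")
    sd = arr.std(ddof=1)
    if sd == 0:
        logger.warning("zero-variance vector cannot be standardized")
        return None
    return (arr - arr.mean()) / sd


def _covariate_projector(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Design matrix [1, covariates]; raises on rank deficiency."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    Q = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(Q)
    if rank < Q.shape[1]:
        raise ValueError(
            f"covariate design is rank-deficient (rank {rank} < {Q.shape[1]} columns); "
            "remove collinear covariates"
        )
    return Q


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on Q."""
    beta, *_ = np.linalg.lstsq(Q, M, rcond=None)
    return M - Q @ beta


def dla_regression(
    topic_loading: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Covariate-adjusted regression of outcome on one topic loading.

    Inputs are expected already standardized; the returned coefficient is the
    standardized beta of the topic in the joint OLS, with its two-sided
    t-test p-value.
    """
    t = np.asarray(topic_loading, dtype=float)[:, None]
    y = np.asarray(outcome, dtype=float)
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    n = len(y)
    n_cov = 0 if C is None else C.shape[1]
    if n <= n_cov + 2:
        raise ValueError(f"n={n} too small for {n_cov} covariates")
    betas, ps = _mass_regression(t, y, C)
    return float(betas[0]), float(ps[0])


def _mass_regression(
    T: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-OLS topic coefficients and p-values for all columns of T."""
    n = len(y)
    Q = _covariate_projector(covariates, n)
    y_r = _residualize(y[:, None], Q).ravel()
    T_r = _residualize(T, Q)
    ss_t = np.einsum("ij,ij->j", T_r, T_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (T_r.T @ y_r) / ss_t
        rss = y_r @ y_r - beta**2 * ss_t
        df = n - Q.shape[1] - 1
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(sigma2 / ss_t)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, p


def bh_correct(p_values, q_star: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns the monotone adjusted q-values and the boolean rejection set at
    level ``q_star`` (the two views are equivalent: q <= q* iff the step-up
    cutoff rejects).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, *_ = multipletests(p, alpha=q_star, method="fdr_bh")
    return q, reject


@dataclass
class DLAResult:
    topic_id: int
    beta: float
    p_value: float
    q_value: float
    significant: bool
    direction: int              # +1 risk-like, -1 protective-like


def run_dla(
    loadings: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    q_star: float = 0.05,
) -> pd.DataFrame:
    """Per-topic covariate-adjusted DLA over a county-by-topic table.

    Zero-variance topics are excluded before BH (the family size m counts
    only tested topics).  The result is sorted by |beta| descending within
    sign, with columns topic, beta, p, q, significant, direction.
    """
    loadings = loadings.loc[outcome.index]
    y = standardize(outcome)
    if y is None:
        raise ValueError("outcome has zero variance")
    C = None
    if covariates is not None and covariates.shape[1] > 0:
        cols = []
        for name in covariates.columns:
            zc = standardize(covariates[name].loc[outcome.index])
            if zc is None:
                logger.warning("dropping zero-variance covariate %r", name)
                continue
            cols.append(zc)
        C = np.column_stack(cols) if cols else None

    topic_ids = []
    columns = []
    for tcol in loadings.columns:
        zt = standardize(loadings[tcol])
        if zt is None:
            logger.warning("excluding zero-variance topic %r from DLA", tcol)
            continue
        topic_ids.append(tcol)
        columns.append(zt)
    if not columns:
        raise ValueError("no topics with nonzero variance to test")
    T = np.column_stack(columns)
    betas, ps = _mass_regression(T, y, C)
    q, reject = bh_correct(ps, q_star)
    out = pd.DataFrame(
        {
            "topic": topic_ids,
            "beta": betas,
            "p": ps,
            "q": q,
            "significant": reject,
            "direction": np.where(betas >= 0, 1, -1),
        }
    )
    out = out.sort_values(
        ["direction", "beta"],
        key=lambda s: -s.abs() if s.name == "beta" else s,
        ascending=[False, True],
    ).reset_index(drop=True)
    return out


def export_topic_clouds(
    results: pd.DataFrame,
    lexicon: TopicLexicon,
    top_n: int = 12,
    only_significant: bool = True,
) -> dict[str, dict[int, pd.DataFrame]]:
    """Ranked word-weight lists for (significant) topics, split by sign.

    For each topic the ``top_n`` words by within-topic lexicon weight are
    returned (ties broken lexicographically), grouped into ``positive`` and
    ``negative`` association sets — the tabular equivalent of the usual
    word-cloud panels.
    """
    if only_significant:
        results = results[results["significant"]]
    out: dict[str, dict[int, pd.DataFrame]] = {"positive": {}, "negative": {}}
    for _, row in results.iterrows():
        topic = int(row["topic"]) if not isinstance(row["topic"], str) else int(
            str(row["topic"]).removeprefix("topic_")
        )
        if topic < 0 or topic >= lexicon.n_topics:
            raise ValueError(f"topic {topic} absent from lexicon with {lexicon.n_topics} topics")
        w = lexicon.weights[:, topic]
        order = np.lexsort((lexicon.vocabulary.astype(str), -w))[:top_n]
        frame = pd.DataFrame(
            {"word": lexicon.vocabulary[order], "weight": w[order]}
        ).reset_index(drop=True)
        key = "positive" if row["beta"] >= 0 else "negative"
        out[key][topic] = frame
    return out
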