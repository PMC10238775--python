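"""Temporal (epidemic-wave) analysis.

Predictors are aggregated within an early wave of the epidemic (by default
the heroin wave, 2010-2012) and related to mortality during the later
synthetic-opioid wave (2013-2019) and to the wave-to-wave *change* in
mortality.  Slicing re-applies the aggregation inclusion thresholds within
the wave window, so the surviving county set can shrink relative to the
full-period analysis.  Language rows of the resulting table reuse the
prediction module's leakage-free cross-validation for their out-of-sample r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import aggregate
from .baselines import fisher_ci, significance_stars
from .predict import PipelineConfig, cross_validate
from .synth import UserTokenCounts

logger = logging.getLogger(__name__)


@dataclass
class WaveSpec:
    """Inclusive year windows per wave plus in-wave inclusion thresholds."""

    waves: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"wave2": (2010, 2012), "wave3": (2013, 2019)}
    )
    min_users: int = aggregate.MIN_USERS_PER_COUNTY
    min_tweets: int = aggregate.MIN_TWEETS_PER_USER

    def __post_init__(self) -> None:
        spans = sorted(self.waves.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"wave year ranges overlap: {spans}")


def wave_slice(
    tokens: UserTokenCounts, spec: WaveSpec, wave: str
) -> aggregate.CountyWordFrequencies:
    """Restrict token records to one wave's years, then re-aggregate.

    A user's tweet count within the slice is the sum over their in-window
    records, so a user can qualify in the full period yet fall below the
    tweet threshold inside the wave (and vice versa).
    """
    y0, y1 = spec.waves[wave]
    years = tokens.users["year"].to_numpy()
    keep = (years >= y0) & (years <= y1)
    if not keep.any():
        raise ValueError(f"no records in wave {wave!r} ({y0}-{y1})")
    sliced = UserTokenCounts(
        counts=tokens.counts[keep],
        vocabulary=tokens.vocabulary,
        users=tokens.users.loc[keep].reset_index(drop=True),
    )
    # user totals (tokens and tweets) are re-summed within the slice, so a
    # user can fail the tweet threshold in-wave while passing full-period
    uf = aggregate.user_relative_frequencies(sliced)
    return aggregate.county_word_frequencies(
        uf, min_users=spec.min_users, min_tweets=spec.min_tweets
    )


def wave_outcomes(
    county_table: pd.DataFrame,
    wave2_col: str = "rate_wave2",
    wave3_col: str = "rate_wave3",
) -> pd.DataFrame:
    """Per-county later-wave rate and the wave-to-wave change.

    Counties missing either wave's rate are dropped (count logged).
    """
    table = (
        county_table.set_index("county_id")
        if "county_id" in county_table
        else county_table
    )
    both = table[[wave2_col, wave3_col]].dropna()
    dropped = len(table) - len(both)
    if dropped:
        logger.info("dropping %d counties missing a wave rate", dropped)
    return pd.DataFrame(
        {
            "wave3_rate": both[wave3_col],
            "delta": both[wave3_col] - both[wave2_col],
        }
    )


def _correlation_row(name: str, x: pd.Series, outcomes: pd.DataFrame) -> dict:
    row: dict = {"predictor": name, "kind": "correlation"}
    for col, label in (("wave3_rate", "wave3"), ("delta", "delta")):
        r, p = stats.pearsonr(x.to_numpy(dtype=float), outcomes[col].to_numpy(dtype=float))
        lo, hi = fisher_ci(r, len(x))
        row[f"r_{label}"] = float(r)
        row[f"ci_{label}"] = (lo, hi)
        row[f"p_{label}"] = float(p)
        row[f"stars_{label}"] = significance_stars(p)
    return row


def wave_table(
    predictors: pd.DataFrame,
    outcomes: pd.DataFrame,
    language_blocks: dict[str, tuple[pd.DataFrame, pd.DataFrame | None]] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Wave-analysis report: one row per predictor and language model.

    Plain predictors get Pearson r with a Fisher 95% CI and significance
    stars against both the later-wave rate and the change.  Each entry of
    ``language_blocks`` maps a model name to (language features, covariates
    or None); those rows report the cross-validated out-of-sample pooled r
    (same machinery and leakage guarantees as the prediction module), with
    the CI/stars computed on the pooled held-out predictions.
    """
    shared = predictors.index.intersection(outcomes.index)
    outcomes = outcomes.loc[shared]
    rows = [
        _correlation_row(str(col), predictors.loc[shared, col], outcomes)
        for col in predictors.columns
    ]
    for name, (features, covariates) in (language_blocks or {}).items():
        row: dict = {"predictor": name, "kind": "out_of_sample"}
        idx = features.index.intersection(outcomes.index)
        for col, label in (("wave3_rate", "wave3"), ("delta", "delta")):
            cv = cross_validate(
                features=features.loc[idx],
                y=outcomes.loc[idx, col],
                config=config,
                covariates=None if covariates is None else covariates.loc[idx],
            )
            r = cv.pooled_r
            _, p = stats.pearsonr(
                cv.oos_predictions.to_numpy(), cv.y.to_numpy()
            )
            lo, hi = fisher_ci(r, len(idx))
            row[f"r_{label}"] = float(r)
            row[f"ci_{label}"] = (lo, hi)
            row[f"p_{label}"] = float(p)
            row[f"stars_{label}"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)
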