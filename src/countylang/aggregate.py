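"""County-level language features: word frequencies and topic loadings.

The aggregation order is fixed and matters: token counts are normalized to
relative frequencies *per user record* first, then averaged (unweighted)
across the county's surviving users, so a prolific user cannot dominate the
county estimate.  Topic loadings are the lexicon projection

    loading[c, t] = sum_w P(t | w) * P(w | c)

summed over the intersection of the county vocabulary and the lexicon; words
missing from either side contribute nothing and no renormalization is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lexicon import TopicLexicon
from .synth import UserTokenCounts

logger = logging.getLogger(__name__)

#: inclusion thresholds used in the full-scale analysis
MIN_USERS_PER_COUNTY = 100
MIN_TWEETS_PER_USER = 30
MIN_REPORTS_PER_COUNTY = 300
MIN_DEATHS_PER_COUNTY = 20


@dataclass
class UserFrequencies:
    """Row-normalized user-record word distributions."""

    freq: sp.csr_matrix
    vocabulary: np.ndarray
    users: pd.DataFrame


@dataclass
class CountyWordFrequencies:
    """Per-county relative word frequencies (each row sums to 1)."""

    freq: np.ndarray            # (C, V) dense; county counts are small
    vocabulary: np.ndarray
    county_ids: np.ndarray
    n_users: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.freq)
        return pd.DataFrame(
            {
                "county_id": self.county_ids[rows],
                "word": self.vocabulary[cols],
                "freq": self.freq[rows, cols],
            }
        )


def user_relative_frequencies(tokens: UserTokenCounts) -> UserFrequencies:
    """Collapse per-year records to users and normalize counts to distributions.

    A user's token counts (and tweet count) are summed over their records
    before normalizing, so thresholds downstream see whole-user totals.
    Users with zero total tokens are excluded (with a warning): they carry no
    language information and would produce undefined frequencies.
    """
    users = tokens.users
    county_per_user = users.groupby("user_id")["county_id"].nunique()
    multi = county_per_user[county_per_user > 1]
    if len(multi):
        raise ValueError(f"users mapped to multiple counties: {list(multi.index[:10])}")
    user_index = pd.Index(users["user_id"].unique())
    rows = user_index.get_indexer(users["user_id"])
    collapse = sp.coo_matrix(
        (np.ones(len(users)), (rows, np.arange(len(users)))),
        shape=(len(user_index), len(users)),
    ).tocsr()
    counts = sp.csr_matrix(collapse @ tokens.counts)
    meta = (
        users.groupby("user_id", sort=False)
        .agg(county_id=("county_id", "first"), tweet_count=("tweet_count", "sum"))
        .loc[user_index]
        .rename_axis("user_id")
        .reset_index()
    )
    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep = totals > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("excluding %d users with zero tokens", dropped)
    counts = counts[keep]
    totals = totals[keep]
    freq = sp.csr_matrix(counts.multiply(1.0 / totals[:, None]))
    return UserFrequencies(
        freq=freq,
        vocabulary=tokens.vocabulary,
        users=meta.loc[keep].reset_index(drop=True),
    )


def county_word_frequencies(
    user_freqs: UserFrequencies,
    min_users: int = MIN_USERS_PER_COUNTY,
    min_tweets: int = MIN_TWEETS_PER_USER,
) -> CountyWordFrequencies:
    """Average user distributions within counties, applying inclusion rules.

    Users with fewer than ``min_tweets`` tweets are dropped first; counties
    with fewer than ``min_users`` surviving users are then dropped.  The
    county frequency is the unweighted mean of its surviving users'
    distributions — each user counts equally regardless of volume.
    """
    users = user_freqs.users
    qualified = users["tweet_count"].to_numpy() >= min_tweets
    n_user_drop = int((~qualified).sum())
    if n_user_drop:
        logger.info("dropping %d user records below %d tweets", n_user_drop, min_tweets)
    freq = user_freqs.freq[qualified]
    users = users.loc[qualified]

    counts_by_county = users.groupby("county_id", sort=True).size()
    surviving = counts_by_county[counts_by_county >= min_users]
    n_county_drop = len(counts_by_county) - len(surviving)
    if n_county_drop:
        logger.info(
            "dropping %d counties with fewer than %d qualifying users",
            n_county_drop,
            min_users,
        )
    county_ids = surviving.index.to_numpy(dtype=object)
    if len(county_ids) == 0:
        logger.warning("no counties survive the user thresholds")
        return CountyWordFrequencies(
            freq=np.zeros((0, len(user_freqs.vocabulary))),
            vocabulary=user_freqs.vocabulary,
            county_ids=county_ids,
            n_users=np.zeros(0, dtype=int),
        )
    county_index = pd.Index(county_ids)
    rows = county_index.get_indexer(users["county_id"])
    ok = rows >= 0
    # group mean via sparse indicator matrix
    n_users = surviving.to_numpy()
    indicator = sp.coo_matrix(
        (np.ones(ok.sum()), (rows[ok], np.flatnonzero(ok))),
        shape=(len(county_ids), freq.shape[0]),
    ).tocsr()
    mean = np.asarray((indicator @ freq).todense()) / n_users[:, None]
    return CountyWordFrequencies(
        freq=mean,
        vocabulary=user_freqs.vocabulary,
        county_ids=county_ids,
        n_users=n_users,
    )


def project_topics(
    cwf: CountyWordFrequencies, lexicon: TopicLexicon
) -> pd.DataFrame:
    """Project county word frequencies onto topic loadings.

    Returns a county-by-topic DataFrame (index county_id, integer topic
    columns).  Only the intersection of the two vocabularies contributes;
    out-of-lexicon mass is silently dropped, not renormalized.
    """
    lex_index = lexicon.word_index()
    pos = lex_index.get_indexer(pd.Index(cwf.vocabulary))
    shared = pos >= 0
    if not shared.any():
        raise ValueError(
            "no vocabulary overlap between county frequencies "
            f"({len(cwf.vocabulary)} words) and lexicon ({lexicon.n_words} words)"
        )
    loadings = cwf.freq[:, shared] @ lexicon.weights[pos[shared]]
    return pd.DataFrame(
        loadings,
        index=pd.Index(cwf.county_ids, name="county_id"),
        columns=np.arange(lexicon.n_topics),
    )


def assemble_analysis_table(
    loadings: pd.DataFrame,
    county_table: pd.DataFrame,
    min_reports: int = MIN_REPORTS_PER_COUNTY,
    min_deaths: int = MIN_DEATHS_PER_COUNTY,
) -> pd.DataFrame:
    """Inner-join language loadings with the county outcome table and apply
    the self-report and death-count inclusion thresholds.

    Per-filter attrition counts are logged.  Topic columns are renamed
    ``topic_<t>`` so they coexist with outcome/covariate columns.
    """
    outcomes = county_table.set_index("county_id") if "county_id" in county_table else county_table
    lang = loadings.rename(columns=lambda t: f"topic_{t}")
    joined = lang.join(outcomes, how="inner")
    n0 = len(joined)
    if "n_reports" in joined:
        joined = joined[joined["n_reports"] >= min_reports]
    logger.info("self-report filter (>=%d): %d -> %d counties", min_reports, n0, len(joined))
    n1 = len(joined)
    if "death_count" in joined:
        joined = joined[joined["death_count"] >= min_deaths]
    logger.info("death-count filter (>=%d): %d -> %d counties", min_deaths, n1, len(joined))
    if len(joined) == 0:
        raise ValueError("no counties survive the join and inclusion thresholds")
    return joined


def topic_columns(table: pd.DataFrame) -> list[str]:
    """Names of the language (topic-loading) columns in an analysis table."""
    return [c for c in table.columns if isinstance(c, str) and c.startswith("topic_")]
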