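"""Shared fixtures: tiny topic models, crafted county fixtures, helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from countylang.lexicon import TopicLexicon
from countylang.synth import UserTokenCounts, generate_topic_model


@pytest.fixture(scope="session")
def small_topic_model():
    return generate_topic_model(K=4, V=50, concentration=0.3, n_signal=2, seed=7)


@pytest.fixture
def single_topic_lexicon():
    """One topic, P(t|w) = 1 for every word."""
    vocab = np.array(["w1", "w2", "w3"], dtype=object)
    return TopicLexicon(vocabulary=vocab, weights=np.ones((3, 1)))


def make_tokens(records: list[tuple[str, str, int, dict[str, int], int]]) -> UserTokenCounts:
    """Build UserTokenCounts from (user, county, year, word->count, tweets)."""
    vocab = sorted({w for *_, counts, _ in records for w in counts})
    vindex = {w: i for i, w in enumerate(vocab)}
    mat = np.zeros((len(records), len(vocab)))
    users = []
    for i, (user, county, year, counts, tweets) in enumerate(records):
        for w, c in counts.items():
            mat[i, vindex[w]] = c
        users.append(
            {"user_id": user, "county_id": county, "year": year, "tweet_count": tweets}
        )
    return UserTokenCounts(
        counts=sp.csr_matrix(mat),
        vocabulary=np.array(vocab, dtype=object),
        users=pd.DataFrame(users),
    )


def threshold_fixture():
    """Eight-county fixture with one county violating each inclusion rule.

    Survivors by design: counties 00001, 00006, 00007, 00008 (all boundary
    values inclusive: exactly 20 deaths, 300 reports, 100 users, 30 tweets).
    """
    records = []
    county_rows = []
    plans = {
        "00001": dict(users=100, tweets=30, deaths=20, reports=300),   # all boundaries, kept
        "00002": dict(users=100, tweets=30, deaths=19, reports=300),   # deaths < 20
        "00003": dict(users=100, tweets=30, deaths=20, reports=299),   # reports < 300
        "00004": dict(users=99, tweets=30, deaths=20, reports=300),    # users < 100
        "00005": dict(users=100, tweets=30, deaths=20, reports=300,
                      low_tweet_users=1),                              # 1 user at 29 tweets -> 99
        "00006": dict(users=150, tweets=40, deaths=25, reports=400),
        "00007": dict(users=100, tweets=30, deaths=50, reports=1000),
        "00008": dict(users=120, tweets=31, deaths=21, reports=301),
    }
    for county, plan in plans.items():
        low = plan.get("low_tweet_users", 0)
        for u in range(plan["users"]):
            tweets = 29 if u < low else plan["tweets"]
            records.append(
                (f"{county}-u{u:03d}", county, 2015, {"w1": 2, "w2": 1}, tweets)
            )
        county_rows.append(
            {
                "county_id": county,
                "mortality_rate": 30.0,
                "death_count": plan["deaths"],
                "population": 100_000,
                "n_reports": plan["reports"],
            }
        )
    return make_tokens(records), pd.DataFrame(county_rows), {"00001", "00006", "00007", "00008"}
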