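"""Aggregation contracts: normalization order, topic projection, thresholds."""

import numpy as np
import pandas as pd
import pytest

from countylang import aggregate
from countylang.lexicon import TopicLexicon

from conftest import make_tokens, threshold_fixture


def _freq_of(uf, user_id):
    i = uf.users.index[uf.users["user_id"] == user_id][0]
    return np.asarray(uf.freq[i].todense()).ravel()


class TestUserFrequencies:
    def test_direct_normalization(self):
        tokens = make_tokens([("u1", "00001", 2015, {"w1": 3, "w2": 1}, 30)])
        uf = aggregate.user_relative_frequencies(tokens)
        np.testing.assert_allclose(
            _freq_of(uf, "u1"), [0.75, 0.25], atol=1e-9
        )

    def test_single_word_user(self):
        tokens = make_tokens([("u1", "00001", 2015, {"w1": 7}, 30)])
        uf = aggregate.user_relative_frequencies(tokens)
        assert _freq_of(uf, "u1")[0] == 1.0

    def test_disjoint_vocabularies_stay_disjoint(self):
        tokens = make_tokens(
            [("u1", "00001", 2015, {"w1": 2}, 30), ("u2", "00001", 2015, {"w2": 5}, 30)]
        )
        uf = aggregate.user_relative_frequencies(tokens)
        a, b = _freq_of(uf, "u1"), _freq_of(uf, "u2")
        assert a @ b == 0.0 and a.sum() == b.sum() == 1.0

    def test_zero_token_user_excluded(self, caplog):
        tokens = make_tokens(
            [("u1", "00001", 2015, {"w1": 2}, 30), ("u2", "00001", 2015, {}, 30)]
        )
        # the empty user contributes a zero row
        with caplog.at_level("WARNING"):
            uf = aggregate.user_relative_frequencies(tokens)
        assert list(uf.users["user_id"]) == ["u1"]

    def test_multi_year_records_collapse_to_user_totals(self):
        tokens = make_tokens(
            [
                ("u1", "00001", 2011, {"w1": 1}, 20),
                ("u1", "00001", 2014, {"w2": 3}, 20),
            ]
        )
        uf = aggregate.user_relative_frequencies(tokens)
        assert uf.users.loc[0, "tweet_count"] == 40
        np.testing.assert_allclose(_freq_of(uf, "u1"), [0.25, 0.75])


class TestCountyFrequencies:
    def test_county_below_min_users_excluded(self):
        records = [(f"u{i}", "00001", 2015, {"w1": 1}, 30) for i in range(99)]
        uf = aggregate.user_relative_frequencies(make_tokens(records))
        cwf = aggregate.county_word_frequencies(uf, min_users=100, min_tweets=30)
        assert len(cwf.county_ids) == 0

    def test_user_below_min_tweets_excluded_before_county_count(self):
        records = [(f"u{i}", "00001", 2015, {"w1": 1}, 30) for i in range(100)]
        records[0] = ("u0", "00001", 2015, {"w1": 1}, 29)
        uf = aggregate.user_relative_frequencies(make_tokens(records))
        cwf = aggregate.county_word_frequencies(uf, min_users=100, min_tweets=30)
        assert len(cwf.county_ids) == 0  # 99 qualifying users remain

    def test_county_mean_is_unweighted_over_users(self):
        tokens = make_tokens(
            [("u1", "00001", 2015, {"w1": 1}, 30), ("u2", "00001", 2015, {"w2": 1}, 30)]
        )
        uf = aggregate.user_relative_frequencies(tokens)
        cwf = aggregate.county_word_frequencies(uf, min_users=1, min_tweets=1)
        np.testing.assert_allclose(cwf.freq[0], [0.5, 0.5], atol=1e-9)

    def test_prolific_user_cannot_dominate(self):
        # user-then-county averaging: 1000 tokens from one user weigh the
        # same as 1 token from another; pooled counts would give ~0.999
        tokens = make_tokens(
            [
                ("u1", "00001", 2015, {"w1": 1000}, 30),
                ("u2", "00001", 2015, {"w2": 1}, 30),
            ]
        )
        uf = aggregate.user_relative_frequencies(tokens)
        cwf = aggregate.county_word_frequencies(uf, min_users=1, min_tweets=1)
        np.testing.assert_allclose(cwf.freq[0], [0.5, 0.5], atol=1e-12)
        pooled = 1000 / 1001
        assert abs(cwf.freq[0][0] - pooled) > 0.4

    def test_rows_sum_to_one(self, small_topic_model):
        from countylang.synth import generate_counties

        tokens, _ = generate_counties(
            C=4, users_per_county=(3, 5), tokens_per_user=(10, 30),
            tweets_per_user=(30, 40), topic_model=small_topic_model,
            delta=1.0, kappa=10.0, seed=0,
        )
        uf = aggregate.user_relative_frequencies(tokens)
        cwf = aggregate.county_word_frequencies(uf, min_users=1, min_tweets=1)
        np.testing.assert_allclose(cwf.freq.sum(axis=1), 1.0, atol=1e-9)


class TestProjectTopics:
    def test_single_topic_completeness(self, single_topic_lexicon):
        cwf = aggregate.CountyWordFrequencies(
            freq=np.array([[0.2, 0.3, 0.5]]),
            vocabulary=single_topic_lexicon.vocabulary,
            county_ids=np.array(["00001"], dtype=object),
            n_users=np.array([5]),
        )
        loadings = aggregate.project_topics(cwf, single_topic_lexicon)
        assert loadings.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_two_word_example(self):
        lex = TopicLexicon(
            vocabulary=np.array(["w1", "w2"], dtype=object),
            weights=np.array([[1.0], [0.0]]),
        )
        cwf = aggregate.CountyWordFrequencies(
            freq=np.array([[0.5, 0.5]]),
            vocabulary=lex.vocabulary,
            county_ids=np.array(["00001"], dtype=object),
            n_users=np.array([1]),
        )
        assert aggregate.project_topics(cwf, lex).iloc[0, 0] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(12)
        C, V, K = 5, 50, 4
        vocab = np.array([f"w{i}" for i in range(V)], dtype=object)
        freq = rng.dirichlet(np.ones(V), size=C)
        weights = rng.dirichlet(np.ones(K), size=V)
        lex = TopicLexicon(vocabulary=vocab, weights=weights)
        cwf = aggregate.CountyWordFrequencies(
            freq=freq, vocabulary=vocab,
            county_ids=np.array([f"{c:05d}" for c in range(C)], dtype=object),
            n_users=np.ones(C, dtype=int),
        )
        loadings = aggregate.project_topics(cwf, lex)
        # independent double-loop summation
        expected = np.zeros((C, K))
        for c in range(C):
            for t in range(K):
                s = 0.0
                for w in range(V):
                    s += weights[w, t] * freq[c, w]
                expected[c, t] = s
        np.testing.assert_allclose(loadings.to_numpy(), expected, atol=1e-12)

    def test_out_of_lexicon_words_contribute_nothing(self):
        lex = TopicLexicon(
            vocabulary=np.array(["w1"], dtype=object), weights=np.array([[1.0]])
        )
        cwf = aggregate.CountyWordFrequencies(
            freq=np.array([[0.4, 0.6]]),
            vocabulary=np.array(["w1", "w_unknown"], dtype=object),
            county_ids=np.array(["00001"], dtype=object),
            n_users=np.array([1]),
        )
        # mass on the unknown word is dropped, not renormalized
        assert aggregate.project_topics(cwf, lex).iloc[0, 0] == pytest.approx(0.4)

    def test_empty_intersection_raises_with_sizes(self):
        lex = TopicLexicon(
            vocabulary=np.array(["x1"], dtype=object), weights=np.array([[1.0]])
        )
        cwf = aggregate.CountyWordFrequencies(
            freq=np.array([[1.0]]),
            vocabulary=np.array(["w1"], dtype=object),
            county_ids=np.array(["00001"], dtype=object),
            n_users=np.array([1]),
        )
        with pytest.raises(ValueError, match="1 words"):
            aggregate.project_topics(cwf, lex)

    def test_projection_is_linear_in_county_distribution(self):
        rng = np.random.default_rng(5)
        V, K = 20, 3
        vocab = np.array([f"w{i}" for i in range(V)], dtype=object)
        lex = TopicLexicon(vocabulary=vocab, weights=rng.dirichlet(np.ones(K), size=V))
        a = rng.dirichlet(np.ones(V))
        b = rng.dirichlet(np.ones(V))
        for alpha in (0.0, 0.25, 0.7, 1.0):
            mix = alpha * a + (1 - alpha) * b

            def project(dist):
                cwf = aggregate.CountyWordFrequencies(
                    freq=dist[None, :], vocabulary=vocab,
                    county_ids=np.array(["00001"], dtype=object),
                    n_users=np.array([1]),
                )
                return aggregate.project_topics(cwf, lex).to_numpy()[0]

            np.testing.assert_allclose(
                project(mix), alpha * project(a) + (1 - alpha) * project(b), atol=1e-12
            )


class TestAssembleTable:
    def test_threshold_fixture_survivor_set(self, caplog):
        tokens, county_table, survivors = threshold_fixture()
        uf = aggregate.user_relative_frequencies(tokens)
        cwf = aggregate.county_word_frequencies(uf, min_users=100, min_tweets=30)
        lex = TopicLexicon(
            vocabulary=np.array(["w1", "w2"], dtype=object),
            weights=np.array([[1.0], [1.0]]),
        )
        loadings = aggregate.project_topics(cwf, lex)
        table = aggregate.assemble_analysis_table(
            loadings, county_table, min_reports=300, min_deaths=20
        )
        assert set(table.index) == survivors

    def test_filter_idempotence(self):
        tokens, county_table, _ = threshold_fixture()
        uf = aggregate.user_relative_frequencies(tokens)
        cwf = aggregate.county_word_frequencies(uf, min_users=100, min_tweets=30)
        lex = TopicLexicon(
            vocabulary=np.array(["w1", "w2"], dtype=object),
            weights=np.array([[1.0], [1.0]]),
        )
        loadings = aggregate.project_topics(cwf, lex)
        once = aggregate.assemble_analysis_table(loadings, county_table)
        twice = aggregate.assemble_analysis_table(
            once[[c for c in once.columns if c.startswith("topic_")]].rename(
                columns=lambda c: int(c.removeprefix("topic_"))
            ),
            once.drop(columns=[c for c in once.columns if c.startswith("topic_")]).reset_index(),
        )
        assert once.index.equals(twice.index)

    def test_empty_join_raises(self):
        loadings = pd.DataFrame(
            [[0.5]], index=pd.Index(["99999"], name="county_id"), columns=[0]
        )
        county_table = pd.DataFrame(
            {"county_id": ["00001"], "mortality_rate": [10.0],
             "death_count": [30], "n_reports": [400]}
        )
        with pytest.raises(ValueError):
            aggregate.assemble_analysis_table(loadings, county_table)
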