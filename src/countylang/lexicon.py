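"""Word-topic conditional lexicon: P(topic | word) weights over a vocabulary.

A :class:`TopicLexicon` is the object that carries the conditional weights
used to project county word frequencies onto topic loadings.  It mirrors the
format of the public 2000-topic social-media LDA lexica distributed as long
``term,topic,weight`` tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TopicLexicon:
    """Conditional topic weights P(topic | word).

    Parameters
    ----------
    vocabulary
        Array of word strings, length V.  Order defines the row order of
        ``weights``.
    weights
        (V, K) array; ``weights[w, t]`` is P(topic t | word w).  Weights are
        non-negative; for a lexicon derived from a topic model with a uniform
        topic prior each row sums to 1.
    """

    vocabulary: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.vocabulary = np.asarray(self.vocabulary, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a (V, K) matrix")
        if len(self.vocabulary) != self.weights.shape[0]:
            raise ValueError(
                f"vocabulary length {len(self.vocabulary)} does not match "
                f"weights rows {self.weights.shape[0]}"
            )
        if np.any(self.weights < 0):
            raise ValueError("lexicon weights must be non-negative")

    @property
    def n_topics(self) -> int:
        return self.weights.shape[1]

    @property
    def n_words(self) -> int:
        return self.weights.shape[0]

    def word_index(self) -> pd.Index:
        return pd.Index(self.vocabulary)

    def to_frame(self) -> pd.DataFrame:
        """Long ``term,topic,weight`` table, zero weights omitted."""
        rows, cols = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "term": self.vocabulary[rows],
                "topic": cols,
                "weight": self.weights[rows, cols],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TopicLexicon":
        required = {"term", "topic", "weight"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"lexicon table missing columns: {sorted(missing)}")
        terms = pd.Index(frame["term"].astype(str).unique())
        topics = np.sort(frame["topic"].astype(int).unique())
        n_topics = int(topics.max()) + 1 if len(topics) else 0
        weights = np.zeros((len(terms), n_topics))
        r = terms.get_indexer(frame["term"].astype(str))
        c = frame["topic"].astype(int).to_numpy()
        weights[r, c] = frame["weight"].to_numpy(dtype=float)
        return cls(vocabulary=terms.to_numpy(dtype=object), weights=weights)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TopicLexicon":
        return cls.from_frame(pd.read_csv(path))
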