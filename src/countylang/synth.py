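"""Synthetic county-mapped corpora with planted, recoverable signal.

The generator emulates the data situation of county-level language
surveillance studies: each county has a set of social-media users, each user
emits tokens from a personal topic mixture, and a latent per-county risk
factor ``z`` simultaneously (a) shifts the prevalence of designated *risk*
and *protective* topics and (b) drives a continuous mortality rate together
with correlated covariates and self-report aggregates.  Because ``z`` and all
coupling parameters are recorded, every downstream stage (aggregation, topic
projection, cross-validated prediction, differential language analysis, wave
slicing) can be validated against known ground truth.

Generation model
----------------
* Topic model: K topic-word rows ``phi[t] ~ Dirichlet(concentration)`` over a
  V-word vocabulary; the word-topic lexicon is the Bayes inversion with a
  uniform topic prior, ``P(t|w) = phi[t,w] / sum_t' phi[t',w]``.
* Counties: ``z_c ~ N(0,1)``; county topic prior
  ``theta_c = softmax(log_base + delta * z_c * s)`` where ``s`` is +1 on risk
  topics, -1 on protective topics, 0 elsewhere.
* Users: mixture ``theta_u ~ Dirichlet(kappa * theta_c)``; token counts are a
  multinomial draw from the mixed word distribution ``theta_u @ phi``
  (distributionally identical to sampling a topic then a word per token).
* Outcome: ``y_c = mu + gamma * z_c + sum_j w_j x_cj + eps`` truncated at 0,
  with covariates ``x_cj = a_j z_c + N(0,1)``; death count is the rate scaled
  by population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lexicon import TopicLexicon

logger = logging.getLogger(__name__)

RISK = 1
PROTECTIVE = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TopicModel:
    """A K-topic, V-word emission model plus its derived conditional lexicon."""

    phi: np.ndarray                     # (K, V) rows are distributions
    topic_lexicon: TopicLexicon         # P(topic | word), (V, K)
    signal_topics: dict[int, int]       # topic index -> +1 (risk) / -1 (protective)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    @property
    def n_words(self) -> int:
        return self.phi.shape[1]

    @property
    def risk_topics(self) -> list[int]:
        return sorted(t for t, s in self.signal_topics.items() if s == RISK)

    @property
    def protective_topics(self) -> list[int]:
        return sorted(t for t, s in self.signal_topics.items() if s == PROTECTIVE)

    def sign_vector(self) -> np.ndarray:
        s = np.zeros(self.n_topics)
        for t, sign in self.signal_topics.items():
            s[t] = sign
        return s


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted signal."""

    county_ids: np.ndarray              # (C,) zero-padded id strings
    z: np.ndarray                       # (C,) latent risk factor, ~N(0,1)
    theta: np.ndarray                   # (C, K) county topic priors
    delta: float                        # topic-prevalence coupling
    kappa: float                        # user-mixture concentration
    signal_topics: dict[int, int]
    seed: int
    # outcome-stage parameters, filled by generate_outcome
    gamma: float | None = None
    mu: float | None = None
    noise_sd: float | None = None
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    r2_language: float | None = None

    def manifest(self) -> dict:
        """JSON-serializable record of the simulation truth."""
        return {
            "seed": int(self.seed),
            "delta": float(self.delta),
            "kappa": float(self.kappa),
            "gamma": None if self.gamma is None else float(self.gamma),
            "mu": None if self.mu is None else float(self.mu),
            "noise_sd": None if self.noise_sd is None else float(self.noise_sd),
            "r2_language": None if self.r2_language is None else float(self.r2_language),
            "signal_topics": {str(t): int(s) for t, s in sorted(self.signal_topics.items())},
            "covariate_effects": {
                k: [float(a), float(w)] for k, (a, w) in self.covariate_effects.items()
            },
            "county_ids": [str(c) for c in self.county_ids],
            "z": [float(v) for v in self.z],
        }


@dataclass
class UserTokenCounts:
    """Sparse user-by-word token counts plus per-record user metadata.

    ``users`` has one row per (user, year) record with columns
    ``user_id, county_id, year, tweet_count``; row *i* of ``counts`` holds that
    record's token counts over ``vocabulary``.
    """

    counts: sp.csr_matrix
    vocabulary: np.ndarray
    users: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.users):
            raise ValueError("counts rows must align with users table")
        if self.counts.shape[1] != len(self.vocabulary):
            raise ValueError("counts columns must align with vocabulary")

    @property
    def n_records(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long token table: user_id, county_id, year, word, count."""
        coo = self.counts.tocoo()
        meta = self.users.iloc[coo.row]
        return pd.DataFrame(
            {
                "user_id": meta["user_id"].to_numpy(),
                "county_id": meta["county_id"].to_numpy(),
                "year": meta["year"].to_numpy(),
                "word": self.vocabulary[coo.col],
                "count": coo.data.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls, tokens: pd.DataFrame, users: pd.DataFrame
    ) -> "UserTokenCounts":
        """Build from long tables (the on-disk TSV layout)."""
        if (tokens["count"] < 0).any():
            raise ValueError("token counts must be non-negative")
        users = users.reset_index(drop=True)
        key = users["user_id"].astype(str) + "\x00" + users["year"].astype(str)
        row_index = pd.Index(key)
        if row_index.has_duplicates:
            raise ValueError("duplicate (user_id, year) records in users table")
        vocab = pd.Index(np.sort(tokens["word"].astype(str).unique()))
        tk = tokens["user_id"].astype(str) + "\x00" + tokens["year"].astype(str)
        r = row_index.get_indexer(tk)
        if (r < 0).any():
            raise ValueError("token table references users absent from users table")
        c = vocab.get_indexer(tokens["word"].astype(str))
        counts = sp.coo_matrix(
            (tokens["count"].to_numpy(dtype=float), (r, c)),
            shape=(len(users), len(vocab)),
        ).tocsr()
        return cls(
            counts=counts,
            vocabulary=vocab.to_numpy(dtype=object),
            users=users,
        )


@dataclass
class CovariateSpec:
    """One simulated county-level variable.

    ``loading`` couples the variable to the latent factor z; ``weight`` is its
    own direct coefficient in the mortality model.
    """

    name: str
    category: str
    loading: float = 0.0
    weight: float = 0.0


@dataclass
class PopulationSpec:
    """County population sizes (log10-uniform) and self-report sampling rate."""

    log10_range: tuple[float, float] = (4.5, 5.7)
    report_rate: float = 0.005


@dataclass
class WaveParams:
    """Outcome parameters for one epidemic wave's mortality rate column."""

    label: str
    mu: float
    gamma: float
    noise_sd: float


def default_covariates() -> list[CovariateSpec]:
    """Area covariates mirroring the usual demographic / socioeconomic /
    healthcare-access catalog used in county mortality baselines."""
    return [
        CovariateSpec("perc_female", "demographics", 0.1, 0.0),
        CovariateSpec("perc_white", "demographics", 0.2, 0.0),
        CovariateSpec("perc_rural", "demographics", 0.3, 0.0),
        CovariateSpec("perc_over_65", "demographics", 0.2, 0.0),
        CovariateSpec("median_age", "demographics", 0.3, 0.0),
        CovariateSpec("perc_hs_diploma", "socioeconomics", -0.1, 0.0),
        CovariateSpec("perc_bachelors", "socioeconomics", -0.3, 0.0),
        CovariateSpec("log_median_income", "socioeconomics", -0.3, 0.0),
        CovariateSpec("unemployment_rate", "socioeconomics", 0.2, 0.0),
        CovariateSpec("primary_care_providers", "access_to_healthcare", -0.1, 0.0),
        CovariateSpec("mental_health_providers", "access_to_healthcare", -0.1, 0.0),
        CovariateSpec("perc_insured", "access_to_healthcare", -0.3, 0.0),
    ]


def default_self_reports() -> list[CovariateSpec]:
    """Psychometric self-report aggregates (well-being, depression, pain)."""
    return [
        CovariateSpec("positive_emotions", "subjective_wellbeing", -0.5, 0.0),
        CovariateSpec("negative_emotions", "subjective_wellbeing", 0.4, 0.0),
        CovariateSpec("life_satisfaction", "subjective_wellbeing", -0.5, 0.0),
        CovariateSpec("depression", "depression", 0.4, 0.0),
        CovariateSpec("pain", "pain", 0.4, 0.0),
    ]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_topic_model(
    K: int,
    V: int,
    concentration: float = 0.3,
    n_signal: int = 0,
    seed: int = 0,
) -> TopicModel:
    """Draw a K-topic emission model and tag ``n_signal`` signal topics.

    Signal topics are split evenly between risk (+) and protective (-); risk
    receives the extra topic when ``n_signal`` is odd.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if V < K:
        raise ValueError("V must be >= K")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not (0 <= n_signal <= K):
        raise ValueError("n_signal must lie in [0, K]")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, concentration), size=K)
    # guard against exact-zero columns from underflow at small concentration
    phi = np.clip(phi, 1e-300, None)
    phi /= phi.sum(axis=1, keepdims=True)
    # Bayes inversion with a uniform topic prior
    weights = (phi / phi.sum(axis=0, keepdims=True)).T
    vocabulary = np.array([f"w{i:05d}" for i in range(V)], dtype=object)
    chosen = rng.choice(K, size=n_signal, replace=False)
    n_risk = math.ceil(n_signal / 2)
    signal = {int(t): RISK for t in chosen[:n_risk]}
    signal.update({int(t): PROTECTIVE for t in chosen[n_risk:]})
    return TopicModel(
        phi=phi,
        topic_lexicon=TopicLexicon(vocabulary=vocabulary, weights=weights),
        signal_topics=signal,
    )


def _check_range(name: str, rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = int(rng_pair[0]), int(rng_pair[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"{name} must be a positive, non-degenerate range; got {rng_pair}")
    return lo, hi


def county_topic_priors(
    z: np.ndarray, topic_model: TopicModel, delta: float, base_log: np.ndarray
) -> np.ndarray:
    """theta_c = softmax(base_log + delta * z_c * s)."""
    s = topic_model.sign_vector()
    logits = base_log[None, :] + delta * z[:, None] * s[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    theta = np.exp(logits)
    theta /= theta.sum(axis=1, keepdims=True)
    return theta


def generate_counties(
    C: int,
    users_per_county: tuple[int, int],
    tokens_per_user: tuple[int, int],
    tweets_per_user: tuple[int, int],
    topic_model: TopicModel,
    delta: float,
    kappa: float,
    seed: int,
    year_span: tuple[int, int] = (2009, 2019),
) -> tuple[UserTokenCounts, GroundTruth]:
    """Draw counties, their latent risk, and their users' token streams."""
    if C < 1:
        raise ValueError("C must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    u_lo, u_hi = _check_range("users_per_county", users_per_county)
    t_lo, t_hi = _check_range("tokens_per_user", tokens_per_user)
    tw_lo, tw_hi = _check_range("tweets_per_user", tweets_per_user)

    rng = np.random.default_rng(seed)
    K, V = topic_model.n_topics, topic_model.n_words

    county_ids = np.array([f"{i + 1:05d}" for i in range(C)], dtype=object)
    z = rng.standard_normal(C)
    base_log = rng.uniform(np.log(0.5), np.log(2.0), size=K)
    theta = county_topic_priors(z, topic_model, delta, base_log)

    n_users = rng.integers(u_lo, u_hi + 1, size=C)
    county_row = np.repeat(np.arange(C), n_users)
    U = len(county_row)

    # user mixtures theta_u ~ Dirichlet(kappa * theta_c), via gamma draws
    alpha = kappa * theta[county_row]
    g = rng.standard_gamma(alpha)
    row_sum = g.sum(axis=1)
    dead = row_sum <= 0
    if dead.any():                       # extreme kappa underflow fallback
        g[dead] = theta[county_row[dead]]
        row_sum = g.sum(axis=1)
    theta_u = g / row_sum[:, None]

    n_tokens = rng.integers(t_lo, t_hi + 1, size=U)
    blocks = []
    chunk = 2048
    for start in range(0, U, chunk):
        stop = min(start + chunk, U)
        p = theta_u[start:stop] @ topic_model.phi
        p /= p.sum(axis=1, keepdims=True)
        blocks.append(sp.csr_matrix(rng.multinomial(n_tokens[start:stop], p)))
    counts = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, V))

    users = pd.DataFrame(
        {
            "user_id": [f"u{i:07d}" for i in range(U)],
            "county_id": county_ids[county_row],
            "year": rng.integers(year_span[0], year_span[1] + 1, size=U),
            "tweet_count": rng.integers(tw_lo, tw_hi + 1, size=U),
        }
    )
    tokens = UserTokenCounts(
        counts=counts, vocabulary=topic_model.topic_lexicon.vocabulary, users=users
    )
    truth = GroundTruth(
        county_ids=county_ids,
        z=z,
        theta=theta,
        delta=float(delta),
        kappa=float(kappa),
        signal_topics=dict(topic_model.signal_topics),
        seed=int(seed),
    )
    return tokens, truth


def generate_outcome(
    ground_truth: GroundTruth,
    covariates: Sequence[CovariateSpec] | None = None,
    self_reports: Sequence[CovariateSpec] | None = None,
    population: PopulationSpec | None = None,
    seed: int = 0,
    gamma: float = 5.0,
    noise_sd: float = 5.0,
    mu: float = 40.0,
    waves: Sequence[WaveParams] | None = None,
) -> pd.DataFrame:
    """Draw the county outcome/covariate table from the latent factor.

    Mortality rate (per 100,000): ``y = mu + gamma*z + sum_j w_j x_j + eps``
    truncated at 0; death count = round(rate * population / 1e5).  The
    theoretical language-explainable variance fraction — the R^2 of the best
    predictor of y that sees only z — is recorded in the ground truth.
    """
    if ground_truth.z is None or len(ground_truth.z) == 0:
        raise ValueError("ground truth carries no latent county factor z")
    covariates = list(default_covariates() if covariates is None else covariates)
    self_reports = list(default_self_reports() if self_reports is None else self_reports)
    population = population or PopulationSpec()
    rng = np.random.default_rng(seed)
    z = ground_truth.z
    C = len(z)

    table = pd.DataFrame({"county_id": ground_truth.county_ids})
    lin = np.zeros(C)
    effects: dict[str, tuple[float, float]] = {}
    total_aw = 0.0
    total_w2 = 0.0
    for spec in covariates + self_reports:
        x = spec.loading * z + rng.standard_normal(C)
        table[spec.name] = x
        lin += spec.weight * x
        effects[spec.name] = (spec.loading, spec.weight)
        total_aw += spec.weight * spec.loading
        total_w2 += spec.weight**2

    log10_pop = rng.uniform(*population.log10_range, size=C)
    pop = np.round(10.0**log10_pop).astype(int)
    table["population"] = pop
    table["n_reports"] = rng.poisson(population.report_rate * pop)

    eps = rng.normal(0.0, noise_sd, size=C)
    rate = np.clip(mu + gamma * z + lin + eps, 0.0, None)
    table["mortality_rate"] = rate
    table["death_count"] = np.round(rate * pop / 1e5).astype(int)

    for wave in waves or []:
        w_eps = rng.normal(0.0, wave.noise_sd, size=C)
        w_rate = np.clip(wave.mu + wave.gamma * z + lin + w_eps, 0.0, None)
        table[f"rate_{wave.label}"] = w_rate
        table[f"deaths_{wave.label}"] = np.round(w_rate * pop / 1e5).astype(int)

    signal = gamma + total_aw
    var_y = signal**2 + total_w2 + noise_sd**2
    ground_truth.gamma = float(gamma)
    ground_truth.mu = float(mu)
    ground_truth.noise_sd = float(noise_sd)
    ground_truth.covariate_effects = effects
    ground_truth.r2_language = float(signal**2 / var_y) if var_y > 0 else 0.0
    return table


# ---------------------------------------------------------------------------
# one-call study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Defaults define the desk-scale benchmark study conditions."""

    C: int = 600
    K: int = 50
    V: int = 2000
    concentration: float = 0.3
    n_signal: int = 10
    users_per_county: tuple[int, int] = (20, 25)
    tokens_per_user: tuple[int, int] = (300, 600)
    tweets_per_user: tuple[int, int] = (30, 120)
    year_span: tuple[int, int] = (2009, 2019)
    delta: float = 1.0
    kappa: float = 30.0
    gamma: float = 5.0
    noise_sd: float = 5.0
    mu: float = 40.0
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    self_reports: list[CovariateSpec] = field(default_factory=default_self_reports)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    waves: list[WaveParams] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    topic_model: TopicModel
    tokens: UserTokenCounts
    ground_truth: GroundTruth
    county_table: pd.DataFrame

    def manifest(self, config: SimulationConfig) -> dict:
        return {"config": config.to_dict(), "ground_truth": self.ground_truth.manifest()}


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SimulationResult:
    """Run the full generator: topic model, counties/users/tokens, outcomes.

    Sub-stage seeds are derived deterministically from ``seed`` so each stage
    has an independent stream.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    topic_model = generate_topic_model(
        K=config.K,
        V=config.V,
        concentration=config.concentration,
        n_signal=config.n_signal,
        seed=sub[0],
    )
    tokens, truth = generate_counties(
        C=config.C,
        users_per_county=config.users_per_county,
        tokens_per_user=config.tokens_per_user,
        tweets_per_user=config.tweets_per_user,
        topic_model=topic_model,
        delta=config.delta,
        kappa=config.kappa,
        seed=sub[1],
        year_span=config.year_span,
    )
    county_table = generate_outcome(
        truth,
        covariates=config.covariates,
        self_reports=config.self_reports,
        population=config.population,
        seed=sub[2],
        gamma=config.gamma,
        noise_sd=config.noise_sd,
        mu=config.mu,
        waves=config.waves,
    )
    return SimulationResult(
        topic_model=topic_model, tokens=tokens, ground_truth=truth, county_table=county_table
    )
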