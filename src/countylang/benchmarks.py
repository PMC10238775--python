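"""Named benchmark study conditions and shared helpers.

These configurations define the desk-scale simulation studies used by the
validation suite and by ``scripts/acceptance.py``: they are the package's
frozen study conditions, not tuning knobs.  Thresholds are relaxed relative
to the full-scale analysis because the synthetic counties carry 20-25 users
each (the full-scale 100-user floor is exercised separately on crafted
fixtures).

* ``prediction_benchmark_config`` — language-explainable variance fraction
  0.5 (gamma = noise_sd = 5), so a perfect readout of the latent factor
  predicts at r = sqrt(0.5) ~= 0.707 out of sample.
* ``dla_benchmark_config`` — 10 signal topics among 200, outcome coupling
  chosen so the planted marginal standardized effect of a signal topic is
  ~0.3 at the benchmark's language fidelity; covariates are decoupled from
  the latent factor so the covariate-adjusted effect equals the marginal.
* ``fusion_benchmark_config`` — language and covariates carry partially
  independent signal (covariates load weakly on the latent factor but have
  their own direct outcome effects), so the fused model should beat either
  component model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aggregate
from .synth import CovariateSpec, SimulationConfig, SimulationResult, simulate_study

#: thresholds used with the desk-scale generator (20-25 users per county)
RELAXED = dict(min_users=5, min_tweets=1, min_reports=0, min_deaths=0)


def prediction_benchmark_config() -> SimulationConfig:
    return SimulationConfig()  # defaults: C=600, K=50, V=2000, R^2_lang = 0.5


def dla_benchmark_config() -> SimulationConfig:
    covariates = [CovariateSpec(f"cov_{j}", "demographics", 0.0, 0.0) for j in range(5)]
    return SimulationConfig(
        C=600,
        K=200,
        V=2000,
        n_signal=10,
        covariates=covariates,
        self_reports=[],
        gamma=1.0,
        noise_sd=1.8,
        mu=40.0,
    )


def fusion_benchmark_config() -> SimulationConfig:
    covariates = [
        CovariateSpec("cov_a", "socioeconomics", 0.5, 2.5),
        CovariateSpec("cov_b", "socioeconomics", 0.5, 2.5),
        CovariateSpec("cov_c", "socioeconomics", 0.5, 2.5),
        CovariateSpec("cov_d", "demographics", 0.0, 0.0),
        CovariateSpec("cov_e", "demographics", 0.0, 0.0),
    ]
    return SimulationConfig(
        C=600, K=50, V=2000, n_signal=10, covariates=covariates,
        self_reports=[], gamma=4.0, noise_sd=4.0, mu=40.0,
    )


def analysis_study_config() -> SimulationConfig:
    """The full desk-scale study driven by the analysis/ scripts: the
    prediction benchmark conditions plus per-wave mortality rates (the
    later-wave coupling grows, emulating an intensifying epidemic)."""
    from .synth import WaveParams

    cfg = SimulationConfig()
    cfg.waves = [
        WaveParams("wave2", mu=35.0, gamma=3.0, noise_sd=5.0),
        WaveParams("wave3", mu=45.0, gamma=6.0, noise_sd=5.0),
    ]
    return cfg


def simulate_analysis_table(
    config: SimulationConfig, seed: int
) -> tuple[SimulationResult, pd.DataFrame]:
    """Simulate a study and build its assembled analysis table."""
    sim = simulate_study(config, seed=seed)
    uf = aggregate.user_relative_frequencies(sim.tokens)
    cwf = aggregate.county_word_frequencies(
        uf, min_users=RELAXED["min_users"], min_tweets=RELAXED["min_tweets"]
    )
    loadings = aggregate.project_topics(cwf, sim.topic_model.topic_lexicon)
    table = aggregate.assemble_analysis_table(
        loadings,
        sim.county_table,
        min_reports=RELAXED["min_reports"],
        min_deaths=RELAXED["min_deaths"],
    )
    return sim, table


def latent_factor(sim: SimulationResult, table: pd.DataFrame) -> pd.Series:
    """Ground-truth z aligned to an analysis table's county index."""
    z = pd.Series(sim.ground_truth.z, index=sim.ground_truth.county_ids)
    return z.loc[table.index]


def covariate_names(config: SimulationConfig) -> list[str]:
    return [s.name for s in list(config.covariates) + list(config.self_reports)]
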