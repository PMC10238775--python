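"""End-to-end driver: simulate -> aggregate -> predict -> dla -> baselines -> waves.

All randomness flows from the global seed through documented per-stage
substreams (``stage_seed``: seed + a stable CRC32 hash of the stage name,
reduced mod 2^31), so inserting or re-running one stage never shifts
another's draws.  Every run directory is self-describing: ``manifest.json``
echoes the resolved configuration, package version, and simulation ground
truth.  Output files carry no timestamps, so identical (config, seed) runs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, aggregate, dla
from .baselines import (
    VariableCatalog,
    category_cv,
    controlled_association,
    univariate_correlations,
)
from .config import RunConfig
from .io import write_json, write_table
from .predict import compare_models, cross_validate
from .synth import simulate_study
from .waves import WaveSpec, wave_outcomes, wave_slice, wave_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "aggregate", "predict", "dla", "baselines", "waves")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed substream."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the artifact directory.

    A stage failure propagates with the stage name; artifacts written by
    earlier stages persist.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        # ------------------------------------------------------------- simulate
        sim = simulate_study(config.simulate, seed=stage_seed(config.seed, "simulate"))
        write_table(sim.tokens.to_frame(), out / "tokens.tsv", sep="\t")
        write_table(sim.tokens.users, out / "users.tsv", sep="\t")
        write_table(sim.county_table, out / "county_table.csv")
        sim.topic_model.topic_lexicon.to_csv(out / "topic_lexicon.csv")
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "ground_truth": sim.ground_truth.manifest(),
        }
        write_json(manifest, out / "manifest.json")

        # ------------------------------------------------------------ aggregate
        stage = "aggregate"
        agg = config.aggregate
        uf = aggregate.user_relative_frequencies(sim.tokens)
        cwf = aggregate.county_word_frequencies(
            uf, min_users=agg.min_users, min_tweets=agg.min_tweets
        )
        write_table(cwf.to_frame(), out / "county_word_freq.csv")
        loadings = aggregate.project_topics(cwf, sim.topic_model.topic_lexicon)
        long = loadings.stack().rename("loading").reset_index()
        long.columns = ["county_id", "topic", "loading"]
        write_table(long, out / "county_topics.csv")
        table = aggregate.assemble_analysis_table(
            loadings,
            sim.county_table,
            min_reports=agg.min_reports,
            min_deaths=agg.min_deaths,
        )

        # -------------------------------------------------------------- predict
        stage = "predict"
        pcfg = dataclasses.replace(config.predict, seed=stage_seed(config.seed, "predict"))
        topic_cols = aggregate.topic_columns(table)
        catalog = VariableCatalog.from_specs(
            list(config.simulate.covariates) + list(config.simulate.self_reports)
        )
        covar_cols = catalog.variables()
        y = table["mortality_rate"].astype(float)
        lang = table[topic_cols]
        covs = table[covar_cols]
        models = {
            "twitter": cross_validate(lang, y, pcfg),
            "all_nonlanguage": cross_validate(None, y, pcfg, covariates=covs),
            "twitter_plus_all": cross_validate(lang, y, pcfg, covariates=covs),
        }
        write_json({k: v.to_dict() for k, v in models.items()}, out / "cv_result.json")
        comparisons = {}
        for a, b in [("twitter", "all_nonlanguage"), ("twitter_plus_all", "twitter"),
                     ("twitter_plus_all", "all_nonlanguage")]:
            t, p = compare_models(models[a], models[b], y)
            comparisons[f"{a}_vs_{b}"] = {"t": t, "p": p}
        write_json(comparisons, out / "comparisons.json")

        # ------------------------------------------------------------------ dla
        stage = "dla"
        sociodem = catalog.variables("demographics") + catalog.variables("socioeconomics")
        results = dla.run_dla(
            table[topic_cols].rename(columns=lambda c: int(c.removeprefix("topic_"))),
            y,
            covariates=table[sociodem],
            q_star=config.dla.q_star,
        )
        write_table(results, out / "dla_results.csv")
        clouds = dla.export_topic_clouds(
            results, sim.topic_model.topic_lexicon, top_n=config.dla.top_n
        )
        for sign, topics in clouds.items():
            for topic, words in topics.items():
                write_table(words, out / "clouds" / sign / f"topic_{topic}.csv")

        # ------------------------------------------------------------ baselines
        stage = "baselines"
        uni = univariate_correlations(table, "mortality_rate", catalog)
        write_table(uni, out / "univariate.csv")
        cat_rows = []
        for cat in sorted(set(catalog.categories.values())) + ["all"]:
            cv = category_cv(table, "mortality_rate", catalog, cat, pcfg)
            cat_rows.append(
                {"category": cat, "pooled_r": cv.pooled_r, "fold_se": cv.fold_se,
                 "mae": cv.mae, "mse": cv.mse}
            )
        write_table(pd.DataFrame(cat_rows), out / "category_cv.csv")
        ctrl_rows = []
        for var in covar_cols:
            controls = [c for c in covar_cols if c != var]
            beta, p = controlled_association(table[var], y, table[controls])
            ctrl_rows.append({"variable": var, "beta": beta, "p": p})
        write_table(pd.DataFrame(ctrl_rows), out / "controlled.csv")

        # ---------------------------------------------------------------- waves
        stage = "waves"
        if config.waves.enabled and {"rate_wave2", "rate_wave3"} <= set(sim.county_table.columns):
            spec = WaveSpec(
                waves={"wave2": config.waves.wave2, "wave3": config.waves.wave3},
                min_users=config.waves.min_users or agg.min_users,
                min_tweets=config.waves.min_tweets or agg.min_tweets,
            )
            cwf2 = wave_slice(sim.tokens, spec, "wave2")
            loadings2 = aggregate.project_topics(cwf2, sim.topic_model.topic_lexicon)
            outcomes = wave_outcomes(sim.county_table)
            shared = loadings2.index.intersection(outcomes.index)
            predictors = sim.county_table.set_index("county_id").loc[shared, covar_cols]
            wcfg = dataclasses.replace(pcfg, seed=stage_seed(config.seed, "waves"))
            wt = wave_table(
                predictors,
                outcomes.loc[shared],
                language_blocks={
                    "twitter": (loadings2.loc[shared], None),
                    "all": (predictors, None),
                    "twitter_plus_all": (loadings2.loc[shared], predictors),
                },
                config=wcfg,
            )
            wt["ci_wave3"] = wt["ci_wave3"].map(lambda t: f"[{t[0]:.3f}, {t[1]:.3f}]")
            wt["ci_delta"] = wt["ci_delta"].map(lambda t: f"[{t[0]:.3f}, {t[1]:.3f}]")
            write_table(wt, out / "wave_table.csv")
    except Exception:
        logger.error("pipeline failed in stage %r; partial artifacts kept in %s", stage, out)
        raise
    return out
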