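#!/usr/bin/env python
"""Cross-validated prediction: language vs covariates vs fused.

Fits the feature-selection / PCA / ridge stack under 10-fold CV for three
models — topic loadings alone, all non-language covariates, and their fusion
— and compares them by a paired t-test on absolute out-of-sample errors.
"""

import argparse
from pathlib import Path

import pandas as pd

from countylang import aggregate, benchmarks, predict
from countylang.io import read_json, write_json, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
parser.add_argument("--folds", type=int, default=10)
args = parser.parse_args()

seed = read_json(args.out / "manifest.json")["seed"]
config = benchmarks.analysis_study_config()
county = pd.read_csv(args.out / "county_table.csv", dtype={"county_id": str})
long = pd.read_csv(args.out / "county_topics.csv", dtype={"county_id": str})
loadings = long.pivot(index="county_id", columns="topic", values="loading")

table = aggregate.assemble_analysis_table(
    loadings, county,
    min_reports=benchmarks.RELAXED["min_reports"],
    min_deaths=benchmarks.RELAXED["min_deaths"],
)
y = table["mortality_rate"].astype(float)
lang = table[aggregate.topic_columns(table)]
covs = table[benchmarks.covariate_names(config)]
pcfg = predict.PipelineConfig(seed=seed, k_folds=args.folds)

models = {
    "twitter": predict.cross_validate(lang, y, pcfg),
    "all_nonlanguage": predict.cross_validate(None, y, pcfg, covariates=covs),
    "twitter_plus_all": predict.cross_validate(lang, y, pcfg, covariates=covs),
}
rows = [
    {"model": name, "pooled_r": cv.pooled_r, "fold_se": cv.fold_se,
     "spearman_rho": cv.spearman_rho, "mae": cv.mae, "mse": cv.mse}
    for name, cv in models.items()
]
write_table(pd.DataFrame(rows), args.out / "cv_metrics.csv")

comparisons = {}
for a, b in [("twitter", "all_nonlanguage"), ("twitter_plus_all", "twitter"),
             ("twitter_plus_all", "all_nonlanguage")]:
    t, p = predict.compare_models(models[a], models[b], y)
    comparisons[f"{a}_vs_{b}"] = {"t": t, "p": p}
write_json(comparisons, args.out / "comparisons.json")

print(f"{len(table)} counties, {args.folds}-fold CV")
for row in rows:
    print(f"  {row['model']:>18}: pooled r = {row['pooled_r']:.3f} "
          f"(fold SE {row['fold_se']:.3f}), MAE {row['mae']:.2f} per 100k")
for name, c in comparisons.items():
    print(f"  {name}: t = {c['t']:.2f}, p = {c['p']:.2e}")
print(f"wrote cv_metrics.csv and comparisons.json to {args.out}")
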