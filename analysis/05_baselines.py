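#!/usr/bin/env python
"""Non-language baselines: univariate correlations and category-level CV.

Computes per-variable Pearson/Spearman correlations with mortality (BH
corrected, one family), then the out-of-sample accuracy of each covariate
category as a multiple-regression block, and the all-categories model.
"""

import argparse
from pathlib import Path

import pandas as pd

from countylang import aggregate, benchmarks
from countylang.baselines import VariableCatalog, category_cv, univariate_correlations
from countylang.io import read_json, write_table
from countylang.predict import PipelineConfig

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
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

catalog = VariableCatalog.from_specs(list(config.covariates) + list(config.self_reports))
uni = univariate_correlations(table, "mortality_rate", catalog)
write_table(uni, args.out / "univariate.csv")

pcfg = PipelineConfig(seed=seed)
rows = []
for cat in sorted(set(catalog.categories.values())) + ["all"]:
    cv = category_cv(table, "mortality_rate", catalog, cat, pcfg)
    rows.append({"category": cat, "pooled_r": cv.pooled_r, "fold_se": cv.fold_se})
cat_table = pd.DataFrame(rows).sort_values("pooled_r", ascending=False)
write_table(cat_table, args.out / "category_cv.csv")

top = uni.reindex(uni["pearson_r"].abs().sort_values(ascending=False).index).head(3)
print(f"univariate correlations over {len(uni)} variables "
      f"({int(uni['significant'].sum())} significant after BH):")
for _, r in top.iterrows():
    print(f"  {r['variable']:>20}: r = {r['pearson_r']:+.3f}{r['stars']}")
print("category out-of-sample accuracy:")
for _, r in cat_table.iterrows():
    print(f"  {r['category']:>20}: pooled r = {r['pooled_r']:.3f}")
print(f"wrote univariate.csv and category_cv.csv to {args.out}")
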