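#!/usr/bin/env python
"""Aggregate user token streams into county topic loadings.

Regenerates the token tables deterministically from the manifest seed, then
runs the fixed aggregation order — per-user normalization, unweighted
user-then-county averaging, lexicon projection onto topic loadings — with
the desk-scale inclusion thresholds.
"""

import argparse
from pathlib import Path

from countylang import aggregate, benchmarks
from countylang.io import read_json, write_table
from countylang.synth import simulate_study

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

seed = read_json(args.out / "manifest.json")["seed"]
sim = simulate_study(benchmarks.analysis_study_config(), seed=seed)

uf = aggregate.user_relative_frequencies(sim.tokens)
cwf = aggregate.county_word_frequencies(
    uf, min_users=benchmarks.RELAXED["min_users"],
    min_tweets=benchmarks.RELAXED["min_tweets"],
)
loadings = aggregate.project_topics(cwf, sim.topic_model.topic_lexicon)
long = loadings.stack().rename("loading").reset_index()
long.columns = ["county_id", "topic", "loading"]
write_table(long, args.out / "county_topics.csv")

print(f"aggregated {len(uf.users)} users into {len(cwf.county_ids)} counties")
print(f"  loadings sum to 1 per county: max deviation "
      f"{abs(loadings.sum(axis=1) - 1).max():.2e}")
print(f"wrote county_topics.csv ({len(long)} rows) to {args.out}")
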