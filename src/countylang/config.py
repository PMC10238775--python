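"""Run configuration: YAML-backed, strictly validated.

Unknown keys anywhere in the document are rejected before any stage runs;
every run writes a manifest echoing the resolved configuration and the
package version, which suffices to re-run the identical analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .predict import PipelineConfig
from .synth import CovariateSpec, PopulationSpec, SimulationConfig, WaveParams


@dataclass
class AggregateConfig:
    min_users: int = 100
    min_tweets: int = 30
    min_reports: int = 300
    min_deaths: int = 20


@dataclass
class DlaConfig:
    q_star: float = 0.05
    top_n: int = 12


@dataclass
class WavesConfig:
    enabled: bool = False
    wave2: tuple[int, int] = (2010, 2012)
    wave3: tuple[int, int] = (2013, 2019)
    # None -> inherit the aggregate-stage thresholds
    min_users: int | None = None
    min_tweets: int | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    aggregate: AggregateConfig = field(default_factory=AggregateConfig)
    predict: PipelineConfig = field(default_factory=PipelineConfig)
    dla: DlaConfig = field(default_factory=DlaConfig)
    waves: WavesConfig = field(default_factory=WavesConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_LIST_FIELDS = {
    "covariates": CovariateSpec,
    "self_reports": CovariateSpec,
    "waves_params": WaveParams,
}


def _build(cls, data: Any, path: str = ""):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        here = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in {
                "SimulationConfig", "AggregateConfig", "PipelineConfig",
                "DlaConfig", "WavesConfig", "PopulationSpec",
            }
        ):
            target = {
                "SimulationConfig": SimulationConfig,
                "AggregateConfig": AggregateConfig,
                "PipelineConfig": PipelineConfig,
                "DlaConfig": DlaConfig,
                "WavesConfig": WavesConfig,
                "PopulationSpec": PopulationSpec,
            }.get(f.type if isinstance(f.type, str) else f.type.__name__)
            kwargs[name] = _build(target, value, here)
        elif name in ("covariates", "self_reports"):
            kwargs[name] = [_build(CovariateSpec, v, f"{here}[{i}]") for i, v in enumerate(value)]
        elif name == "waves" and cls is SimulationConfig:
            kwargs[name] = [_build(WaveParams, v, f"{here}[{i}]") for i, v in enumerate(value)]
        elif isinstance(value, list) and name in (
            "users_per_county", "tokens_per_user", "tweets_per_user",
            "year_span", "wave2", "wave3", "log10_range",
        ):
            kwargs[name] = tuple(value)
        elif name == "lambda_grid":
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def demo_config(seed: int = 0) -> RunConfig:
    """Desk-scale end-to-end configuration (completes in minutes on one CPU)."""
    sim = SimulationConfig(
        C=150,
        K=20,
        V=500,
        n_signal=6,
        users_per_county=(20, 25),
        tokens_per_user=(200, 400),
        waves=[
            WaveParams("wave2", mu=35.0, gamma=4.0, noise_sd=5.0),
            WaveParams("wave3", mu=45.0, gamma=6.0, noise_sd=5.0),
        ],
    )
    return RunConfig(
        seed=seed,
        simulate=sim,
        aggregate=AggregateConfig(min_users=15, min_tweets=30, min_reports=200, min_deaths=10),
        predict=PipelineConfig(k_folds=10),
        waves=WavesConfig(enabled=True, min_users=3),
    )
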