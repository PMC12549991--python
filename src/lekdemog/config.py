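"""Run configuration: MCMC settings, selection thresholds, lag windows,
candidate scales, and paths, with YAML round-tripping.

Every pipeline run writes its fully resolved configuration (including the
seed) next to its outputs so that stochastic results are reproducible
bit-for-bit with the same sampler version.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .covariates import LAG_WINDOWS, LIFESTAGE_RADII_M, POPULATION_RADII_M
from .mcmc import MCMCConfig

__all__ = ["SelectionConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SelectionConfig:
    """Two-stage variable/scale selection knobs.

    ``grouping_threshold`` is the |correlation| at which covariates are
    grouped; ``screen_pd`` the stage-1 probability-of-direction retention
    threshold; ``lambda_bounds`` the Uniform hyperprior support of the
    Laplace shrinkage rate.
    """

    grouping_threshold: float = 0.65
    screen_pd: float = 0.80
    lambda_bounds: tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.grouping_threshold < 1.0:
            raise ValueError("grouping_threshold must lie in (0, 1)")
        if not 0.5 <= self.screen_pd <= 1.0:
            raise ValueError("screen_pd must lie in [0.5, 1]")


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    windows: dict = field(
        default_factory=lambda: {
            name: {
                "start": list(w.start_month_day),
                "end": list(w.end_month_day),
                "start_offset": w.start_offset,
                "end_offset": w.end_offset,
            }
            for name, w in LAG_WINDOWS.items()
        })
    scales: dict = field(
        default_factory=lambda: {
            "population_radii_m": list(POPULATION_RADII_M),
            "lifestage_radii_m": list(LIFESTAGE_RADII_M),
            "decay_alphas_m": list(LIFESTAGE_RADII_M),
        })
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        selection = dataclasses.asdict(self.selection)
        selection["lambda_bounds"] = list(selection["lambda_bounds"])
        return {
            "mcmc": dataclasses.asdict(self.mcmc),
            "selection": selection,
            "windows": self.windows,
            "scales": self.scales,
            "paths": self.paths,
        }


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcmc = MCMCConfig(**raw.get("mcmc", {}))
    sel_raw = dict(raw.get("selection", {}))
    if "lambda_bounds" in sel_raw:
        sel_raw["lambda_bounds"] = tuple(sel_raw["lambda_bounds"])
    selection = SelectionConfig(**sel_raw)
    cfg = RunConfig(mcmc=mcmc, selection=selection)
    if "windows" in raw:
        cfg.windows = raw["windows"]
    if "scales" in raw:
        cfg.scales = raw["scales"]
    cfg.paths = raw.get("paths", {})
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
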