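"""Pipeline configuration: one YAML document drives every stage."""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .core import PotentialGrid
from .errors import InvalidArgumentError
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    """End-to-end run parameters, grouped per stage.

    ``seed`` is the single root of all randomness; it overrides the
    simulation block's seed so one number controls the whole run.  If
    ``panel_path`` is set the simulation stage is skipped and traces are
    loaded from that CSV instead.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    panel_path: str | None = None
    truth_tree_path: str | None = None
    # preprocess
    normalization: str = "minmax"
    # fusion
    bins: int = 25
    density_grid_size: int = 50
    bandwidth: float | None = None  # None -> Scott's rule
    hot_threshold_quantile: float = 0.75
    # chemometrics
    n_components: int = 3
    feature_mode: str = "concatenate"
    # phylo
    metric: str = "euclidean"
    linkage: str = "average"
    k: int = 5
    # run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins < 2 or self.density_grid_size < 2:
            raise InvalidArgumentError("bins and density_grid_size must be >= 2")
        if not 0 < self.hot_threshold_quantile < 1:
            raise InvalidArgumentError("hot_threshold_quantile must lie in (0, 1)")
        if self.n_components < 1 or self.k < 1:
            raise InvalidArgumentError("n_components and k must be positive")
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @property
    def grid(self) -> PotentialGrid:
        return self.simulation.grid


def _grid_to_dict(grid: PotentialGrid) -> dict:
    return {"start": grid.start, "stop": grid.stop, "step": grid.step}


def to_yaml(config: PipelineConfig, path: str | os.PathLike) -> None:
    sim = dataclasses.asdict(config.simulation)
    sim["grid"] = _grid_to_dict(config.simulation.grid)
    doc = dataclasses.asdict(config)
    doc["simulation"] = sim
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def from_yaml(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim_doc = doc.pop("simulation", {}) or {}
    grid_doc = sim_doc.pop("grid", None)
    if grid_doc:
        sim_doc["grid"] = PotentialGrid(**grid_doc)
    known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_doc) - known_sim
    if unknown:
        raise InvalidArgumentError(f"unknown simulation key(s): {sorted(unknown)}")
    simulation = SimulationConfig(**sim_doc)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise InvalidArgumentError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(simulation=simulation, **doc)
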