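"""Declarative pipeline configuration (YAML key/value document).

All trial, simulation, crown, competition, model and evaluation settings
live in one structured file; CLI flags override the file. Unknown keys
are rejected so typos fail loudly, and every random stage references the
explicit top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .simulate import CHMParams, SimulationParams, TRAIT_DEFAULTS
from .trial import TrialDesignParams

__all__ = ["PipelineConfig", "load_config"]

_SECTIONS = {"seed", "output_dir", "trial", "simulation", "chm", "crowns",
             "competition", "models", "evaluation", "inputs"}


@dataclass
class CrownSettings:
    sigma: float = 1.5            # smoothing sigma, cells
    kernel: int = 3               # pit-closing structuring element
    min_distance: float = 1.5     # marker dominance window, metres
    min_height: float = 2.0       # marker height floor, metres
    crown_min_height: float = 1.0
    crown_apex_fraction: float = 0.3
    markers: str = "stems"        # 'stems' | 'auto'
    match_max_dist: float = 1.6   # metres, apex-to-stem matching


@dataclass
class CompetitionSettings:
    radius: Optional[float] = None  # None = auto from spacing and 20 neighbours
    connectivity: int = 4
    specs: list = field(default_factory=lambda: ["CVF_CIA_NA", "CVF_CIA_NB"])


@dataclass
class ModelSettings:
    families: list = field(default_factory=lambda: ["B", "BA", "BC", "BAC"])
    traits: list = field(default_factory=lambda: ["H", "DBH", "V", "D38", "A"])
    competition: str = "fixed"    # 'fixed' | 'random'
    n_starts: int = 1
    maxiter: int = 4000


@dataclass
class EvaluationSettings:
    bic_convention: str = "printed"


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "treeace_out"
    trial: TrialDesignParams = field(default_factory=TrialDesignParams)
    simulation: dict = field(default_factory=dict)   # trait -> SimulationParams
    mortality_rate: float = 0.1
    chm: CHMParams = field(default_factory=lambda: CHMParams(
        resolution=0.25, noise_sd=0.05, pit_rate=0.002))
    crowns: CrownSettings = field(default_factory=CrownSettings)
    competition: CompetitionSettings = field(default_factory=CompetitionSettings)
    models: ModelSettings = field(default_factory=ModelSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    inputs: dict = field(default_factory=dict)

    def trait_params(self) -> dict:
        params = dict(TRAIT_DEFAULTS)
        params.update(self.simulation)
        return params


def _build(cls, data: dict, what: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | None = None, overrides: dict | None = None
                ) -> PipelineConfig:
    """Load a YAML config file, applying ``overrides`` on top."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - _SECTIONS - {"mortality_rate"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    cfg = PipelineConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "output_dir" in raw:
        cfg.output_dir = str(raw["output_dir"])
    if "mortality_rate" in raw:
        cfg.mortality_rate = float(raw["mortality_rate"])
    if "trial" in raw:
        d = dict(raw["trial"] or {})
        if "replicate_arrangement" in d and d["replicate_arrangement"]:
            d["replicate_arrangement"] = tuple(d["replicate_arrangement"])
        cfg.trial = _build(TrialDesignParams, d, "trial")
    if "simulation" in raw:
        sims = {}
        for trait, d in (raw["simulation"] or {}).items():
            sims[trait] = _build(SimulationParams, dict(d), f"simulation.{trait}")
        cfg.simulation = sims
    if "chm" in raw:
        cfg.chm = _build(CHMParams, dict(raw["chm"] or {}), "chm")
    if "crowns" in raw:
        cfg.crowns = _build(CrownSettings, dict(raw["crowns"] or {}), "crowns")
    if "competition" in raw:
        cfg.competition = _build(CompetitionSettings,
                                 dict(raw["competition"] or {}), "competition")
    if "models" in raw:
        cfg.models = _build(ModelSettings, dict(raw["models"] or {}), "models")
    if "evaluation" in raw:
        cfg.evaluation = _build(EvaluationSettings,
                                dict(raw["evaluation"] or {}), "evaluation")
    if "inputs" in raw:
        cfg.inputs = dict(raw["inputs"] or {})
    return cfg
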