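"""Run configuration: one validated object drives the whole pipeline.

Defaults mirror the study design the pipeline emulates: a 126-species world
(66 narrow-niche, dispersal-limited species and 60 broad-niche, fully
dispersing species), 22 correlated environmental layers, and 180 floras
(3 basins x 6 decadal size classes x 10 per stratum) on a 100-ha-per-cell
grid.  The ``scaled()`` constructor yields the reduced world used for
multi-seed parameter-recovery runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["GuildConfig", "WorldConfig", "EngineConfig", "StackerConfig",
           "EvalConfig", "RunConfig"]


class GuildConfig(BaseModel):
    n_species: int = Field(ge=1)
    breadth_mean: float = Field(gt=0)
    breadth_cv: float = Field(default=0.25, ge=0)
    dispersal_fraction: float = Field(default=1.0, gt=0, le=1)
    suitability_cutoff: float = Field(default=0.2, gt=0, lt=1)
    n_niche_layers: int = Field(default=4, ge=1)
    occurrence_mix: tuple[float, float, float] = (0.1, 0.4, 0.5)
    optimum_quantiles: tuple[float, float] = (0.0, 1.0)

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "GuildConfig":
        if abs(sum(self.occurrence_mix) - 1.0) > 1e-9:
            raise ValueError("occurrence_mix must sum to 1")
        return self


class WorldConfig(BaseModel):
    n_rows: int = Field(default=200, ge=1)
    n_cols: int = Field(default=200, ge=1)
    cell_area_ha: float = Field(default=100.0, gt=0)
    n_basins: int = Field(default=3, ge=1)
    n_layers: int = Field(default=22, ge=2)
    layer_correlation: float = Field(default=0.6, ge=0, lt=1)
    smoothness: float = Field(default=8.0, gt=0)
    bias_strength: float = Field(default=0.5, ge=0)
    per_stratum: int = Field(default=10, ge=1)
    nondetection_prob: float = Field(default=0.0, ge=0, lt=1)
    guilds: dict[str, GuildConfig] = Field(
        default_factory=lambda: {
            "narrow": GuildConfig(
                n_species=66, breadth_mean=0.5, dispersal_fraction=0.5,
                optimum_quantiles=(0.7, 0.97),
            ),
            "broad": GuildConfig(
                n_species=60, breadth_mean=1.0, dispersal_fraction=1.0
            ),
        }
    )


class EngineConfig(BaseModel):
    beta0: float = Field(default=1.0, gt=0)
    min_background: int = Field(default=1000, ge=1)
    train_fraction: float = Field(default=0.7, gt=0, lt=1)
    threshold_percentile: float = Field(default=0.10, ge=0, lt=1)
    hinge: bool = True


class StackerConfig(BaseModel):
    min_suitable_cells: int = Field(default=1, ge=1)


class EvalConfig(BaseModel):
    ci_level: float = Field(default=0.95, gt=0, lt=1)


class RunConfig(BaseModel):
    world: WorldConfig = Field(default_factory=WorldConfig)
    engine: EngineConfig = Field(default_factory=EngineConfig)
    stacker: StackerConfig = Field(default_factory=StackerConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def scaled(cls) -> "RunConfig":
        """Reduced world for repeated-seed recovery runs: 30 species, 90 floras."""
        cfg = cls()
        cfg.world.guilds["narrow"].n_species = 15
        cfg.world.guilds["broad"].n_species = 15
        cfg.world.per_stratum = 5
        return cfg
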