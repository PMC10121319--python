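import numpy as np
import pytest

from enmstack.config import GuildConfig, RunConfig
from enmstack.grid import LandscapeGrid
from enmstack.simulate import EnvLayerSet, generate_environment


@pytest.fixture(scope="session")
def small_grid() -> LandscapeGrid:
    return LandscapeGrid(n_rows=20, n_cols=20, cell_area=100.0)


@pytest.fixture(scope="session")
def small_env(small_grid) -> EnvLayerSet:
    return generate_environment(small_grid, n_layers=4, smoothness=3.0, seed=7)


@pytest.fixture(scope="session")
def tiny_config() -> RunConfig:
    """A minutes-free world for end-to-end tests: 60x60 grid, 8 species."""
    cfg = RunConfig()
    cfg.world.n_rows = cfg.world.n_cols = 60
    cfg.world.n_layers = 6
    cfg.world.smoothness = 4.0
    cfg.world.per_stratum = 1
    cfg.world.guilds["narrow"] = GuildConfig(
        n_species=4, breadth_mean=0.5, dispersal_fraction=0.5,
        optimum_quantiles=(0.7, 0.97), occurrence_mix=(0.0, 0.5, 0.5),
    )
    cfg.world.guilds["broad"] = GuildConfig(
        n_species=4, breadth_mean=1.0, occurrence_mix=(0.0, 0.5, 0.5),
    )
    cfg.engine.min_background = 300
    return cfg


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    from enmstack.pipeline import run_analysis

    return run_analysis(tiny_config, seed=11)


def flat_env_from_values(values: np.ndarray, cell_area: float = 100.0) -> EnvLayerSet:
    """Single-layer environment on a 1 x n grid with the given cell values."""
    values = np.asarray(values, dtype=float).reshape(1, -1)
    grid = LandscapeGrid(n_rows=1, n_cols=values.shape[1], cell_area=cell_area,
                         n_basins=1)
    return EnvLayerSet(grid=grid, layers={"env01": values})
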