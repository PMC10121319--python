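"""Simulate a small virtual-species world and inspect its structure.

Builds an 80x80 landscape (100 ha cells, three basins) with 8 correlated
environmental layers, two guilds of virtual species, biased occurrence
records, and floras stratified by basin and decadal area class.
"""

import numpy as np

from enmstack.config import GuildConfig, RunConfig
from enmstack.pipeline import simulate_world

cfg = RunConfig()
cfg.world.n_rows = cfg.world.n_cols = 80
cfg.world.n_layers = 8
cfg.world.per_stratum = 2
cfg.world.guilds["narrow"] = GuildConfig(
    n_species=5, breadth_mean=0.5, dispersal_fraction=0.5,
    optimum_quantiles=(0.7, 0.97),
)
cfg.world.guilds["broad"] = GuildConfig(n_species=5, breadth_mean=1.0)

world = simulate_world(cfg, seed=1)

print(f"grid: {world.grid.n_rows}x{world.grid.n_cols} cells of "
      f"{world.grid.cell_area:.0f} ha, basins: {world.grid.basin_names}")
print(f"layers: {world.env.n_layers}, species: {len(world.species)}, "
      f"occurrence records: {len(world.occurrences)}")
print(f"floras: {len(world.floras)} "
      f"(3 basins x size classes x {cfg.world.per_stratum})")
print()
print("species_id   guild   |suitable| |occupied|  n_records")
for sp in world.species:
    n_occ = (world.occurrences["species_id"] == sp.species_id).sum()
    print(f"{sp.species_id:<12} {sp.guild:<7} {world.suitable[sp.species_id].size:>9}"
          f" {world.occupied[sp.species_id].size:>10} {n_occ:>10}")

# dispersal limitation: the narrow guild occupies only half its suitable area,
# which is the mechanism that makes stacked models overpredict its richness
narrow_frac = np.mean([
    world.occupied[s.species_id].size / max(world.suitable[s.species_id].size, 1)
    for s in world.species if s.guild == "narrow"
])
print(f"\nnarrow-guild occupied/suitable fraction: {narrow_frac:.2f} (target 0.5)")
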