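"""Synthetic-world generator: environments, species, occurrences, floras."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box as shapely_box

from enmstack.grid import LandscapeGrid
from enmstack.simulate import (
    EnvLayerSet,
    VirtualSpecies,
    cells_intersecting_rect,
    generate_environment,
    generate_floras,
    generate_guild,
    sample_occurrences,
    true_range,
    true_suitability,
)


def make_species(**kw) -> VirtualSpecies:
    defaults = dict(
        species_id="sp1",
        guild="narrow",
        niche_optimum={"env01": 0.0},
        niche_breadth={"env01": 1.0},
        suitability_cutoff=0.2,
        dispersal_fraction=1.0,
        target_n_occurrences=50,
    )
    defaults.update(kw)
    return VirtualSpecies(**defaults)


class TestGenerateEnvironment:
    def test_identity_target_gives_uncorrelated_layers(self):
        grid = LandscapeGrid(n_rows=200, n_cols=200)
        for seed in range(10):
            env = generate_environment(
                grid, n_layers=2, correlation_target=np.eye(2),
                smoothness=8.0, seed=seed,
            )
            a, b = (env.layers[n].ravel() for n in env.names)
            assert abs(np.corrcoef(a, b)[0, 1]) < 0.15

    def test_perfect_correlation_gives_affine_copies(self, small_grid):
        target = np.ones((2, 2))
        env = generate_environment(small_grid, 2, target, smoothness=3.0, seed=3)
        a, b = (env.layers[n].ravel() for n in env.names)
        slope, intercept, r, *_ = stats.linregress(a, b)
        assert abs(r) > 1 - 1e-9

    def test_same_seed_bit_identical(self, small_grid):
        e1 = generate_environment(small_grid, 3, seed=5)
        e2 = generate_environment(small_grid, 3, seed=5)
        for name in e1.names:
            np.testing.assert_array_equal(e1.layers[name], e2.layers[name])

    def test_indefinite_target_rejected(self, small_grid):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="definite"):
            generate_environment(small_grid, 2, bad, seed=0)

    def test_empirical_correlation_approaches_target(self):
        grid = LandscapeGrid(n_rows=200, n_cols=200)
        target = np.array([[1.0, 0.8], [0.8, 1.0]])
        env = generate_environment(grid, 2, target, smoothness=5.0, seed=1)
        a, b = (env.layers[n].ravel() for n in env.names)
        assert abs(np.corrcoef(a, b)[0, 1] - 0.8) < 0.1


class TestTrueSuitability:
    def test_closed_forms(self):
        from tests.conftest import flat_env_from_values

        env = flat_env_from_values([0.0, 1.0, 2.0])
        sp = make_species(niche_optimum={"env01": 0.0}, niche_breadth={"env01": 1.0})
        suit = true_suitability(sp, env).ravel()
        # optimum -> 1; one-sigma offset -> exp(-1/2); all within [0, 1]
        assert suit[0] == pytest.approx(1.0)
        assert suit[1] == pytest.approx(np.exp(-0.5))
        assert np.all((suit >= 0) & (suit <= 1))

    def test_product_over_layers(self, small_env):
        names = small_env.names[:2]
        sp = make_species(
            niche_optimum={n: 0.0 for n in names},
            niche_breadth={n: 1.0 for n in names},
        )
        suit = true_suitability(sp, small_env)
        expected = np.exp(
            -sum(small_env.layers[n] ** 2 for n in names) / 2.0
        )
        np.testing.assert_allclose(suit, expected)

    def test_missing_layer_named_in_error(self, small_env):
        sp = make_species(niche_optimum={"nope": 0.0}, niche_breadth={"nope": 1.0})
        with pytest.raises(KeyError, match="nope"):
            true_suitability(sp, small_env)


class TestTrueRange:
    def test_full_dispersal_occupies_all_suitable(self, small_env):
        sp = make_species(
            niche_optimum={small_env.names[0]: 0.0},
            niche_breadth={small_env.names[0]: 1.0},
            dispersal_fraction=1.0,
        )
        suitable, occupied = true_range(sp, small_env, seed=1)
        np.testing.assert_array_equal(suitable, occupied)

    def test_half_dispersal_takes_half_the_cells(self):
        # exactly 100 suitable cells in a 20x20 world
        grid = LandscapeGrid(n_rows=20, n_cols=20)
        values = np.full((20, 20), 10.0)
        values[:10, :10] = 0.0
        env = EnvLayerSet(grid=grid, layers={"env01": values})
        sp = make_species(dispersal_fraction=0.5)
        suitable, occupied = true_range(sp, env, seed=2)
        assert suitable.size == 100
        assert abs(occupied.size - 50) <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("frac", [0.3, 0.7, 1.0])
    def test_occupied_subset_of_suitable(self, small_env, seed, frac):
        sp = make_species(
            niche_optimum={small_env.names[0]: 0.0},
            niche_breadth={small_env.names[0]: 1.5},
            dispersal_fraction=frac,
        )
        suitable, occupied = true_range(sp, small_env, seed=seed)
        assert np.isin(occupied, suitable).all()

    def test_occupied_range_is_connected_when_grown_from_one_seed(self):
        # a single large suitable component: the flood fill never restarts,
        # so the occupied set must be 4-connected
        grid = LandscapeGrid(n_rows=15, n_cols=15)
        env = EnvLayerSet(grid=grid, layers={"env01": np.zeros((15, 15))})
        sp = make_species(dispersal_fraction=0.4)
        _, occupied = true_range(sp, env, seed=3)
        mask = np.zeros(grid.n_cells, dtype=bool)
        mask[occupied] = True
        from scipy import ndimage

        labeled, n_comp = ndimage.label(
            mask.reshape(15, 15), structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
        )
        assert n_comp == 1

    def test_no_suitable_cells_warns_and_returns_empty(self, small_env):
        sp = make_species(
            niche_optimum={small_env.names[0]: 100.0},
            niche_breadth={small_env.names[0]: 0.01},
        )
        with pytest.warns(UserWarning, match="no suitable cells"):
            suitable, occupied = true_range(sp, small_env, seed=1)
        assert suitable.size == 0 and occupied.size == 0


class TestSampleOccurrences:
    def test_all_points_inside_occupied_cells(self, small_grid):
        occupied = np.arange(40, 80)
        sp = make_species(target_n_occurrences=50)
        occ = sample_occurrences(sp, occupied, small_grid, seed=4)
        assert len(occ) == 50
        assert occ["cell_id"].isin(occupied).all()
        # jittered coordinates stay in the stated cell
        np.testing.assert_array_equal(
            small_grid.cell_of_xy(occ["x"].to_numpy(), occ["y"].to_numpy()),
            occ["cell_id"].to_numpy(),
        )

    def test_degenerate_bias_hits_one_cell(self, small_grid):
        occupied = np.arange(40, 80)
        bias = np.zeros(small_grid.n_cells)
        bias[55] = 1.0
        sp = make_species(target_n_occurrences=30)
        occ = sample_occurrences(sp, occupied, small_grid, bias_field=bias, seed=5)
        assert (occ["cell_id"] == 55).all()

    def test_cell_frequencies_follow_bias_weights(self, small_grid):
        occupied = np.arange(0, 20)
        weights = np.zeros(small_grid.n_cells)
        weights[occupied] = np.linspace(1, 3, 20)
        sp = make_species(target_n_occurrences=10_000)
        occ = sample_occurrences(sp, occupied, small_grid, bias_field=weights, seed=6)
        counts = occ["cell_id"].value_counts().reindex(occupied, fill_value=0)
        expected = weights[occupied] / weights[occupied].sum() * len(occ)
        assert stats.chisquare(counts.to_numpy(), expected).pvalue > 0.01

    def test_empty_range_yields_zero_rows(self, small_grid):
        sp = make_species()
        occ = sample_occurrences(sp, np.empty(0, dtype=int), small_grid, seed=1)
        assert len(occ) == 0

    def test_record_kind_mixture(self, small_grid):
        sp = make_species(target_n_occurrences=5000)
        occ = sample_occurrences(sp, np.arange(100), small_grid, seed=8)
        frac_keep = occ["record_kind"].isin(["specimen", "observation"]).mean()
        assert frac_keep == pytest.approx(0.9, abs=0.03)


def big_flora_grid() -> LandscapeGrid:
    # basin area 1.2e7 ha so even the 10^7 class fits untruncated
    return LandscapeGrid(n_rows=60, n_cols=60, cell_area=10_000.0)


class TestGenerateFloras:
    def test_full_stratification_yields_180(self):
        grid = big_flora_grid()
        floras = generate_floras(grid, {}, per_stratum=10, seed=1)
        assert len(floras) == 180
        per_class = pd.Series([f.size_class for f in floras]).value_counts()
        assert (per_class == 30).all()

    def test_one_per_stratum_yields_18(self):
        floras = generate_floras(big_flora_grid(), {}, per_stratum=1, seed=2)
        assert len(floras) == 18

    def test_areas_lie_in_their_class_interval(self):
        for f in generate_floras(big_flora_grid(), {}, per_stratum=3, seed=3):
            assert 10 ** (f.size_class - 1) < f.area_ha <= 10**f.size_class
            xmin, ymin, xmax, ymax = f.rect
            assert (xmax - xmin) * (ymax - ymin) / 1e4 == pytest.approx(f.area_ha)

    def test_flora_lies_within_one_basin(self):
        grid = big_flora_grid()
        for f in generate_floras(grid, {}, per_stratum=2, seed=4):
            b = grid.basin_names.index(f.basin)
            bx0, by0, bx1, by1 = grid.basin_extent(b)
            xmin, ymin, xmax, ymax = f.rect
            assert bx0 <= xmin and xmax <= bx1 + 1e-9
            assert by0 <= ymin and ymax <= by1 + 1e-9

    def test_reported_matches_brute_force_overlap(self):
        grid = big_flora_grid()
        rng = np.random.default_rng(5)
        occupied = {
            f"sp{i}": np.sort(rng.choice(grid.n_cells, size=200, replace=False))
            for i in range(6)
        }
        floras = generate_floras(grid, occupied, per_stratum=2, seed=6)
        cs = grid.cell_size
        for f in floras:
            poly = shapely_box(*f.rect)
            expected = set()
            for sp, cells in occupied.items():
                for cid in cells:
                    r, c = grid.rowcol(cid)
                    cell_poly = shapely_box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs)
                    inter = poly.intersection(cell_poly)
                    if inter.area > 1e-9 * poly.area:
                        expected.add(sp)
                        break
            assert f.reported_species == expected, f.flora_id

    def test_oversized_class_truncated_with_warning(self):
        grid = LandscapeGrid(n_rows=30, n_cols=30, cell_area=100.0)  # 3e4 ha/basin
        with pytest.warns(UserWarning, match="truncated|skipped"):
            floras = generate_floras(grid, {}, per_stratum=1, seed=7)
        assert all(f.area_ha <= grid.basin_area_ha(0) for f in floras)

    def test_nondetection_thins_reported_lists(self):
        grid = big_flora_grid()
        occupied = {f"sp{i}": np.arange(grid.n_cells) for i in range(40)}
        full = generate_floras(grid, occupied, per_stratum=1, seed=8)
        thinned = generate_floras(
            grid, occupied, per_stratum=1, seed=8, nondetection_prob=0.5
        )
        n_full = sum(len(f.reported_species) for f in full)
        n_thin = sum(len(f.reported_species) for f in thinned)
        assert n_full == 40 * 18
        assert 0 < n_thin < n_full


class TestGuildRoster:
    def test_narrow_guild_has_smaller_mean_breadth(self, small_env):
        narrow = generate_guild(
            small_env, "narrow", 10, seed=1, breadth_mean=0.5,
            dispersal_fraction=0.5, optimum_quantiles=(0.7, 0.97),
        )
        broad = generate_guild(small_env, "broad", 10, seed=1, breadth_mean=1.0)
        mean_b = lambda roster: np.mean(
            [b for sp in roster for b in sp.niche_breadth.values()]
        )
        assert mean_b(narrow) < mean_b(broad)

    def test_guild_shares_niche_layers(self, small_env):
        roster = generate_guild(small_env, "narrow", 5, seed=2)
        layer_sets = {tuple(sorted(sp.niche_optimum)) for sp in roster}
        assert len(layer_sets) == 1


class TestWorldReproducibility:
    def test_same_master_seed_same_world(self, tiny_config):
        from enmstack.pipeline import simulate_world

        w1 = simulate_world(tiny_config, seed=42)
        w2 = simulate_world(tiny_config, seed=42)
        pd.testing.assert_frame_equal(w1.occurrences, w2.occurrences)
        assert [f.flora_id for f in w1.floras] == [f.flora_id for f in w2.floras]
        assert all(
            np.array_equal(w1.occupied[s], w2.occupied[s]) for s in w1.occupied
        )
        for n in w1.env.names:
            np.testing.assert_array_equal(w1.env.layers[n], w2.env.layers[n])

    def test_dispersal_limitation_builds_in_overprediction(self, tiny_run):
        """Suitable-but-unoccupied area guarantees bbox suitability >= reports."""
        world, results = tiny_run
        suit_masks = {
            s: np.isin(np.arange(world.grid.n_cells), cells)
            for s, cells in world.suitable.items()
        }
        for f in world.floras:
            cells = cells_intersecting_rect(world.grid, f.rect)
            n_suitable_species = sum(
                1 for s, m in suit_masks.items() if m[cells].any()
            )
            assert n_suitable_species >= len(f.reported_species)
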