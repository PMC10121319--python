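"""Richness statistics: z coefficient, regressions, confusion, ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enmstack.curation import CuratedOccurrences
from enmstack.evaluate import (
    ConfusionCounts,
    ZRecord,
    assign_size_class,
    confusion_counts,
    fisher_ci,
    fit_regression,
    niche_breadth_summary,
    ratio_area_regression,
    sensitivity,
    species_area_scatter,
    specificity,
    z_coefficient,
)
from enmstack.simulate import FloraSpec
from enmstack.stacking import FloraPrediction


def make_flora(fid, area, reported=(), size_class=None):
    k = size_class if size_class is not None else max(2, int(np.ceil(np.log10(area))))
    side = np.sqrt(area * 1e4)
    return FloraSpec(
        flora_id=fid, rect=(0, 0, side, side), area_ha=area, basin="b",
        size_class=k, reported_species=frozenset(reported),
    )


def make_pred(fid, predicted, s_rep, n_models=10):
    return FloraPrediction(
        flora_id=fid, predicted_species=frozenset(predicted),
        s_rep_modeled=s_rep, n_cropped_models=n_models,
    )


class TestZCoefficient:
    def test_equal_richness_gives_zero(self):
        assert z_coefficient(7, 7, 2e4, 1e4) == 0.0

    def test_proportional_scaling_gives_one(self):
        for k in (2, 10, 3.7):
            assert z_coefficient(k * 5, 5, k * 1e4, 1e4) == pytest.approx(1.0)

    def test_formula_oracle(self):
        # z = [log 9 - log 2] / [log 5e4 - log 1e4] = log(4.5)/log(5)
        expected = np.log(4.5) / np.log(5.0)
        assert z_coefficient(9, 2, 5e4, 1e4) == pytest.approx(expected, abs=1e-12)

    def test_base_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sp, sr = rng.integers(1, 50, 2)
            af = rng.uniform(1e2, 1e5)
            ab = af * rng.uniform(1.1, 10)
            z10 = z_coefficient(sp, sr, ab, af)
            zln = (np.log(sp) - np.log(sr)) / (np.log(ab) - np.log(af))
            assert z10 == pytest.approx(zln, rel=1e-12)

    def test_na_conditions(self):
        assert np.isnan(z_coefficient(0, 5, 2e4, 1e4))
        assert np.isnan(z_coefficient(5, 0, 2e4, 1e4))
        assert np.isnan(z_coefficient(5, 5, 1e4, 1e4))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_coefficient(-1, 5, 2e4, 1e4)
        with pytest.raises(ValueError):
            z_coefficient(5, 5, 1e3, 1e4)  # bbox smaller than flora


class TestSpeciesAreaScatter:
    def test_rows_decompose_z(self):
        recs = [
            ZRecord("f1", 9, 2, 5e4, 1e4),
            ZRecord("f2", 5, 5, 2e4, 1e4),   # z = 0, kept
            ZRecord("f3", 0, 5, 2e4, 1e4),   # NA, dropped
        ]
        df = species_area_scatter(recs)
        assert list(df["flora_id"]) == ["f1", "f2"]
        row = df.iloc[0]
        assert row["dlog_richness"] / row["dlog_area"] == pytest.approx(recs[0].z)


class TestFitRegression:
    def test_perfect_line(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        reg = fit_regression(x, y)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_hand_ols_three_points(self):
        reg = fit_regression(np.array([0, 1, 2.0]), np.array([0, 1, 0.0]))
        assert reg.slope == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_r_squared_equals_r_squared_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.random(15)
            y = rng.random(15)
            reg = fit_regression(x, y)
            assert reg.r_squared == pytest.approx(reg.r**2, abs=1e-12)

    def test_zero_variance_gives_na_with_reason(self):
        reg = fit_regression(np.ones(5), np.arange(5.0))
        assert np.isnan(reg.slope) and reg.reason is not None


class TestFisherCI:
    def test_zero_r_truncated_at_zero(self):
        lo, hi = fisher_ci(0.0, 30)
        assert lo == 0.0
        assert hi == pytest.approx(np.tanh(stats.norm.ppf(0.975) / np.sqrt(27)))

    def test_closed_form_oracle(self):
        lo, hi = fisher_ci(0.9, 30)
        zeta = np.arctanh(0.9)
        half = stats.norm.ppf(0.975) / np.sqrt(27)
        assert lo == pytest.approx(np.tanh(zeta - half), abs=1e-12)
        assert hi == pytest.approx(np.tanh(zeta + half), abs=1e-12)
        assert (lo, hi) == (pytest.approx(0.797, abs=5e-3), pytest.approx(0.951, abs=5e-3))

    def test_width_shrinks_with_n(self):
        widths = [np.diff(fisher_ci(0.5, n))[0] for n in (10, 30, 100)]
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_r(self):
        assert fisher_ci(1.0, 30) == (1.0, 1.0)

    def test_interval_contains_r_after_truncation(self):
        for r in (0.1, 0.5, 0.95):
            lo, hi = fisher_ci(r, 25)
            assert lo <= r <= hi


class TestConfusion:
    def test_set_enumeration_oracle(self):
        roster = {f"s{i}" for i in range(1, 11)}
        pred = make_pred("f", {"s1", "s2", "s3", "s4", "s5"}, s_rep=4)
        flo = make_flora("f", 1e3, reported=("s4", "s5", "s6", "s7"))
        cc = confusion_counts(pred, flo, roster)
        assert (cc.a, cc.b, cc.c, cc.d) == (2, 3, 2, 3)
        assert cc.total == 10

    def test_perfect_prediction(self):
        roster = {"a", "b", "c"}
        pred = make_pred("f", roster, s_rep=3)
        flo = make_flora("f", 1e3, reported=tuple(roster))
        cc = confusion_counts(pred, flo, roster)
        assert sensitivity(cc) == 1.0
        assert np.isnan(specificity(cc))  # no unreported species to judge

    def test_sensitivity_formula_and_na_rule(self):
        assert sensitivity(ConfusionCounts("f", a=3, b=0, c=1, d=6)) == 0.75
        assert np.isnan(sensitivity(ConfusionCounts("f", a=0, b=5, c=0, d=5)))
        assert specificity(ConfusionCounts("f", a=0, b=5, c=0, d=5)) == 0.5

    def test_counts_restricted_to_roster(self):
        roster = {"a", "b"}
        pred = make_pred("f", {"a", "zzz"}, s_rep=1)
        flo = make_flora("f", 1e3, reported=("b", "yyy"))
        cc = confusion_counts(pred, flo, roster)
        assert cc.total == 2
        assert (cc.a, cc.b, cc.c, cc.d) == (0, 1, 1, 0)


class TestRatioRegression:
    def test_equal_richness_all_ratios_one(self):
        preds = [make_pred(f"f{i}", {f"s{j}" for j in range(4)}, s_rep=4) for i in range(5)]
        floras = {f"f{i}": make_flora(f"f{i}", 10 ** (2 + i % 3 + 0.5)) for i in range(5)}
        table, reg, summary = ratio_area_regression(preds, floras)
        assert (table["ratio_pred_over_rep"] == 1.0).all()
        assert summary["mean_ratio_pred_over_rep"] == 1.0
        assert reg.slope == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_ratios(self):
        preds = [
            make_pred("f1", {f"s{j}" for j in range(2)}, s_rep=1),  # ratio 2
            make_pred("f2", {f"s{j}" for j in range(8)}, s_rep=1),  # ratio 8
        ]
        floras = {f: make_flora(f, 1e3) for f in ("f1", "f2")}
        _, _, summary = ratio_area_regression(preds, floras)
        assert summary["mean_ratio_pred_over_rep"] == 5.0
        assert summary["pooled_ratio_pred_over_rep"] == 5.0

    def test_regression_matches_hand_ols(self):
        preds = [
            make_pred("f1", {"s1"}, s_rep=1),
            make_pred("f2", {"s1", "s2"}, s_rep=1),
            make_pred("f3", {"s1", "s2", "s3", "s4"}, s_rep=1),
        ]
        floras = {
            "f1": make_flora("f1", 1e2), "f2": make_flora("f2", 1e3),
            "f3": make_flora("f3", 1e4),
        }
        _, reg, _ = ratio_area_regression(preds, floras)
        x = np.log10([1e2, 1e3, 1e4])
        y = np.log10([1, 2, 4])
        expected = stats.linregress(x, y)
        assert reg.slope == pytest.approx(expected.slope)
        assert reg.r_squared == pytest.approx(expected.rvalue**2)

    def test_zero_richness_floras_excluded(self):
        preds = [make_pred("f1", set(), s_rep=3), make_pred("f2", {"s1"}, s_rep=0)]
        floras = {f: make_flora(f, 1e3) for f in ("f1", "f2")}
        table, reg, summary = ratio_area_regression(preds, floras)
        assert len(table) == 0 and reg is None and summary == {}


class TestAssignSizeClass:
    @pytest.mark.parametrize(
        "area,k",
        [(100.0, 2), (101.0, 3), (11.0, 2), (1e3, 3), (1e3 + 1, 4),
         (5e6, 7), (1e7, 7)],
    )
    def test_boundaries(self, area, k):
        assert assign_size_class(area) == k

    @pytest.mark.parametrize("area", [10.0, 5.0, 1.01e7])
    def test_out_of_range(self, area):
        with pytest.raises(ValueError):
            assign_size_class(area)


class TestNicheBreadthSummary:
    def test_identical_cells_mean_is_value(self, small_env):
        cells = np.array([7, 7, 7])
        cur = CuratedOccurrences("sp", cells, n_raw=3)
        df = niche_breadth_summary([cur], small_env, variables=[small_env.names[0]])
        expected = small_env.values_at(np.array([7]), [small_env.names[0]])[0, 0]
        assert df.iloc[0, 1] == pytest.approx(expected)

    def test_matches_bruteforce_average(self, small_env):
        rng = np.random.default_rng(2)
        cells = rng.choice(small_env.grid.n_cells, 25, replace=False)
        cur = CuratedOccurrences("sp", cells, n_raw=25)
        df = niche_breadth_summary([cur], small_env)
        for name in small_env.names:
            manual = np.mean([small_env.layers[name].ravel()[c] for c in np.unique(cells)])
            assert df.loc[0, name] == pytest.approx(manual)

    def test_unknown_variable_rejected(self, small_env):
        cur = CuratedOccurrences("sp", np.arange(3), n_raw=3)
        with pytest.raises(KeyError, match="bogus"):
            niche_breadth_summary([cur], small_env, variables=["bogus"])

    def test_broad_guild_spreads_wider_than_narrow(self, tiny_run):
        """Generalists' per-species means scatter more along their niche axes."""
        world, results = tiny_run
        spreads = {}
        for guild, res in results.items():
            sp0 = next(s for s in world.species if s.guild == guild)
            niche_layers = list(sp0.niche_optimum)
            spreads[guild] = res.niche_breadth[niche_layers].std().mean()
        assert spreads["broad"] > spreads["narrow"]
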