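"""End-to-end orchestration: simulate -> curate/fit -> stack -> evaluate.

Each guild is analysed separately (its own target-group background, its own
stacked predictions and confusion matrices), mirroring the separate
treatment of ecologically contrasting taxon groups.  A *parameter-recovery
study* repeats the whole pipeline over several master seeds on the scaled
world and summarises the patterns the analysis is meant to recover:
richness regressions strengthening with flora size, guild-contrasted
sensitivity/specificity, systematic overprediction for the
dispersal-limited guild, and test omission inside the tolerable band.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .config import RunConfig
from .curation import (
    CATEGORY_EXCLUDED,
    CATEGORY_TRAIN_TEST,
    CuratedOccurrences,
    build_background,
    dedupe_to_cells,
    filter_records,
    split_train_test,
)
from .evaluate import (
    RegressionSummary,
    ZRecord,
    build_z_records,
    confusion_counts,
    niche_breadth_summary,
    ratio_area_regression,
    regressions_by_size_class,
    sensitivity,
    specificity,
)
from .grid import LandscapeGrid
from .maxent import (
    MaxentModel,
    binarize,
    fit_maxent,
    omission_error,
    predict_suitability,
    ten_percentile_threshold,
)
from .simulate import (
    EnvLayerSet,
    FloraSpec,
    VirtualSpecies,
    collection_bias_field,
    generate_environment,
    generate_floras,
    generate_guild,
    sample_occurrences,
    true_range,
)
from .stacking import FloraPrediction, bounding_box, stack_richness

logger = logging.getLogger(__name__)

__all__ = [
    "World",
    "GuildResult",
    "simulate_world",
    "analyze_guild",
    "run_analysis",
    "run_pipeline",
    "parameter_recovery_study",
]


# ---------------------------------------------------------------------------
# world simulation
# ---------------------------------------------------------------------------


@dataclass
class World:
    """A simulated study system with complete ground truth."""

    grid: LandscapeGrid
    env: EnvLayerSet
    species: list[VirtualSpecies]
    suitable: dict[str, np.ndarray]
    occupied: dict[str, np.ndarray]
    occurrences: pd.DataFrame
    floras: list[FloraSpec]
    bias: np.ndarray
    seed: int


def simulate_world(config: RunConfig, seed: int) -> World:
    """Generate the full synthetic world from one master seed."""
    w = config.world
    grid = LandscapeGrid(
        n_rows=w.n_rows, n_cols=w.n_cols, cell_area=w.cell_area_ha,
        n_basins=w.n_basins,
    )
    idx = np.arange(w.n_layers)
    corr = w.layer_correlation ** np.abs(idx[:, None] - idx[None, :])
    env = generate_environment(
        grid, n_layers=w.n_layers, correlation_target=corr,
        smoothness=w.smoothness, seed=seed,
    )
    species: list[VirtualSpecies] = []
    offset = 0
    for guild_name, g in w.guilds.items():
        species.extend(
            generate_guild(
                env,
                guild_name,
                g.n_species,
                seed,
                n_niche_layers=g.n_niche_layers,
                breadth_mean=g.breadth_mean,
                breadth_cv=g.breadth_cv,
                dispersal_fraction=g.dispersal_fraction,
                suitability_cutoff=g.suitability_cutoff,
                occurrence_mix=g.occurrence_mix,
                optimum_quantiles=g.optimum_quantiles,
                index_offset=0,
            )
        )
        offset += g.n_species
    bias = collection_bias_field(grid, seed, strength=w.bias_strength)
    suitable, occupied = {}, {}
    tables = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty ranges are tolerated here
        for i, sp in enumerate(species):
            s, o = true_range(sp, env, seed=seed, species_index=i)
            suitable[sp.species_id], occupied[sp.species_id] = s, o
            tables.append(
                sample_occurrences(sp, o, grid, bias, seed=seed, species_index=i)
            )
        occurrences = pd.concat(tables, ignore_index=True)
        floras = generate_floras(
            grid, occupied, per_stratum=w.per_stratum, seed=seed,
            nondetection_prob=w.nondetection_prob,
        )
    return World(
        grid=grid, env=env, species=species, suitable=suitable,
        occupied=occupied, occurrences=occurrences, floras=floras,
        bias=bias, seed=seed,
    )


# ---------------------------------------------------------------------------
# per-guild analysis
# ---------------------------------------------------------------------------


@dataclass
class GuildResult:
    """Everything the pipeline computes for one guild."""

    guild: str
    curated: dict[str, CuratedOccurrences]
    background: np.ndarray
    models: dict[str, MaxentModel]
    binary_maps: dict[str, np.ndarray]
    eval_records: pd.DataFrame
    predictions: list[FloraPrediction]
    bbox_areas: dict[str, float]
    z_records: list[ZRecord]
    regressions: list[RegressionSummary]
    confusion: pd.DataFrame
    ratio_table: pd.DataFrame
    ratio_regression: RegressionSummary | None
    ratio_summary: dict[str, float]
    niche_breadth: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_guild(
    guild: str,
    world: World,
    config: RunConfig,
    curated_all: dict[str, CuratedOccurrences],
) -> GuildResult:
    """Fit, threshold, stack and evaluate all modelled species of one guild."""
    eng, stk = config.engine, config.stacker
    guild_ids = [sp.species_id for sp in world.species if sp.guild == guild]
    roster = [curated_all[s] for s in guild_ids if s in curated_all]
    background = build_background(
        roster, world.grid, world.env,
        min_background=eng.min_background, seed=world.seed,
    )
    models: dict[str, MaxentModel] = {}
    binary_maps: dict[str, np.ndarray] = {}
    eval_rows = []
    for cur in roster:
        if cur.category == CATEGORY_EXCLUDED:
            logger.info("species %s excluded (%d unique cells)",
                        cur.species_id, cur.n_kept)
            continue
        train, test = split_train_test(
            cur, seed=world.seed, train_fraction=eng.train_fraction
        )
        model = fit_maxent(
            train, background, world.env,
            beta0=eng.beta0, species_id=cur.species_id, hinge=eng.hinge,
        )
        model.test_cells = test
        smap = predict_suitability(model, world.env)
        flat = smap.values.ravel()
        model.threshold = ten_percentile_threshold(
            flat[train], percentile=eng.threshold_percentile
        )
        bmap = binarize(smap, model.threshold)
        models[cur.species_id] = model
        binary_maps[cur.species_id] = bmap
        train_om = omission_error(bmap, train)
        test_om = omission_error(bmap, test) if test.size else np.nan
        eval_rows.append(
            {
                "species_id": cur.species_id,
                "guild": guild,
                "category": cur.category,
                "n_raw": cur.n_raw,
                "n_kept": cur.n_kept,
                "n_train": train.size,
                "n_test": test.size,
                "train_omission": train_om,
                "test_omission": test_om,
            }
        )
    eval_records = pd.DataFrame(eval_rows)

    floras = {f.flora_id: f for f in world.floras}
    predictions, bbox_areas = [], {}
    for f in world.floras:
        box = bounding_box(f, world.grid)
        bbox_areas[f.flora_id] = box.area_ha
        predictions.append(
            stack_richness(
                binary_maps, f, world.grid,
                min_suitable_cells=stk.min_suitable_cells, box=box,
            )
        )

    z_records = build_z_records(predictions, floras, bbox_areas)
    regressions = regressions_by_size_class(predictions, floras)
    conf_rows = []
    roster_ids = set(models)
    for p in predictions:
        cc = confusion_counts(p, floras[p.flora_id], roster_ids)
        conf_rows.append(
            {
                "flora_id": p.flora_id,
                "size_class": floras[p.flora_id].size_class,
                "area_ha": floras[p.flora_id].area_ha,
                "a": cc.a, "b": cc.b, "c": cc.c, "d": cc.d,
                "sensitivity": sensitivity(cc),
                "specificity": specificity(cc),
            }
        )
    confusion = pd.DataFrame(conf_rows)
    ratio_table, ratio_reg, ratio_summary = ratio_area_regression(predictions, floras)
    breadth = niche_breadth_summary(
        [c for c in roster if c.category != CATEGORY_EXCLUDED], world.env
    )
    return GuildResult(
        guild=guild,
        curated={c.species_id: c for c in roster},
        background=background,
        models=models,
        binary_maps=binary_maps,
        eval_records=eval_records,
        predictions=predictions,
        bbox_areas=bbox_areas,
        z_records=z_records,
        regressions=regressions,
        confusion=confusion,
        ratio_table=ratio_table,
        ratio_regression=ratio_reg,
        ratio_summary=ratio_summary,
        niche_breadth=breadth,
    )


def run_analysis(config: RunConfig, seed: int) -> tuple[World, dict[str, GuildResult]]:
    """Simulate one world and run the full analysis for every guild."""
    world = simulate_world(config, seed)
    filtered = filter_records(world.occurrences)
    curated = dedupe_to_cells(filtered, world.grid, world.env)
    results = {
        guild: analyze_guild(guild, world, config, curated)
        for guild in config.world.guilds
    }
    return world, results


# ---------------------------------------------------------------------------
# artifact-writing pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, seed: int, outdir: Path | str) -> dict:
    """Run the whole analysis and write all artifacts plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world, results = run_analysis(config, seed)

    config.to_yaml(outdir / "config.yaml")
    eio.write_env(outdir / "env", world.env)
    eio.write_occurrences(outdir / "occurrences.csv", world.occurrences)
    eio.write_floras(outdir / "floras.geojson", world.floras)
    truth = pd.DataFrame(
        [
            {
                "species_id": s,
                "n_suitable": world.suitable[s].size,
                "n_occupied": world.occupied[s].size,
            }
            for s in world.suitable
        ]
    )
    truth.to_csv(outdir / "truth_summary.csv", index=False)

    n_cropped_total = 0
    report: dict = {"seed": seed, "guilds": {}}
    for guild, res in results.items():
        gdir = outdir / guild
        gdir.mkdir(exist_ok=True)
        res.eval_records.to_csv(gdir / "model_eval.csv", index=False)
        weights = {
            s: {
                "threshold": m.threshold,
                "log_normalizer": m.log_normalizer,
                "features": [f.name for f in m.expansion.features],
                "weights": m.weights.tolist(),
            }
            for s, m in res.models.items()
        }
        (gdir / "model_weights.json").write_text(json.dumps(weights))
        pred_df = pd.DataFrame(
            [
                {
                    "flora_id": p.flora_id,
                    "s_pred": p.s_pred,
                    "s_rep_modeled": p.s_rep_modeled,
                    "predicted_species": ";".join(sorted(p.predicted_species)),
                }
                for p in res.predictions
            ]
        )
        pred_df.to_csv(gdir / "flora_predictions.csv", index=False)
        z_df = pd.DataFrame(
            [
                {
                    "flora_id": r.flora_id,
                    "s_pred": r.s_pred,
                    "s_rep": r.s_rep,
                    "a_bbox_ha": r.a_bbox,
                    "a_flora_ha": r.a_flora,
                    "z": r.z,
                }
                for r in res.z_records
            ]
        )
        z_df.to_csv(gdir / "z_records.csv", index=False)
        reg_df = pd.DataFrame(
            [
                {
                    "subset": r.label,
                    "n": r.n,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r_squared": r.r_squared,
                    "r": r.r,
                    "r_ci_low": r.r_ci[0],
                    "r_ci_high": r.r_ci[1],
                }
                for r in res.regressions
            ]
        )
        reg_df.to_csv(gdir / "regressions.csv", index=False)
        res.confusion.to_csv(gdir / "confusion.csv", index=False)
        res.ratio_table.to_csv(gdir / "ratios.csv", index=False)
        res.niche_breadth.to_csv(gdir / "niche_breadth.csv", index=False)
        n_cropped = len(res.predictions) * len(res.models)
        n_cropped_total += n_cropped
        z_vals = np.array([r.z for r in res.z_records])
        z_vals = z_vals[~np.isnan(z_vals)]
        report["guilds"][guild] = {
            "n_modeled_species": len(res.models),
            "n_floras": len(res.predictions),
            "n_cropped_models": n_cropped,
            "z_mean": float(z_vals.mean()) if z_vals.size else None,
            "z_sd": float(z_vals.std(ddof=1)) if z_vals.size > 1 else None,
            "mean_sensitivity": float(res.confusion["sensitivity"].mean()),
            "mean_specificity": float(res.confusion["specificity"].mean()),
            **res.ratio_summary,
        }
    report["n_cropped_models_total"] = n_cropped_total
    report["n_floras"] = len(world.floras)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = eio.write_manifest(
        outdir / "manifest.json", outdir, {"seed": seed, "tool": "enmstack"}
    )
    return report | {"manifest": manifest}


# ---------------------------------------------------------------------------
# parameter-recovery study
# ---------------------------------------------------------------------------


def parameter_recovery_study(
    master_seeds: list[int], config: RunConfig | None = None
) -> dict:
    """Repeat the full pipeline over several master seeds and summarise.

    Returns a dict with per-seed rows and cross-seed means of the headline
    quantities: R-squared by flora size class, guild sensitivity/specificity,
    overprediction ratios, z means, and test omission of well-sampled
    species.
    """
    config = config if config is not None else RunConfig.scaled()
    rows = []
    for seed in master_seeds:
        world, results = run_analysis(config, seed)
        for guild, res in results.items():
            row: dict = {"seed": seed, "guild": guild}
            for reg in res.regressions:
                if reg.label != "all" and np.isfinite(reg.r_squared):
                    row[f"r2_{reg.label}"] = reg.r_squared
            row["mean_sensitivity"] = float(res.confusion["sensitivity"].mean())
            row["mean_specificity"] = float(res.confusion["specificity"].mean())
            row["mean_ratio"] = res.ratio_summary.get("mean_ratio_pred_over_rep")
            z_vals = np.array([r.z for r in res.z_records])
            z_vals = z_vals[~np.isnan(z_vals)]
            row["z_mean"] = float(z_vals.mean()) if z_vals.size else np.nan
            well = res.eval_records[
                res.eval_records["category"] == CATEGORY_TRAIN_TEST
            ]
            row["mean_test_omission"] = (
                float(well["test_omission"].mean()) if len(well) else np.nan
            )
            row["mean_train_omission"] = (
                float(res.eval_records["train_omission"].mean())
                if len(res.eval_records)
                else np.nan
            )
            rows.append(row)
    per_seed = pd.DataFrame(rows)

    size_labels = [f"10^{k}" for k in (2, 3, 4, 5, 6, 7)]
    r2_by_class = {
        lab: float(per_seed[f"r2_{lab}"].mean())
        for lab in size_labels
        if f"r2_{lab}" in per_seed
    }
    by_guild = per_seed.groupby("guild")
    summary = {
        "r2_by_size_class": r2_by_class,
        "mean_sensitivity": by_guild["mean_sensitivity"].mean().to_dict(),
        "mean_specificity": by_guild["mean_specificity"].mean().to_dict(),
        "mean_overprediction_ratio": by_guild["mean_ratio"].mean().to_dict(),
        "z_mean": by_guild["z_mean"].mean().to_dict(),
        "mean_test_omission": float(per_seed["mean_test_omission"].mean()),
        "mean_test_omission_by_guild": by_guild["mean_test_omission"].mean().to_dict(),
    }
    return {"per_seed": per_seed, "summary": summary}
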