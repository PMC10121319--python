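"""Synthetic virtual-species world with fully known truth.

This module builds the study system the richness pipeline is evaluated on:

* spatially autocorrelated, cross-correlated environmental layers on a
  :class:`~enmstack.grid.LandscapeGrid`;
* virtual species in two guilds — a *narrow* guild with tight niches and
  limited dispersal, and a *broad* guild with wide niches and full dispersal —
  each with a known suitability surface, suitable set and occupied range;
* occurrence records sampled from occupied cells under a configurable
  collection-bias field, with a mixture of record kinds so the curation
  filters have something to remove;
* floras: rectangular survey areas stratified by basin and by six
  decadal area classes (10^1 < A <= 10^2 ha up to 10^6 < A <= 10^7 ha),
  each carrying the exact list of species whose occupied range overlaps it.

Because suitable sets, occupied ranges and flora species lists are all known
exactly, every downstream statistic can be checked against ground truth.

All randomness flows from one master seed through named substreams, so the
whole world is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LandscapeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "EnvLayerSet",
    "VirtualSpecies",
    "FloraSpec",
    "substream",
    "generate_environment",
    "true_suitability",
    "true_range",
    "sample_occurrences",
    "generate_floras",
    "cells_intersecting_rect",
]

RECORD_KINDS = ("specimen", "observation", "fossil", "literature", "unknown")

# fixed substream labels: every consumer of randomness draws from one of these
_STREAMS = {
    "environment": 1,
    "species": 2,
    "ranges": 3,
    "occurrences": 4,
    "floras": 5,
    "bias": 6,
    "split": 7,
    "background": 8,
}


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, independent random substream derived from the master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[name], index))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class EnvLayerSet:
    """A stack of per-cell environmental layers sharing one grid.

    ``layers`` maps layer name to a float array of shape
    ``(n_rows, n_cols)``; NaN marks missing data.  ``correlation_target``
    records the cross-layer correlation matrix used at generation time
    (None for layer sets read from files).
    """

    grid: LandscapeGrid
    layers: dict[str, np.ndarray]
    correlation_target: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {shape}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def matrix(self) -> np.ndarray:
        """(n_cells, L) value matrix in layer order, row-major cell order."""
        return np.column_stack([self.layers[n].ravel() for n in self.layers])

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_cells,) mask of cells with no missing layer value."""
        return np.all(np.isfinite(self.matrix()), axis=1)

    def values_at(self, cell_ids: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """(n, k) layer values at the given cells."""
        names = names if names is not None else self.names
        rows, cols = self.grid.rowcol(np.asarray(cell_ids))
        return np.column_stack([self.layers[n][rows, cols] for n in names])


def generate_environment(
    grid: LandscapeGrid,
    n_layers: int = 22,
    correlation_target: np.ndarray | None = None,
    smoothness: float = 8.0,
    seed: int = 0,
) -> EnvLayerSet:
    """Generate spatially autocorrelated, cross-correlated layers.

    Each layer is a Gaussian random field produced by smoothing white noise
    with a Gaussian kernel of scale ``smoothness`` (in cells) and
    standardising; cross-layer structure is imposed by mixing the fields with
    the Cholesky factor of ``correlation_target``, so empirical correlations
    between layers converge on the target as the grid grows.

    Parameters
    ----------
    correlation_target
        Symmetric positive-definite L x L matrix; defaults to an AR(1)-style
        matrix ``rho**|i-j|`` with rho = 0.6, mimicking the strong
        collinearity of bioclim-style predictor sets.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if correlation_target is None:
        idx = np.arange(n_layers)
        correlation_target = 0.6 ** np.abs(idx[:, None] - idx[None, :])
    correlation_target = np.asarray(correlation_target, dtype=float)
    if correlation_target.shape != (n_layers, n_layers):
        raise ValueError("correlation_target must be L x L")
    if not np.allclose(correlation_target, correlation_target.T):
        raise ValueError("correlation_target must be symmetric")
    eigval, eigvec = np.linalg.eigh(correlation_target)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        raise ValueError(
            "correlation_target must be positive-(semi)definite; "
            f"smallest eigenvalue {eigval.min():.3e}"
        )
    # symmetric square root: exact unit off-diagonals collapse layers to
    # affine copies instead of failing a strict Cholesky
    chol = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T

    rng = substream(seed, "environment")
    fields = np.empty((n_layers, grid.n_rows, grid.n_cols))
    for j in range(n_layers):
        white = rng.standard_normal((grid.n_rows, grid.n_cols))
        smooth = ndimage.gaussian_filter(white, sigma=smoothness, mode="wrap")
        fields[j] = (smooth - smooth.mean()) / smooth.std()
    mixed = np.tensordot(chol, fields, axes=(1, 0))
    # restandardise so every layer has unit scale regardless of the mixing row
    mixed /= mixed.std(axis=(1, 2), keepdims=True)
    layers = {f"env{j + 1:02d}": mixed[j] for j in range(n_layers)}
    return EnvLayerSet(grid=grid, layers=layers, correlation_target=correlation_target)


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------


@dataclass
class VirtualSpecies:
    """A simulated species with a known product-Gaussian niche.

    Suitability in a cell is the product over niche layers of Gaussian
    responses ``exp(-(e_j - mu_j)^2 / (2 sigma_j^2))``, so it is 1 where the
    environment hits every optimum.  Cells at or above ``suitability_cutoff``
    form the suitable set; the occupied range is a contiguous subset of it
    covering ``dispersal_fraction`` of suitable cells.
    """

    species_id: str
    guild: str  # "narrow" | "broad"
    niche_optimum: dict[str, float]
    niche_breadth: dict[str, float]
    suitability_cutoff: float = 0.2
    dispersal_fraction: float = 1.0
    target_n_occurrences: int = 100

    def __post_init__(self) -> None:
        if set(self.niche_optimum) != set(self.niche_breadth):
            raise ValueError("niche_optimum and niche_breadth layers must match")
        if any(s <= 0 for s in self.niche_breadth.values()):
            raise ValueError("niche_breadth must be positive")
        if not 0 < self.suitability_cutoff < 1:
            raise ValueError("suitability_cutoff must lie in (0, 1)")
        if not 0 < self.dispersal_fraction <= 1:
            raise ValueError("dispersal_fraction must lie in (0, 1]")


def true_suitability(sp: VirtualSpecies, env: EnvLayerSet) -> np.ndarray:
    """Per-cell suitability in [0, 1] (shape ``(n_rows, n_cols)``)."""
    missing = [n for n in sp.niche_optimum if n not in env.layers]
    if missing:
        raise KeyError(f"species {sp.species_id}: missing layers {missing}")
    log_s = np.zeros((env.grid.n_rows, env.grid.n_cols))
    for name, mu in sp.niche_optimum.items():
        sigma = sp.niche_breadth[name]
        log_s -= (env.layers[name] - mu) ** 2 / (2.0 * sigma**2)
    return np.exp(log_s)


def _flood_fill_subset(
    suitable_mask: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow a connected subset of ``target`` True cells by seeded BFS.

    BFS (4-neighbour) from a random suitable cell; if a connected component
    is exhausted before the target is reached, growth restarts from a fresh
    random suitable cell, so the result is a union of whole components plus
    one partially grown component.
    """
    n_rows, n_cols = suitable_mask.shape
    remaining = np.flatnonzero(suitable_mask.ravel())
    chosen = np.zeros(suitable_mask.size, dtype=bool)
    visited = np.zeros(suitable_mask.size, dtype=bool)
    count = 0
    flat = suitable_mask.ravel()
    while count < target:
        pool = remaining[~visited[remaining]]
        if pool.size == 0:  # pragma: no cover - target <= |suitable| upstream
            break
        queue = deque([int(rng.choice(pool))])
        visited[queue[0]] = True
        while queue and count < target:
            cid = queue.popleft()
            chosen[cid] = True
            count += 1
            r, c = cid // n_cols, cid % n_cols
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    nid = rr * n_cols + cc
                    if flat[nid] and not visited[nid]:
                        visited[nid] = True
                        queue.append(nid)
    return np.flatnonzero(chosen)


def true_range(
    sp: VirtualSpecies, env: EnvLayerSet, seed: int = 0, species_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Suitable and occupied cell-id sets for one species.

    The suitable set is every cell with suitability >= the species cutoff;
    the occupied set is a flood-fill-grown subset holding
    ``round(dispersal_fraction * |suitable|)`` cells, emulating dispersal
    limitation while keeping ranges contiguous.

    Returns
    -------
    (suitable_cells, occupied_cells)
        Sorted integer cell-id arrays, ``occupied ⊆ suitable``.
    """
    suit = true_suitability(sp, env)
    mask = suit >= sp.suitability_cutoff
    suitable = np.flatnonzero(mask.ravel())
    if suitable.size == 0:
        warnings.warn(
            f"species {sp.species_id}: no suitable cells; empty range",
            stacklevel=2,
        )
        return suitable, suitable.copy()
    if sp.dispersal_fraction >= 1.0:
        return suitable, suitable.copy()
    target = int(round(sp.dispersal_fraction * suitable.size))
    target = max(target, 1)
    rng = substream(seed, "ranges", species_index)
    occupied = _flood_fill_subset(mask, target, rng)
    return suitable, np.sort(occupied)


def sample_occurrences(
    sp: VirtualSpecies,
    occupied_cells: np.ndarray,
    grid: LandscapeGrid,
    bias_field: np.ndarray | None = None,
    seed: int = 0,
    species_index: int = 0,
    record_kind_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw occurrence records from the occupied range under collection bias.

    ``target_n_occurrences`` cells are drawn (with replacement — real
    occurrence data revisit cells) with probability proportional to
    ``bias_field``; points are jittered uniformly within their cell.  Record
    kinds follow the configured mixture; the default keeps 90% of records as
    specimens/observations and spreads 10% over the kinds the curation stage
    must discard.
    """
    if record_kind_probs is None:
        record_kind_probs = {
            "specimen": 0.6,
            "observation": 0.3,
            "fossil": 0.04,
            "literature": 0.03,
            "unknown": 0.03,
        }
    cols = ["species_id", "x", "y", "cell_id", "record_kind"]
    if occupied_cells.size == 0:
        logger.info("species %s has an empty range; no occurrences", sp.species_id)
        return pd.DataFrame(columns=cols)
    if bias_field is None:
        weights = np.ones(occupied_cells.size)
    else:
        weights = np.asarray(bias_field).ravel()[occupied_cells].astype(float)
    if np.any(weights < 0):
        raise ValueError("bias_field must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("bias_field vanishes on the occupied set")
    rng = substream(seed, "occurrences", species_index)
    n = sp.target_n_occurrences
    cells = rng.choice(occupied_cells, size=n, p=weights / total)
    cx, cy = grid.cell_center(cells)
    cs = grid.cell_size
    x = cx + rng.uniform(-0.5, 0.5, n) * cs
    y = cy + rng.uniform(-0.5, 0.5, n) * cs
    kinds_names = list(record_kind_probs)
    kinds = rng.choice(kinds_names, size=n, p=np.array(list(record_kind_probs.values())))
    return pd.DataFrame(
        {
            "species_id": sp.species_id,
            "x": x,
            "y": y,
            "cell_id": cells,
            "record_kind": kinds,
        }
    )


def collection_bias_field(grid: LandscapeGrid, seed: int, strength: float = 0.5,
                          smoothness: float = 12.0) -> np.ndarray:
    """Smooth multiplicative collection-bias surface (mean roughly 1).

    Emulates uneven survey effort — the reason target-group background
    sampling exists — as the exponential of a smooth Gaussian field.
    """
    rng = substream(seed, "bias")
    white = rng.standard_normal((grid.n_rows, grid.n_cols))
    smooth = ndimage.gaussian_filter(white, sigma=smoothness, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return np.exp(strength * smooth)


# ---------------------------------------------------------------------------
# floras
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FloraSpec:
    """A rectangular survey area with its reported species list.

    ``size_class`` is the exponent k of the decadal class upper bound:
    areas satisfy 10^(k-1) < A <= 10^k ha, k in 2..7.
    """

    flora_id: str
    rect: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax (m)
    area_ha: float
    basin: str
    size_class: int
    reported_species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.rect
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate flora rectangle")
        if not 10 ** (self.size_class - 1) < self.area_ha <= 10**self.size_class:
            raise ValueError(
                f"flora {self.flora_id}: area {self.area_ha} ha outside class "
                f"10^{self.size_class}"
            )


def cells_intersecting_rect(
    grid: LandscapeGrid, rect: tuple[float, float, float, float]
) -> np.ndarray:
    """Cell ids whose square overlaps the rectangle with positive area."""
    xmin, ymin, xmax, ymax = rect
    x0, y0, _, _ = grid.extent
    cs = grid.cell_size
    c0 = max(int(np.floor((xmin - x0) / cs)), 0)
    c1 = min(int(np.ceil((xmax - x0) / cs)), grid.n_cols)
    r0 = max(int(np.floor((ymin - y0) / cs)), 0)
    r1 = min(int(np.ceil((ymax - y0) / cs)), grid.n_rows)
    # a cell touching the rectangle only along an edge does not overlap it
    if c0 < c1 and x0 + (c1 - 1) * cs >= xmax:
        c1 -= 1
    if c0 < c1 and x0 + (c0 + 1) * cs <= xmin:
        c0 += 1
    if r0 < r1 and y0 + (r1 - 1) * cs >= ymax:
        r1 -= 1
    if r0 < r1 and y0 + (r0 + 1) * cs <= ymin:
        r0 += 1
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return grid.cell_id(rows.ravel(), cols.ravel())


SIZE_CLASSES = (2, 3, 4, 5, 6, 7)


def generate_floras(
    grid: LandscapeGrid,
    occupied_by_species: dict[str, np.ndarray],
    per_stratum: int = 10,
    seed: int = 0,
    nondetection_prob: float = 0.0,
) -> list[FloraSpec]:
    """Stratified random floras: basins x six size classes x ``per_stratum``.

    Areas are log-uniform within each class interval (10^(k-1), 10^k] ha,
    rectangles have a random aspect ratio and uniform position inside their
    basin, and each flora's reported list is the exact set of species whose
    occupied range overlaps the rectangle, thinned by ``nondetection_prob``
    per species (default 0: perfect detection).

    Size classes whose lower bound exceeds the basin area are skipped and
    classes whose upper bound exceeds it are truncated, with a warning.
    """
    rng = substream(seed, "floras")
    occ_masks = {
        sp: np.isin(np.arange(grid.n_cells), cells)
        for sp, cells in occupied_by_species.items()
    }
    floras: list[FloraSpec] = []
    for b in range(grid.n_basins):
        bx0, by0, bx1, by1 = grid.basin_extent(b)
        basin_area = grid.basin_area_ha(b)
        bname = grid.basin_names[b]
        for k in SIZE_CLASSES:
            lo, hi = 10.0 ** (k - 1), 10.0**k
            if lo >= basin_area:
                warnings.warn(
                    f"size class 10^{k} skipped in {bname}: lower bound "
                    f"{lo:.0f} ha exceeds basin area {basin_area:.0f} ha",
                    stacklevel=2,
                )
                continue
            if hi > basin_area:
                warnings.warn(
                    f"size class 10^{k} truncated to basin area "
                    f"{basin_area:.0f} ha in {bname}",
                    stacklevel=2,
                )
                hi = basin_area
            for i in range(per_stratum):
                area_ha = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                area_m2 = area_ha * 1e4
                bw, bh = bx1 - bx0, by1 - by0
                # aspect = width/height, log-uniform in [1/2, 2], clamped to fit
                aspect = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                w = float(np.sqrt(area_m2 * aspect))
                if w > bw:
                    w = bw
                h = area_m2 / w
                if h > bh:
                    h = bh
                    w = area_m2 / h
                x = float(rng.uniform(bx0, bx1 - w))
                y = float(rng.uniform(by0, by1 - h))
                rect = (x, y, x + w, y + h)
                cells = cells_intersecting_rect(grid, rect)
                present = {
                    sp for sp, mask in occ_masks.items() if mask[cells].any()
                }
                if nondetection_prob > 0:
                    present = {
                        sp for sp in present if rng.random() >= nondetection_prob
                    }
                floras.append(
                    FloraSpec(
                        flora_id=f"{bname}-c{k}-f{i + 1}",
                        rect=rect,
                        area_ha=area_ha,
                        basin=bname,
                        size_class=k,
                        reported_species=frozenset(present),
                    )
                )
    return floras


# ---------------------------------------------------------------------------
# guild rosters
# ---------------------------------------------------------------------------


def generate_guild(
    env: EnvLayerSet,
    guild: str,
    n_species: int,
    seed: int,
    *,
    n_niche_layers: int = 4,
    breadth_mean: float = 1.0,
    breadth_cv: float = 0.25,
    dispersal_fraction: float = 1.0,
    suitability_cutoff: float = 0.2,
    occurrence_mix: tuple[float, float, float] = (0.1, 0.4, 0.5),
    optimum_quantiles: tuple[float, float] = (0.0, 1.0),
    index_offset: int = 0,
) -> list[VirtualSpecies]:
    """Draw a guild roster of virtual species from the environment.

    Each species' optimum is the environment at a random valid cell (so its
    suitable set is never empty) on a random subset of ``n_niche_layers``
    layers; breadths are lognormal around ``breadth_mean``.
    ``optimum_quantiles`` restricts candidate optimum cells to a quantile
    band of each niche layer, so a specialist guild can be confined to a
    climatic corner of the landscape (the way cacti concentrate in warm,
    arid regions) while a generalist guild samples the whole gradient.
    Target occurrence counts follow the three-way mixture ``occurrence_mix``
    over the sparse (3-6), moderate (20-99) and well-sampled (120-400)
    regimes, so the roster spans the record-count categories the curation
    stage assigns.
    """
    rng = substream(seed, "species", _STREAMS_GUILD.setdefault(guild, len(_STREAMS_GUILD)))
    valid = np.flatnonzero(env.valid_mask())
    names = env.names
    species = []
    lo_n, mid_n, hi_n = occurrence_mix
    q_lo, q_hi = optimum_quantiles
    # one niche-layer set per guild: species in a family respond to shared
    # climatic axes, they differ in optima and breadths along them
    layer_sel = list(rng.choice(names, size=min(n_niche_layers, len(names)),
                                replace=False))
    pool = valid
    if (q_lo, q_hi) != (0.0, 1.0):
        vals_all = env.values_at(valid, layer_sel)
        lo_b = np.quantile(vals_all, q_lo, axis=0)
        hi_b = np.quantile(vals_all, q_hi, axis=0)
        inside = np.all((vals_all >= lo_b) & (vals_all <= hi_b), axis=1)
        if inside.any():
            pool = valid[inside]
    for i in range(n_species):
        cell = int(rng.choice(pool))
        vals = env.values_at(np.array([cell]), layer_sel)[0]
        breadths = breadth_mean * np.exp(
            rng.normal(0.0, breadth_cv, len(layer_sel))
        )
        u = rng.random()
        if u < lo_n:
            n_occ = int(rng.integers(3, 7))
        elif u < lo_n + mid_n:
            n_occ = int(rng.integers(20, 100))
        else:
            n_occ = int(rng.integers(120, 401))
        species.append(
            VirtualSpecies(
                species_id=f"{guild}-{index_offset + i + 1:03d}",
                guild=guild,
                niche_optimum=dict(zip(layer_sel, vals.tolist())),
                niche_breadth=dict(zip(layer_sel, breadths.tolist())),
                suitability_cutoff=suitability_cutoff,
                dispersal_fraction=dispersal_fraction,
                target_n_occurrences=n_occ,
            )
        )
    return species


_STREAMS_GUILD: dict[str, int] = {"narrow": 0, "broad": 1}
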