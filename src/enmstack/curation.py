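"""Occurrence curation: record filtering, cell deduplication, splits, background.

The modelling stage works on spatially unique presence *cells*, not raw
records.  Curation therefore (1) keeps only specimen/observation records that
fall inside a species' native range (when ranges are supplied), (2) collapses
records to the set of grid cells with complete environmental data, and
(3) assigns each species to a record-count category that decides how it is
modelled:

========  =====================  =========================================
category  unique cells           treatment
========  =====================  =========================================
excluded  <= 6                   dropped from all downstream analyses
train_only  7-99                 all cells train; evaluated on train omission
train_test  >= 100               70/30 train/test split; test omission
========  =====================  =========================================

The background for model fitting is the *target group* background: the union
of all modelled species' presence cells within a guild, which inherits the
survey bias of the presences and thereby cancels much of it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .grid import LandscapeGrid
from .simulate import EnvLayerSet, substream

logger = logging.getLogger(__name__)

__all__ = [
    "CuratedOccurrences",
    "filter_records",
    "dedupe_to_cells",
    "split_train_test",
    "build_background",
]

CATEGORY_EXCLUDED = "excluded"
CATEGORY_TRAIN_ONLY = "train_only"
CATEGORY_TRAIN_TEST = "train_test"

KEEP_KINDS = frozenset({"specimen", "observation"})


@dataclass
class CuratedOccurrences:
    """Spatially unique presence cells for one species, with its category."""

    species_id: str
    kept_cells: np.ndarray  # sorted unique cell ids
    n_raw: int

    def __post_init__(self) -> None:
        self.kept_cells = np.unique(np.asarray(self.kept_cells, dtype=int))

    @property
    def n_kept(self) -> int:
        return int(self.kept_cells.size)

    @property
    def category(self) -> str:
        if self.n_kept <= 6:
            return CATEGORY_EXCLUDED
        if self.n_kept < 100:
            return CATEGORY_TRAIN_ONLY
        return CATEGORY_TRAIN_TEST


def filter_records(
    raw: pd.DataFrame,
    native_ranges: dict[str, object] | None = None,
    excluded_species: set[str] | None = None,
) -> pd.DataFrame:
    """Keep specimen/observation records inside each species' native range.

    ``native_ranges`` maps species id to a shapely geometry; records of
    species without an entry are kept unchanged (the range check is opt-in).
    ``excluded_species`` removes listed species outright (e.g. cultivated
    taxa of unknown native range).
    """
    out = raw[raw["record_kind"].isin(KEEP_KINDS)]
    if excluded_species:
        out = out[~out["species_id"].isin(excluded_species)]
    if native_ranges:
        unknown = set(native_ranges) - set(raw["species_id"].unique())
        if unknown:
            warnings.warn(
                f"native_ranges given for unknown species: {sorted(unknown)}",
                stacklevel=2,
            )
        keep = np.ones(len(out), dtype=bool)
        for sp, geom in native_ranges.items():
            sel = (out["species_id"] == sp).to_numpy()
            if not sel.any():
                continue
            prepared = prep(geom)
            pts = [Point(x, y) for x, y in out.loc[sel, ["x", "y"]].to_numpy()]
            inside = np.fromiter(
                (prepared.covers(p) for p in pts), dtype=bool, count=len(pts)
            )
            keep[sel] = inside
        out = out[keep]
    return out.reset_index(drop=True)


def dedupe_to_cells(
    occ: pd.DataFrame, grid: LandscapeGrid, env: EnvLayerSet
) -> dict[str, CuratedOccurrences]:
    """Collapse records to spatially unique cells with complete data.

    Records falling in cells where any environmental layer is missing are
    dropped (null-value regions such as coastline/lake cells); remaining
    records are reduced to one presence per grid cell.
    """
    if env.grid is not grid and (env.grid.n_rows, env.grid.n_cols) != (
        grid.n_rows,
        grid.n_cols,
    ):
        raise ValueError("grid does not match environment dimensions")
    valid = env.valid_mask()
    out: dict[str, CuratedOccurrences] = {}
    for sp, df in occ.groupby("species_id", sort=True):
        if "cell_id" in df and df["cell_id"].notna().all():
            cells = df["cell_id"].to_numpy(dtype=int)
        else:
            cells = grid.cell_of_xy(df["x"].to_numpy(), df["y"].to_numpy())
        kept = np.unique(cells[valid[cells]])
        out[sp] = CuratedOccurrences(species_id=sp, kept_cells=kept, n_raw=len(df))
    return out


def split_train_test(
    cur: CuratedOccurrences, seed: int = 0, train_fraction: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Random 70/30 train/test partition of a species' presence cells.

    ``|train| = round(train_fraction * n_kept)``.  For species without
    enough records to test (category ``train_only``) every cell goes to
    training and the test set is empty.
    """
    cells = cur.kept_cells
    if cur.category != CATEGORY_TRAIN_TEST:
        logger.info(
            "species %s is %s: all %d cells used for training",
            cur.species_id,
            cur.category,
            cur.n_kept,
        )
        return cells.copy(), np.empty(0, dtype=int)
    rng = substream(seed, "split", _stable_index(cur.species_id))
    n_train = int(np.floor(train_fraction * cur.n_kept + 0.5))
    perm = rng.permutation(cells)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def build_background(
    roster: list[CuratedOccurrences],
    grid: LandscapeGrid,
    env: EnvLayerSet,
    min_background: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Target-group background: union of modelled species' presence cells.

    If the union is smaller than ``min_background`` it is topped up with
    uniformly sampled valid cells so the normalising sample stays
    representative on sparse rosters.
    """
    if not roster:
        raise ValueError("roster is empty")
    modeled = [c for c in roster if c.category != CATEGORY_EXCLUDED]
    if not modeled:
        raise ValueError("roster contains no modeled species")
    union = np.unique(np.concatenate([c.kept_cells for c in modeled]))
    if union.size >= min_background:
        return union
    valid = np.flatnonzero(env.valid_mask())
    pool = np.setdiff1d(valid, union, assume_unique=True)
    n_extra = min(min_background - union.size, pool.size)
    rng = substream(seed, "background")
    extra = rng.choice(pool, size=n_extra, replace=False)
    return np.sort(np.concatenate([union, extra]))


def _stable_index(species_id: str) -> int:
    """Deterministic small substream index from a species id."""
    import zlib

    return zlib.crc32(species_id.encode()) % (2**16)
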