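"""Stack per-species binary maps over flora bounding boxes.

Each flora's survey rectangle is expanded outward to the nearest cell edges
(its *bounding box*, which softens edge effects: disagreement at map edges is
less meaningful than near centres).  Every species' binary suitability map is
cropped to that box; a species counts as predicted present when at least
``min_suitable_cells`` cells in the box are suitable (default 1, the most
permissive rule).  Predicted richness is the size of the predicted set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LandscapeGrid
from .simulate import FloraSpec

__all__ = [
    "BoundingBox",
    "FloraPrediction",
    "bounding_box",
    "crop_model",
    "species_predicted_present",
    "stack_richness",
]


@dataclass(frozen=True)
class BoundingBox:
    """Cell-aligned crop window around one flora.

    ``row0:row1`` and ``col0:col1`` are half-open cell-index ranges; the box
    contains exactly the cells whose centres fall inside the snapped
    rectangle, so its area is ``n_cells * cell_area >= flora area``.
    """

    flora_id: str
    row0: int
    row1: int
    col0: int
    col1: int
    cell_area: float

    @property
    def n_cells(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    @property
    def area_ha(self) -> float:
        return self.n_cells * self.cell_area


@dataclass
class FloraPrediction:
    """Stacked prediction for one flora over the modelled species roster."""

    flora_id: str
    predicted_species: frozenset[str]
    s_rep_modeled: int  # reported richness after dropping unmodelled species
    n_cropped_models: int  # == number of modelled species

    @property
    def s_pred(self) -> int:
        return len(self.predicted_species)


def bounding_box(flora: FloraSpec, grid: LandscapeGrid) -> BoundingBox:
    """Minimal cell-edge-snapped box containing the flora rectangle."""
    xmin, ymin, xmax, ymax = flora.rect
    x0, y0, x1, y1 = grid.extent
    cs = grid.cell_size
    col0 = int(np.floor((xmin - x0) / cs))
    col1 = int(np.ceil((xmax - x0) / cs))
    row0 = int(np.floor((ymin - y0) / cs))
    row1 = int(np.ceil((ymax - y0) / cs))
    col0, row0 = max(col0, 0), max(row0, 0)
    col1, row1 = min(col1, grid.n_cols), min(row1, grid.n_rows)
    if col1 <= col0 or row1 <= row0:
        raise ValueError(f"flora {flora.flora_id} lies outside the grid")
    return BoundingBox(
        flora_id=flora.flora_id,
        row0=row0,
        row1=row1,
        col0=col0,
        col1=col1,
        cell_area=grid.cell_area,
    )


def crop_model(binary: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop a binary map to the cells whose centres lie in the box."""
    return binary[box.row0 : box.row1, box.col0 : box.col1]


def species_predicted_present(cropped: np.ndarray, min_suitable_cells: int = 1) -> bool:
    """True iff at least ``min_suitable_cells`` suitable cells lie in the box."""
    return int(np.count_nonzero(cropped)) >= min_suitable_cells


def stack_richness(
    binary_maps: dict[str, np.ndarray],
    flora: FloraSpec,
    grid: LandscapeGrid,
    min_suitable_cells: int = 1,
    box: BoundingBox | None = None,
) -> FloraPrediction:
    """Stack all modelled species' maps over one flora's bounding box.

    ``binary_maps`` maps species id to its full-grid binary map; the keys
    define the modelled roster.  The reported list is reduced to modelled
    species before comparison, mirroring the removal of unmodelled species
    from published species lists.
    """
    if box is None:
        box = bounding_box(flora, grid)
    predicted = frozenset(
        sp
        for sp, bmap in binary_maps.items()
        if species_predicted_present(crop_model(bmap, box), min_suitable_cells)
    )
    s_rep_modeled = len(flora.reported_species & set(binary_maps))
    return FloraPrediction(
        flora_id=flora.flora_id,
        predicted_species=predicted,
        s_rep_modeled=s_rep_modeled,
        n_cropped_models=len(binary_maps),
    )
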