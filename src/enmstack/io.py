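"""File formats: ESRI ASCII rasters, occurrence CSV, flora GeoJSON, manifests.

All formats are plain text.  Rasters use the ESRI ASCII grid convention
(header of ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value, then rows
from the top of the grid down); coordinates are planar metres and areas
hectares, matching :class:`~enmstack.grid.LandscapeGrid`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape

from .grid import LandscapeGrid
from .simulate import RECORD_KINDS, EnvLayerSet, FloraSpec

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_env",
    "read_env",
    "write_occurrences",
    "read_occurrences",
    "write_floras",
    "read_flora_file",
    "write_manifest",
]

NODATA = -9999.0


def write_ascii_grid(path: Path | str, values: np.ndarray, grid: LandscapeGrid) -> None:
    """Write one layer as an ESRI ASCII grid (top row first; NaN -> NODATA)."""
    path = Path(path)
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path: Path | str) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid; returns (values row 0 = south, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return data, header


def write_env(outdir: Path | str, env: EnvLayerSet) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in env.layers.items():
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, arr, env.grid)
        paths.append(p)
    return paths


def read_env(indir: Path | str, grid: LandscapeGrid | None = None) -> EnvLayerSet:
    """Read all ``.asc`` layers in a directory into one aligned layer set."""
    indir = Path(indir)
    paths = sorted(indir.glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers in {indir}")
    layers, headers = {}, {}
    for p in paths:
        layers[p.stem], headers[p.stem] = read_ascii_grid(p)
    ref_name = next(iter(headers))
    ref = headers[ref_name]
    offenders = [
        n
        for n, h in headers.items()
        if any(abs(h[k] - ref[k]) > 1e-6 for k in ("ncols", "nrows", "xllcorner",
                                                   "yllcorner", "cellsize"))
    ]
    if offenders:
        raise ValueError(
            f"layers misaligned with {ref_name}: {offenders}"
        )
    if grid is None:
        grid = LandscapeGrid(
            n_rows=int(ref["nrows"]),
            n_cols=int(ref["ncols"]),
            cell_area=ref["cellsize"] ** 2 / 1e4,
            origin=(ref["xllcorner"], ref["yllcorner"]),
        )
    return EnvLayerSet(grid=grid, layers=layers)


def write_occurrences(path: Path | str, occ: pd.DataFrame) -> None:
    occ[["species_id", "x", "y", "record_kind"]].to_csv(Path(path), index=False)


def read_occurrences(path: Path | str, grid: LandscapeGrid | None = None) -> pd.DataFrame:
    """Read an occurrence CSV; unrecognised record kinds become "unknown"."""
    df = pd.read_csv(Path(path))
    required = {"species_id", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence file missing columns {required - set(df.columns)}")
    if "record_kind" not in df:
        df["record_kind"] = "unknown"
    bad = ~df["record_kind"].isin(RECORD_KINDS)
    if bad.any():
        df.loc[bad, "record_kind"] = "unknown"
    if grid is not None:
        df["cell_id"] = grid.cell_of_xy(df["x"].to_numpy(), df["y"].to_numpy())
    return df


def write_floras(path: Path | str, floras: list[FloraSpec]) -> None:
    """Write floras as a GeoJSON FeatureCollection of rectangles."""
    features = []
    for f in floras:
        xmin, ymin, xmax, ymax = f.rect
        ring = [
            [xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax], [xmin, ymin]
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "flora_id": f.flora_id,
                    "area_ha": f.area_ha,
                    "basin": f.basin,
                    "size_class": f.size_class,
                    "reported_species": ";".join(sorted(f.reported_species)),
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_flora_file(path: Path | str) -> list[FloraSpec]:
    """Read a GeoJSON FeatureCollection of rectangular floras.

    Missing ``area_ha`` falls back to the polygon area (with a warning);
    non-rectangular polygons are replaced by their bounds.
    """
    data = json.loads(Path(path).read_text())
    floras = []
    for feat in data["features"]:
        geom = shapely_shape(feat["geometry"])
        props = feat.get("properties", {})
        if "area_ha" in props:
            area_ha = float(props["area_ha"])
        else:
            area_ha = geom.area / 1e4
            warnings.warn(
                f"flora {props.get('flora_id', '?')}: no area_ha property; "
                f"computed {area_ha:.1f} ha from the polygon",
                stacklevel=2,
            )
        reported = frozenset(
            s for s in str(props.get("reported_species", "")).split(";") if s
        )
        size_class = int(
            props.get("size_class", int(np.ceil(np.log10(max(area_ha, 10.001)))))
        )
        floras.append(
            FloraSpec(
                flora_id=str(props.get("flora_id", f"flora-{len(floras) + 1}")),
                rect=tuple(geom.bounds),
                area_ha=area_ha,
                basin=str(props.get("basin", "unknown")),
                size_class=size_class,
                reported_species=reported,
            )
        )
    return floras


def write_manifest(path: Path | str, run_dir: Path | str, meta: dict) -> dict:
    """Write a JSON manifest with SHA-256 hashes of every file in the run."""
    run_dir = Path(run_dir)
    hashes = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != Path(path).name:
            hashes[str(p.relative_to(run_dir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    manifest = dict(meta) | {"files": hashes}
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
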