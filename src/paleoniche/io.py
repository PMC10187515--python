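"""Plain-text serialization: ESRI ASCII grids, GeoJSON polygons, CSV point
tables, YAML model manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import GridRaster

__all__ = [
    "write_ascii_grid", "read_ascii_grid", "write_geojson", "read_geojson",
    "write_points_csv", "write_yaml", "read_yaml",
]

_NODATA = -9999.0


def write_ascii_grid(raster: GridRaster, path) -> None:
    """ESRI ASCII grid; row order top-down per the format convention."""
    nr, nc = raster.shape
    vals = np.where(raster.missing_mask, _NODATA, raster.values)
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\ncellsize {raster.cell_size}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.8g")


def read_ascii_grid(path) -> GridRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    missing = vals == header.get("nodata_value", _NODATA)
    vals[missing] = 0.0
    return GridRaster(
        vals,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        missing_mask=missing,
    )


def write_geojson(polygons: list[BaseGeometry], path, properties: list[dict] | None = None) -> None:
    feats = []
    for i, poly in enumerate(polygons):
        props = properties[i] if properties else {"id": i}
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson(path) -> list[BaseGeometry]:
    data = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in data["features"]]


def write_points_csv(points: np.ndarray, cell_index: np.ndarray, path, **extra) -> None:
    df = pd.DataFrame(
        {"x": points[:, 0], "y": points[:, 1],
         "cell_row": cell_index[:, 0], "cell_col": cell_index[:, 1]}
    )
    for k, v in extra.items():
        df[k] = v
    df.to_csv(path, index=False)


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
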