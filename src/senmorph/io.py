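"""File formats: measurement tables (CSV), polygon sets (CSV / GeoJSON-style
JSON), label masks and channels (TIFF/PNG via tifffile / imageio)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .morphometry import Compartment, ShapeObject

__all__ = [
    "read_records",
    "write_records",
    "read_polygons_csv",
    "write_polygons_csv",
    "read_polygons_geojson",
    "read_mask",
    "write_mask",
    "write_channels",
]

FLOAT_FORMAT = "%.6g"  # fixed serialized precision keeps tables platform-stable


def write_records(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for required in ("object_id", "area", "irregularity"):
        if required not in frame.columns:
            raise InputError(f"records file {path} lacks column {required!r}")
    if "track_id" in frame.columns:
        frame["track_id"] = frame["track_id"].fillna("").astype(str)
    return frame


def write_polygons_csv(shapes: Sequence[ShapeObject], path: Union[str, Path]) -> None:
    rows = []
    for s in shapes:
        for i, (x, y) in enumerate(s.polygon):
            rows.append({"object_id": s.object_id, "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_polygons_csv(
    path: Union[str, Path],
    compartment: Union[Compartment, str] = Compartment.CELL,
    pixel_size: float = 1.0,
) -> list[ShapeObject]:
    frame = pd.read_csv(path)
    for col in ("object_id", "vertex_index", "x", "y"):
        if col not in frame.columns:
            raise InputError(f"polygon CSV lacks column {col!r}")
    shapes = []
    for oid, grp in frame.groupby("object_id", sort=True):
        grp = grp.sort_values("vertex_index")
        shapes.append(ShapeObject(
            object_id=str(oid), compartment=compartment,
            polygon=grp[["x", "y"]].to_numpy(dtype=float), pixel_size=pixel_size,
        ))
    return shapes


def read_polygons_geojson(
    path: Union[str, Path],
    compartment: Union[Compartment, str] = Compartment.CELL,
    pixel_size: float = 1.0,
) -> list[ShapeObject]:
    """GeoJSON-style FeatureCollection of Polygon features with an ``object_id`` property."""
    with open(path) as fh:
        payload = json.load(fh)
    shapes = []
    for i, feature in enumerate(payload.get("features", [])):
        geom = feature.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise InputError(f"feature {i} is not a Polygon")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        oid = str(feature.get("properties", {}).get("object_id", f"feature_{i}"))
        shapes.append(ShapeObject(
            object_id=oid, compartment=compartment, polygon=ring, pixel_size=pixel_size,
        ))
    return shapes


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def read_mask(path: Union[str, Path]) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        mask = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        mask = iio.imread(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError(f"mask {path} is not single-channel 2-D")
    return mask.astype(np.int64)


def write_channels(channels: dict[str, np.ndarray], directory: Union[str, Path],
                   prefix: str = "channel") -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, img in channels.items():
        p = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(str(p), np.asarray(img, dtype=np.float32))
        out[name] = p
    return out
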