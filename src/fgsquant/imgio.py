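"""Readers and writers for images, ROI sets, and tabular results.

Conventions: pixel grid is 0-based row-major; polygon vertices are
``(x, y) = (column, row)`` in pixel units (the convention of common image
annotation tools); a pixel belongs to a polygon ROI iff its center lies
inside the ring.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely

from fgsquant.exceptions import ConfigError, EmptyRoiError, FormatError, GeometryError

logger = logging.getLogger("fgsquant")

HISTOLOGY_LABELS = frozenset({"neoplastic", "non-neoplastic"})
NIRF_CALLS = frozenset({"positive", "negative"})


@dataclass
class RoiSet:
    """Named ROIs: polygons (closed rings, pixel coords) and/or boolean rasters."""

    polygons: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (n, 2) xy
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # name -> bool raster

    def names(self) -> list[str]:
        return sorted(set(self.polygons) | set(self.masks))

    def add_polygon(self, name: str, ring: np.ndarray) -> None:
        ring = np.asarray(ring, dtype=float)
        if name in self.polygons or name in self.masks:
            raise ConfigError(f"duplicate ROI name: {name!r}")
        _validate_ring(ring, name)
        self.polygons[name] = ring

    def rasterize(self, name: str, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the named ROI on an ``(height, width)`` grid."""
        if name in self.masks:
            mask = self.masks[name]
            if mask.shape != tuple(shape):
                raise GeometryError(
                    f"mask {name!r} has shape {mask.shape}, expected {tuple(shape)}"
                )
            return mask
        if name not in self.polygons:
            raise KeyError(name)
        mask = rasterize_polygon(self.polygons[name], shape)
        if not mask.any():
            raise EmptyRoiError(f"ROI {name!r} covers no pixel center on grid {shape}")
        return mask


@dataclass(frozen=True)
class SectionRecord:
    """One histologic section: gold-standard label and the NIRF reading."""

    section_id: str
    dog_id: str
    histology_label: str
    nirf_call: str
    tissue_context: str = ""

    def __post_init__(self) -> None:
        if self.histology_label not in HISTOLOGY_LABELS:
            raise ConfigError(f"histology_label must be one of {sorted(HISTOLOGY_LABELS)}")
        if self.nirf_call not in NIRF_CALLS:
            raise ConfigError(f"nirf_call must be one of {sorted(NIRF_CALLS)}")


def _validate_ring(ring: np.ndarray, name: str) -> None:
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
        raise GeometryError(f"ROI {name!r}: ring needs >= 3 (x, y) vertices")
    poly = shapely.Polygon(ring)
    if poly.area == 0:
        raise GeometryError(f"ROI {name!r}: zero-area ring")
    if not poly.is_simple or not poly.is_valid:
        raise GeometryError(f"ROI {name!r}: self-intersecting ring")


def rasterize_polygon(ring: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center-in-polygon rasterization of a closed ring."""
    h, w = shape
    poly = shapely.Polygon(np.asarray(ring, dtype=float))
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
    return inside.reshape(h, w)


def polygon_area(ring: np.ndarray) -> float:
    """Planar (shoelace) area of a closed ring in px^2."""
    return float(shapely.Polygon(np.asarray(ring, dtype=float)).area)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as a grayscale ``(h, w)`` or RGB ``(h, w, 3)`` array."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various internal errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # strip fully-opaque alpha only
        if not np.all(arr[..., 3] == 255):
            raise FormatError(f"{path}: images with transparency are not supported")
        arr = arr[..., :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"{path}: unsupported channel layout {arr.shape}")
    logger.info("read_image %s shape=%s", path, arr.shape)
    return arr


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise FormatError(f"refusing to write non-8-bit image (dtype {arr.dtype})")
    iio.imwrite(path, arr)
    logger.info("write_image %s shape=%s", path, arr.shape)
    return path


def read_rois(path: str | Path, image_shape: tuple[int, int] | None = None) -> RoiSet:
    """Read named ROI polygons from GeoJSON or CSV (``name,x,y`` per vertex).

    GeoJSON must be a FeatureCollection of Polygons, each with a ``name``
    property. Coordinates are (x=column, y=row) pixel units, no CRS.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such ROI file: {path}")
    rois = RoiSet()
    if path.suffix.lower() in {".geojson", ".json"}:
        payload = json.loads(path.read_text())
        if payload.get("type") != "FeatureCollection":
            raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
        for feat in payload.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                raise FormatError(f"{path}: only Polygon geometries are supported")
            name = feat.get("properties", {}).get("name")
            if not name:
                raise FormatError(f"{path}: every feature needs a 'name' property")
            ring = np.asarray(geom["coordinates"][0], dtype=float)
            # GeoJSON rings repeat the first vertex; drop the closing copy
            if ring.shape[0] > 1 and np.allclose(ring[0], ring[-1]):
                ring = ring[:-1]
            rois.add_polygon(name, ring)
    elif path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        required = {"name", "x", "y"}
        if not required.issubset(table.columns):
            raise FormatError(f"{path}: CSV needs columns {sorted(required)}")
        for name, group in table.groupby("name", sort=False):
            rois.add_polygon(str(name), group[["x", "y"]].to_numpy(dtype=float))
    else:
        raise FormatError(f"{path}: unsupported ROI format {path.suffix!r}")
    if image_shape is not None:
        for name in rois.polygons:
            rois.rasterize(name, image_shape)  # validates non-empty on this grid
    logger.info("read_rois %s -> %d ROIs", path, len(rois.names()))
    return rois


def write_results(records: Iterable[Mapping] | pd.DataFrame, path: str | Path,
                  json_mirror: bool = False) -> Path:
    """Write homogeneous records as a UTF-8 CSV with header (optional JSON mirror)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        table = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    if json_mirror:
        path.with_suffix(".json").write_text(table.to_json(orient="records", indent=2))
    logger.info("write_results %s rows=%d", path, len(table))
    return path


def read_section_records(path: str | Path) -> list[SectionRecord]:
    """Read a per-section manifest CSV into validated SectionRecords."""
    table = pd.read_csv(path, dtype=str).fillna("")
    required = {"section_id", "dog_id", "histology_label", "nirf_call"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    return [
        SectionRecord(
            section_id=row.section_id,
            dog_id=row.dog_id,
            histology_label=row.histology_label,
            nirf_call=row.nirf_call,
            tissue_context=getattr(row, "tissue_context", ""),
        )
        for row in table.itertuples()
    ]
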