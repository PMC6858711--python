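"""File formats: cell tables, margin geometry, images, cohorts, scales.

All coordinates are micrometres in image space (origin top-left, x right,
y down).  Cell tables are CSV with header ``x_um,y_um,marker``; margins are
WKT or GeoJSON polygons; images are TIFF or PNG with the scale in a JSON
sidecar ``{"um_per_pixel": ...}``; cohorts are CSV with the enumerated
column schema of the cohort simulator.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .cells import CELL_COLUMNS, MARKERS, empty_cell_table
from .errors import CellTableError, DataError, GeometryError
from .geometry import TumorGeometry

COHORT_COLUMNS = (
    "patient_id", "group", "stage", "ecog_ps", "ldh_elevated", "treatment",
    "subsequent_it", "response", "pfs_time_months", "pfs_event",
    "os_time_months", "os_event",
)


# -- cell tables -----------------------------------------------------------

def read_cells(path) -> pd.DataFrame:
    """Read and validate a cell CSV; errors carry 1-based line numbers."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CellTableError(f"{path}: empty file, expected a header")
        if [h.strip() for h in header[:3]] != list(CELL_COLUMNS):
            raise CellTableError(
                f"{path}: line 1: expected header {','.join(CELL_COLUMNS)}")
        xs, ys, markers = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise CellTableError(f"{path}: line {lineno}: expected 3 "
                                     f"fields, got {len(row)}")
            try:
                x, y = float(row[0]), float(row[1])
            except ValueError:
                raise CellTableError(
                    f"{path}: line {lineno}: non-numeric coordinate")
            m = row[2].strip()
            if m not in MARKERS:
                raise CellTableError(
                    f"{path}: line {lineno}: unknown marker {m!r}")
            xs.append(x)
            ys.append(y)
            markers.append(m)
    if not xs:
        return empty_cell_table()
    return pd.DataFrame({"x_um": xs, "y_um": ys, "marker": markers})


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.loc[:, list(CELL_COLUMNS)].to_csv(path, index=False)


# -- geometry --------------------------------------------------------------

def _validated_polygons(geom) -> MultiPolygon:
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    if not isinstance(geom, MultiPolygon):
        raise GeometryError(f"expected POLYGON/MULTIPOLYGON, got "
                            f"{geom.geom_type}")
    if not geom.is_valid:
        raise GeometryError("invalid (self-intersecting) polygon")
    return geom


def read_geometry(path, field_bounds=None) -> TumorGeometry:
    """Read a WKT or GeoJSON margin polygon (sniffed from content).

    ``field_bounds`` defaults to the polygon envelope when absent.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise GeometryError(f"{path}: empty geometry file")
    if text.startswith("{"):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            feats = obj.get("features", [])
            if not feats:
                raise GeometryError(f"{path}: empty FeatureCollection")
            obj = feats[0]["geometry"]
        elif obj.get("type") == "Feature":
            obj = obj["geometry"]
        geom = shape(obj)
    else:
        try:
            geom = shapely.wkt.loads(text)
        except shapely.errors.GEOSException as exc:
            raise GeometryError(f"{path}: WKT parse error: {exc}")
    geom = _validated_polygons(geom)
    if field_bounds is None:
        field_bounds = geom.bounds
    return TumorGeometry(geom, tuple(field_bounds))


def write_geometry(geometry: TumorGeometry, path) -> None:
    """Write the margin as WKT (.wkt) or GeoJSON (.json/.geojson)."""
    path = Path(path)
    geom = geometry.polygons
    if path.suffix in (".json", ".geojson"):
        path.write_text(json.dumps(mapping(geom)))
    else:
        path.write_text(geom.wkt)


# -- images + scale sidecars ----------------------------------------------

def write_image(image: np.ndarray, path, um_per_pixel: float | None = None
                ) -> None:
    """Write TIFF/PNG; if a scale is given, also a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, image)
    else:
        from PIL import Image
        Image.fromarray(image).save(path)
    if um_per_pixel is not None:
        write_scale(um_per_pixel, path.with_suffix(path.suffix + ".json"))


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    from PIL import Image
    return np.asarray(Image.open(path).convert("RGB"))


def write_scale(um_per_pixel: float, path) -> None:
    Path(path).write_text(json.dumps({"um_per_pixel": float(um_per_pixel)}))


def read_scale(path) -> float:
    obj = json.loads(Path(path).read_text())
    try:
        scale = float(obj["um_per_pixel"])
    except (KeyError, TypeError, ValueError):
        raise DataError(f"{path}: expected JSON with key 'um_per_pixel'")
    if scale <= 0:
        raise DataError(f"{path}: um_per_pixel must be > 0")
    return scale


# -- cohort tables ---------------------------------------------------------

def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: cohort table missing columns {missing}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
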