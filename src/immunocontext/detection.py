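"""RGB cell detection and five-field densitometry.

Pixels of a hematoxylin / fast-red stained image are classified by channel
dominance: a pixel is chromogen-positive when the red channel exceeds the
larger of green and blue by a margin, nuclear when blue dominates
likewise, and background otherwise.  Connected components of each class,
filtered to a plausible cell-area range, become cell centroids.  Because
each slide carries a single immune marker, red components are labelled
with the slide's marker and blue-only components as ``NEG``.

Densities follow the high-power-field scheme: positive cells are counted
in ``n_fields`` square fields of ``field_area_mm2`` each (default five
fields of 1e-3 mm^2) and the density is the mean field count divided by the
field area.  Hotspot placement greedily maximizes the per-field positive
count on a 10 um grid, emulating a pathologist choosing the densest areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from skimage.measure import label as cc_label, regionprops

from .cells import empty_cell_table, make_cell_table
from .errors import ConfigError, GeometryError
from .synthetic import LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_RED


@dataclass(frozen=True)
class PixelClassParams:
    """Thresholds of the channel-dominance pixel classifier.

    ``red_dominance_threshold`` / ``blue_dominance_threshold`` are on the
    0-255 intensity scale; ``background_luminance_min`` documents the
    minimum mean intensity regarded as clean background (pixels that are
    neither red- nor blue-dominant are treated as background regardless,
    since v1 has no pigment/artifact class).  Cell areas are in um^2; the
    20-400 um^2 default spans lymphocytes through macrophages.
    """

    red_dominance_threshold: float = 60.0
    blue_dominance_threshold: float = 60.0
    background_luminance_min: float = 180.0
    min_cell_area_um2: float = 20.0
    max_cell_area_um2: float = 400.0

    def __post_init__(self) -> None:
        if self.red_dominance_threshold <= 0 or self.blue_dominance_threshold <= 0:
            raise ConfigError("dominance thresholds must be > 0")
        if not 0 <= self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ConfigError("need 0 <= min_cell_area < max_cell_area")


@dataclass(frozen=True)
class FieldSpec:
    """High-power-field counting scheme."""

    n_fields: int = 5
    field_area_mm2: float = 1.0e-3
    placement: str = "hotspot"   # "hotspot", "random" or "grid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ConfigError("n_fields must be >= 1")
        if self.field_area_mm2 <= 0:
            raise ConfigError("field_area_mm2 must be > 0")
        if self.placement not in ("hotspot", "random", "grid"):
            raise ConfigError(f"unknown placement {self.placement!r}")

    @property
    def field_side_um(self) -> float:
        return math.sqrt(self.field_area_mm2 * 1.0e6)


def classify_pixels(image: np.ndarray, um_per_pixel: float,
                    params: PixelClassParams | None = None) -> np.ndarray:
    """Label every pixel as background / nucleus / red-positive.

    Returns a uint8 mask with the codes used by the renderer ground truth
    (0 background, 1 blue nucleus, 2 fast-red positive).
    """
    params = params or PixelClassParams()
    if image.ndim != 3 or image.shape[2] != 3:
        raise ConfigError("expected an RGB image of shape (H, W, 3)")
    if um_per_pixel <= 0:
        raise ConfigError("um_per_pixel must be > 0")
    img = image.astype(np.int16)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    red = (r - np.maximum(g, b)) > params.red_dominance_threshold
    blue = (b - np.maximum(r, g)) > params.blue_dominance_threshold
    mask = np.zeros(image.shape[:2], dtype=np.uint8)
    mask[blue] = LABEL_NUCLEUS
    mask[red] = LABEL_RED  # red dominance wins if both fire
    return mask


def detect_cells(mask: np.ndarray, um_per_pixel: float,
                 params: PixelClassParams | None = None,
                 marker: str = "CD8") -> pd.DataFrame:
    """Extract cell centroids from a labelled pixel mask.

    Connected components (8-connectivity) of the red-positive class become
    cells of the slide's ``marker``; blue-nucleus components become ``NEG``
    cells.  Components outside ``[min_cell_area, max_cell_area]`` are
    dropped.  Centroids are reported in um.
    """
    params = params or PixelClassParams()
    px_area_um2 = um_per_pixel * um_per_pixel
    xs: list[float] = []
    ys: list[float] = []
    labels: list[str] = []
    for code, out_marker in ((LABEL_RED, marker), (LABEL_NUCLEUS, "NEG")):
        comp = cc_label(mask == code, connectivity=2)
        for prop in regionprops(comp):
            area = prop.area * px_area_um2
            if params.min_cell_area_um2 <= area <= params.max_cell_area_um2:
                cy, cx = prop.centroid
                xs.append(cx * um_per_pixel)
                ys.append(cy * um_per_pixel)
                labels.append(out_marker)
    if not xs:
        return empty_cell_table()
    return make_cell_table(xs, ys, labels)


@dataclass(frozen=True)
class FieldDensityResult:
    """Per-field positive counts and the resulting mean density."""

    field_origins_um: np.ndarray    # (n_fields, 2) lower-left corners
    field_side_um: float
    counts: np.ndarray              # positive cells per field
    density_per_mm2: float          # mean(count) / field_area


def _candidate_origins(region: BaseGeometry, side: float,
                       grid_um: float) -> tuple[np.ndarray, np.ndarray]:
    xmin, ymin, xmax, ymax = region.bounds
    x0 = np.arange(xmin, xmax - side + 1e-9, grid_um)
    y0 = np.arange(ymin, ymax - side + 1e-9, grid_um)
    if len(x0) == 0 or len(y0) == 0:
        return np.empty(0), np.empty(0)
    gx, gy = np.meshgrid(x0, y0, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    boxes = shapely.box(gx, gy, gx + side, gy + side)
    ok = shapely.within(boxes, region)
    return gx[ok], gy[ok]


def _count_in_square(xs: np.ndarray, ys: np.ndarray, x0: float, y0: float,
                     side: float) -> int:
    return int(np.count_nonzero((xs >= x0) & (xs < x0 + side)
                                & (ys >= y0) & (ys < y0 + side)))


def field_density(cells: pd.DataFrame, region: BaseGeometry,
                  spec: FieldSpec | None = None,
                  grid_um: float = 10.0) -> FieldDensityResult:
    """Count positive cells in non-overlapping square fields inside a region.

    ``region`` is any shapely geometry (typically a tumor compartment).
    Positive cells are those whose marker is not ``NEG``.  Hotspot placement
    picks, greedily and without overlap, the grid-aligned square with the
    highest positive count (ties broken by smallest ``(x, y)``).
    """
    spec = spec or FieldSpec()
    side = spec.field_side_um
    gx, gy = _candidate_origins(region, side, grid_um)
    if len(gx) == 0:
        raise GeometryError("region too small for the requested field size")

    pos = cells.loc[cells["marker"] != "NEG"] if len(cells) else cells
    xs = pos["x_um"].to_numpy(dtype=float) if len(pos) else np.empty(0)
    ys = pos["y_um"].to_numpy(dtype=float) if len(pos) else np.empty(0)

    # Deterministic tie-break: iterate candidates in (x, y) order.
    order = np.lexsort((gy, gx))
    gx, gy = gx[order], gy[order]
    counts_all = np.array([_count_in_square(xs, ys, x0, y0, side)
                           for x0, y0 in zip(gx, gy)])

    chosen: list[tuple[float, float]] = []
    counts: list[int] = []
    if spec.placement == "random":
        rng = np.random.default_rng(spec.seed)
        available = np.ones(len(gx), dtype=bool)
        for _ in range(spec.n_fields):
            idx_pool = np.flatnonzero(available)
            if len(idx_pool) == 0:
                raise GeometryError(
                    f"could not place {spec.n_fields} non-overlapping fields")
            k = int(rng.choice(idx_pool))
            chosen.append((gx[k], gy[k]))
            counts.append(int(counts_all[k]))
            available &= ((np.abs(gx - gx[k]) >= side)
                          | (np.abs(gy - gy[k]) >= side))
    else:
        available = np.ones(len(gx), dtype=bool)
        for _ in range(spec.n_fields):
            idx_pool = np.flatnonzero(available)
            if len(idx_pool) == 0:
                raise GeometryError(
                    f"could not place {spec.n_fields} non-overlapping fields")
            if spec.placement == "hotspot":
                k = idx_pool[int(np.argmax(counts_all[idx_pool]))]
            else:  # grid: first available in (x, y) order
                k = idx_pool[0]
            chosen.append((gx[k], gy[k]))
            counts.append(int(counts_all[k]))
            available &= ((np.abs(gx - gx[k]) >= side)
                          | (np.abs(gy - gy[k]) >= side))

    counts_arr = np.asarray(counts, dtype=int)
    density = counts_arr.mean() / spec.field_area_mm2
    return FieldDensityResult(field_origins_um=np.asarray(chosen, dtype=float),
                              field_side_um=side, counts=counts_arr,
                              density_per_mm2=float(density))
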