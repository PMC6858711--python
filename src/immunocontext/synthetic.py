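"""Synthetic tissue scenes: marked point patterns and pseudo-IHC renders.

Cells of each marker are drawn from an inhomogeneous Poisson process whose
intensity depends on the signed distance ``d`` to the invasive margin
(negative inside the tumor):

    lambda_m(p) = max(0, lambda_base(m, side(p)) + slope_m * d(p))

where ``lambda_base`` is the per-side base intensity in cells/mm^2 and
``slope_m`` (cells/mm^2 per um) tilts the intensity across the margin.
Clamping at zero keeps the linear law well defined everywhere.  Sampling
uses Poisson thinning against a constant envelope, so expected counts equal
the intensity integrated over area and runs are reproducible given the seed.

The renderer emulates a single-marker immunohistochemistry slide: every
cell gets a hematoxylin-blue nucleus disk and chromogen-positive cells
additionally get a fast-red disk, over a bright background with optional
additive Gaussian pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk

from .cells import MARKERS, POSITIVE_MARKERS, empty_cell_table, make_cell_table
from .errors import ConfigError, RenderError
from .geometry import UM2_PER_MM2, TumorGeometry, blob_margin, circle_margin

# Pseudo-IHC palette (RGB, 0-255)
BACKGROUND_RGB = (235, 233, 231)
HEMATOXYLIN_RGB = (70, 70, 185)
FAST_RED_RGB = (210, 60, 85)

# Ground-truth / classification label codes
LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_RED = 0, 1, 2


def _marker_map(value, name: str) -> dict[str, float]:
    """Expand a scalar or partial mapping into a full per-marker dict."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(MARKERS)
        if unknown:
            raise ConfigError(f"{name}: unknown markers {sorted(unknown)}")
        out = {m: float(value.get(m, 0.0)) for m in MARKERS}
    else:
        out = {m: float(value) for m in MARKERS}
    for m, v in out.items():
        if not math.isfinite(v):
            raise ConfigError(f"{name}[{m}] must be finite, got {v}")
    return out


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic tissue scene.

    Default intensities emulate an immune-infiltrated melanoma field:
    moderate cytotoxic T-cell (CD8) density that is higher outside than
    inside the tumor, myeloid (CD163) density higher inside, and abundant
    marker-negative nucleated cells everywhere.
    """

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    margin_shape: str = "circle"          # "circle" or "blob"
    margin_radius_um: float = 400.0
    lambda_in: Mapping[str, float] = field(
        default_factory=lambda: {"CD8": 300.0, "CD163": 700.0, "NEG": 1500.0})
    lambda_out: Mapping[str, float] = field(
        default_factory=lambda: {"CD8": 600.0, "CD163": 400.0, "NEG": 1500.0})
    gradient_slope: Mapping[str, float] = field(
        default_factory=lambda: {"CD8": 0.0, "CD163": 0.0, "NEG": 0.0})
    blob_max_amplitude: float = 0.2
    min_spacing_um: float = 0.0           # > 0 enables hard-core thinning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ConfigError("field dimensions must be > 0")
        if self.margin_radius_um <= 0:
            raise ConfigError("margin_radius_um must be > 0")
        if self.margin_shape not in ("circle", "blob"):
            raise ConfigError(f"unknown margin_shape {self.margin_shape!r}")
        for name in ("lambda_in", "lambda_out"):
            vals = _marker_map(getattr(self, name), name)
            if any(v < 0 for v in vals.values()):
                raise ConfigError(f"{name} intensities must be >= 0")
            object.__setattr__(self, name, vals)
        object.__setattr__(self, "gradient_slope",
                           _marker_map(self.gradient_slope, "gradient_slope"))
        if self.min_spacing_um < 0:
            raise ConfigError("min_spacing_um must be >= 0")

    @property
    def field_bounds(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.field_width_um, self.field_height_um)


@dataclass(frozen=True)
class Scene:
    """A generated tissue scene: geometry + cells + provenance."""

    geometry: TumorGeometry
    cells: pd.DataFrame
    config: SceneConfig


def make_margin(config: SceneConfig) -> TumorGeometry:
    """Build the margin geometry described by a :class:`SceneConfig`."""
    center = (config.field_width_um / 2.0, config.field_height_um / 2.0)
    if config.margin_shape == "circle":
        return circle_margin(center, config.margin_radius_um,
                             config.field_bounds)
    return blob_margin(center, config.margin_radius_um, config.field_bounds,
                       seed=config.seed,
                       max_amplitude=config.blob_max_amplitude)


def thin_min_spacing(cells: pd.DataFrame, min_spacing_um: float) -> pd.DataFrame:
    """Greedy hard-core thinning: keep each cell only if it is at least
    ``min_spacing_um`` from every previously kept cell (table order)."""
    if min_spacing_um <= 0 or len(cells) < 2:
        return cells.reset_index(drop=True)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=min_spacing_um, output_type="ndarray")
    keep = np.ones(len(cells), dtype=bool)
    if len(pairs):
        order = np.argsort(pairs[:, 0], kind="stable")
        for i, j in pairs[order]:
            if keep[i] and keep[j]:
                keep[max(i, j)] = False
    return cells.loc[keep].reset_index(drop=True)


def generate_tissue_scene(config: SceneConfig) -> Scene:
    """Sample one scene from the margin-referenced Poisson model.

    Markers are processed in the fixed order CD8, CD163, NEG from a single
    seeded generator, so output is deterministic given ``config.seed``.
    """
    geometry = make_margin(config)
    rng = np.random.default_rng(config.seed)
    width, height = config.field_width_um, config.field_height_um
    area_mm2 = width * height / UM2_PER_MM2
    diag = math.hypot(width, height)

    frames = []
    for m in MARKERS:
        lam_in = config.lambda_in[m]
        lam_out = config.lambda_out[m]
        slope = config.gradient_slope[m]
        # Constant thinning envelope: the linear law is bounded on the field
        # by its values at the extreme attainable signed distances.
        lam_max = max(lam_in, lam_out,
                      lam_in - slope * diag if slope < 0 else lam_in,
                      lam_out + slope * diag if slope > 0 else lam_out)
        lam_max = max(0.0, lam_max)
        n_cand = rng.poisson(lam_max * area_mm2) if lam_max > 0 else 0
        if n_cand == 0:
            continue
        x = rng.uniform(0.0, width, size=n_cand)
        y = rng.uniform(0.0, height, size=n_cand)
        u = rng.uniform(0.0, 1.0, size=n_cand)
        d = geometry.signed_distance(x, y)
        base = np.where(d <= 0, lam_in, lam_out)
        lam = np.clip(base + slope * d, 0.0, None)
        accept = u * lam_max < lam
        if accept.any():
            frames.append(make_cell_table(x[accept], y[accept],
                                          np.full(accept.sum(), m)))
    cells = (pd.concat(frames, ignore_index=True) if frames
             else empty_cell_table())
    if config.min_spacing_um > 0:
        cells = thin_min_spacing(cells, config.min_spacing_um)
    return Scene(geometry=geometry, cells=cells, config=config)


# -- pseudo-IHC rendering --------------------------------------------------

@dataclass(frozen=True)
class RenderedImage:
    """RGB render of a scene plus scale metadata and ground truth."""

    image: np.ndarray            # (H, W, 3) uint8
    um_per_pixel: float
    truth_mask: np.ndarray       # (H, W) uint8, LABEL_* codes, noise-free
    cells: pd.DataFrame          # ground-truth cell list


def render_ihc_image(scene: Scene, um_per_pixel: float = 0.5,
                     nucleus_radius_um: float = 3.0,
                     positive_radius_um: float = 4.0,
                     noise_sd: float = 0.0,
                     seed: int | None = None) -> RenderedImage:
    """Render a scene as a pseudo-IHC RGB image.

    Every cell is drawn as a hematoxylin-blue nucleus disk; CD8/CD163 cells
    additionally carry a fast-red chromogen disk (drawn on top, and by
    default larger than the nucleus so positives present as single red
    objects).  ``noise_sd`` adds i.i.d. Gaussian noise per channel.  The
    noise stream is seeded by ``seed`` (defaults to the scene seed).
    """
    if um_per_pixel <= 0:
        raise RenderError("um_per_pixel must be > 0")
    if nucleus_radius_um <= 0 or positive_radius_um <= 0:
        raise RenderError("disk radii must be > 0")
    if nucleus_radius_um / um_per_pixel < 1.0:
        raise RenderError(
            f"nucleus radius {nucleus_radius_um} um is below one pixel at "
            f"{um_per_pixel} um/px; cells would be undetectable")

    cfg = scene.config
    h = math.ceil(cfg.field_height_um / um_per_pixel)
    w = math.ceil(cfg.field_width_um / um_per_pixel)
    image = np.empty((h, w, 3), dtype=float)
    image[:] = BACKGROUND_RGB
    truth = np.zeros((h, w), dtype=np.uint8)

    cells = scene.cells
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float) / um_per_pixel
    positive = cells["marker"].isin(POSITIVE_MARKERS).to_numpy()

    for (cx, cy) in xy:  # nuclei first
        rr, cc = draw_disk((cy, cx), nucleus_radius_um / um_per_pixel,
                           shape=(h, w))
        image[rr, cc] = HEMATOXYLIN_RGB
        truth[rr, cc] = LABEL_NUCLEUS
    for (cx, cy) in xy[positive]:  # chromogen on top
        rr, cc = draw_disk((cy, cx), positive_radius_um / um_per_pixel,
                           shape=(h, w))
        image[rr, cc] = FAST_RED_RGB
        truth[rr, cc] = LABEL_RED

    if noise_sd > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        image += rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return RenderedImage(image=image, um_per_pixel=float(um_per_pixel),
                         truth_mask=truth, cells=cells)
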