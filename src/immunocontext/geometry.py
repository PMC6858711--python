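"""Tumor-margin geometry: signed distances and offset-band areas.

The invasive tumor margin is represented as one or more simple polygons in
slide coordinates (micrometres; origin top-left, x rightward, y downward).
The sign convention for distance to the margin follows the density-histogram
layout used throughout the package: **negative inside the tumor parenchyma,
positive in the host tissue**, zero on the margin itself.

Distance-level sets are computed by polygon offsetting (positive buffer for
outward bands, erosion for inward bands); with round joins a shapely buffer
is exactly the Euclidean distance level set, so band areas obtained by
differencing offsets agree with the per-cell signed distances.

All areas are reported in mm^2 (1 mm^2 = 1e6 um^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon, box

from .errors import GeometryError

UM2_PER_MM2 = 1.0e6

# Segments per quarter circle used for buffering; at the scales used here
# (margin radii >= 100 um, offsets <= 500 um) the discretization error of a
# band area is < 1e-5 mm^2.
QUAD_SEGS = 64


@dataclass(frozen=True)
class TumorGeometry:
    """Invasive-margin polygon(s) plus the rectangular field of view.

    Parameters
    ----------
    polygons
        A shapely ``Polygon`` or ``MultiPolygon`` whose exterior rings are
        the invasive margin.  Interior rings (holes) are host tissue.
    field_bounds
        ``(xmin, ymin, xmax, ymax)`` of the imaged field in um.  Band areas
        and compartment areas are clipped to this rectangle so densities
        stay unbiased near image edges.
    """

    polygons: MultiPolygon
    field_bounds: tuple[float, float, float, float]
    clipped: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        geom = self.polygons
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        if not isinstance(geom, MultiPolygon):
            raise GeometryError(
                f"expected Polygon or MultiPolygon, got {type(geom).__name__}"
            )
        if geom.is_empty or geom.area <= 0:
            raise GeometryError("empty tumor geometry")
        if not geom.is_valid:
            raise GeometryError(
                "invalid (self-intersecting or degenerate) margin polygon"
            )
        object.__setattr__(self, "polygons", geom)
        xmin, ymin, xmax, ymax = map(float, self.field_bounds)
        if not (xmax > xmin and ymax > ymin):
            raise GeometryError("field_bounds must be a non-empty rectangle")
        object.__setattr__(self, "field_bounds", (xmin, ymin, xmax, ymax))
        clipped = not geom.within(box(xmin, ymin, xmax, ymax))
        object.__setattr__(self, "clipped", clipped)
        if clipped:
            warnings.warn(
                "tumor margin extends beyond field_bounds; areas are clipped",
                stacklevel=2,
            )

    # -- basic properties --------------------------------------------------

    @property
    def field_box(self) -> Polygon:
        return box(*self.field_bounds)

    @property
    def boundary(self):
        """The invasive margin as a (Multi)LineString."""
        return self.polygons.boundary

    @property
    def tumor_area_mm2(self) -> float:
        """Intratumoral area inside the field of view, in mm^2."""
        return self.polygons.intersection(self.field_box).area / UM2_PER_MM2

    # -- signed distance ---------------------------------------------------

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorized point-in-tumor test (holes count as host tissue)."""
        return shapely.contains_xy(self.polygons, np.asarray(x, float),
                                   np.asarray(y, float))

    def signed_distance(self, x, y) -> np.ndarray:
        """Signed Euclidean distance (um) to the nearest margin point.

        Negative inside the tumor parenchyma, positive outside, 0 on the
        margin.  Points outside ``field_bounds`` trigger a warning but the
        distance is still computed.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if x.shape != y.shape:
            raise GeometryError("x and y must have the same shape")
        xmin, ymin, xmax, ymax = self.field_bounds
        if len(x) and (np.any(x < xmin) or np.any(x > xmax)
                       or np.any(y < ymin) or np.any(y > ymax)):
            warnings.warn("cells outside field_bounds; distances computed "
                          "anyway", stacklevel=2)
        pts = shapely.points(np.column_stack([x, y]))
        d = shapely.distance(pts, self.boundary)
        inside = self.contains_xy(x, y)
        return np.where(inside, -d, d)

    # -- offsetting and band areas ----------------------------------------

    def offset_region(self, d: float):
        """Region at signed distance <= ``d`` from the tumor interior.

        ``d > 0`` dilates the tumor region by ``d`` um, ``d < 0`` erodes it,
        ``d = 0`` returns the tumor polygons themselves.
        """
        if d == 0:
            return self.polygons
        return self.polygons.buffer(d, quad_segs=QUAD_SEGS)

    def band_area(self, d_lo: float, d_hi: float) -> tuple[float, bool]:
        """Area (mm^2) of the band ``d_lo < d <= d_hi``, clipped to the field.

        Returns ``(area_mm2, degenerate)`` where ``degenerate`` is True when
        an erosion collapsed to nothing (the band cannot exist inside the
        tumor at that depth).
        """
        if not (np.isfinite(d_lo) and np.isfinite(d_hi)):
            raise GeometryError("band edges must be finite")
        if d_lo >= d_hi:
            raise GeometryError(f"need d_lo < d_hi, got ({d_lo}, {d_hi})")
        outer = self.offset_region(d_hi)
        inner = self.offset_region(d_lo)
        degenerate = d_hi <= 0 and outer.is_empty
        band = outer.difference(inner).intersection(self.field_box)
        return band.area / UM2_PER_MM2, degenerate or band.is_empty

    def peritumoral_region(self, extent_um: float = 500.0,
                           inner_extent_um: float = 0.0):
        """Host-tissue band adjacent to the margin, clipped to the field.

        By default the 500 um band *outside* the margin; ``inner_extent_um``
        optionally extends the compartment inward (for a reading of the
        peritumoral region as centered on the border).
        """
        if extent_um <= 0:
            raise GeometryError("peritumoral extent must be > 0")
        region = self.offset_region(extent_um).difference(
            self.offset_region(-inner_extent_um) if inner_extent_um > 0
            else self.polygons
        )
        return region.intersection(self.field_box)


# -- margin generators -----------------------------------------------------

def circle_margin(center: tuple[float, float], radius_um: float,
                  field_bounds: tuple[float, float, float, float],
                  quad_segs: int = 128) -> TumorGeometry:
    """Circular invasive margin (a 4*quad_segs-gon approximation)."""
    if radius_um <= 0:
        raise GeometryError("radius must be > 0")
    poly = Point(*center).buffer(radius_um, quad_segs=quad_segs)
    return TumorGeometry(poly, field_bounds)


def blob_margin(center: tuple[float, float], radius_um: float,
                field_bounds: tuple[float, float, float, float],
                seed: int = 0, n_harmonics: int = 4,
                max_amplitude: float = 0.2,
                n_vertices: int = 512) -> TumorGeometry:
    """Irregular ("blob") margin: a radial Fourier perturbation of a circle.

    The radius law is ``r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k))``
    over harmonics k = 2..(n_harmonics+1) with ``sum_k |a_k| <= max_amplitude
    < 1``, so the curve is star-shaped about the center and therefore always
    a simple polygon.
    """
    if radius_um <= 0:
        raise GeometryError("radius must be > 0")
    if not 0 <= max_amplitude < 1:
        raise GeometryError("max_amplitude must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ks = np.arange(2, 2 + n_harmonics)
    raw = rng.uniform(-1.0, 1.0, size=n_harmonics) / ks  # damp high orders
    total = np.abs(raw).sum()
    amps = raw * (max_amplitude / total if total > 0 else 0.0)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius_um * (1.0 + np.sum(
        amps[:, None] * np.cos(ks[:, None] * theta[None, :] + phases[:, None]),
        axis=0))
    xs = center[0] + r * np.cos(theta)
    ys = center[1] + r * np.sin(theta)
    poly = Polygon(np.column_stack([xs, ys]))
    return TumorGeometry(poly, field_bounds)
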