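"""Margin-referenced spatial profiling of cell patterns.

Given cells and a tumor-margin geometry, this module computes per-cell
signed distances, assigns tumor compartments, and builds the 20 um
distance-class density histogram: counts of each marker in consecutive
bands of signed distance within +/-100 um of the margin, normalized by the
band areas (clipped to the field of view) to give densities in cells/mm^2.

Conventions: distance is negative inside the tumor (the histogram reads
tumor on the left, host tissue on the right); a cell exactly on the margin
is intratumoral; bands are half-open ``(lo, hi]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .geometry import UM2_PER_MM2, TumorGeometry
from .cells import MARKERS


def signed_distance(cells: pd.DataFrame,
                    geometry: TumorGeometry) -> np.ndarray:
    """Per-cell signed distance (um) to the invasive margin."""
    if not len(cells):
        return np.empty(0)
    return geometry.signed_distance(cells["x_um"].to_numpy(),
                                    cells["y_um"].to_numpy())


def assign_compartment(cells: pd.DataFrame, geometry: TumorGeometry,
                       peritumoral_extent_um: float = 500.0,
                       inner_extent_um: float = 0.0) -> np.ndarray:
    """Label each cell intratumoral / peritumoral / outside.

    Intratumoral: signed distance <= -inner_extent (0 by default, i.e. any
    point in the parenchyma, boundary included); peritumoral: within the
    margin band up to ``peritumoral_extent_um`` outside (and optionally
    ``inner_extent_um`` inside); outside: beyond that.
    """
    if peritumoral_extent_um <= 0:
        raise GeometryError("peritumoral extent must be > 0")
    d = signed_distance(cells, geometry)
    labels = np.full(len(d), "outside", dtype=object)
    labels[d <= 0] = "intratumoral"
    labels[(d > 0) & (d <= peritumoral_extent_um)] = "peritumoral"
    if inner_extent_um > 0:
        labels[(d > -inner_extent_um) & (d <= 0)] = "peritumoral"
    return labels


@dataclass(frozen=True)
class DistanceProfile:
    """Per-band counts, areas and densities around the margin."""

    band_edges_um: np.ndarray          # e.g. -100, -80, ..., 100
    counts: pd.DataFrame               # rows = bands, columns = markers
    band_areas_mm2: np.ndarray
    degenerate: np.ndarray             # bool per band (collapsed erosion)
    n_excluded: int                    # cells with |d| > extent

    @property
    def densities(self) -> pd.DataFrame:
        """Cells/mm^2 per band and marker (NaN for degenerate bands)."""
        areas = np.where(self.band_areas_mm2 > 0, self.band_areas_mm2, np.nan)
        return self.counts.div(areas, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: band_lo_um, band_hi_um, marker, count, area, density."""
        rows = []
        dens = self.densities
        for i, (lo, hi) in enumerate(zip(self.band_edges_um[:-1],
                                         self.band_edges_um[1:])):
            for m in self.counts.columns:
                rows.append({
                    "band_lo_um": lo, "band_hi_um": hi, "marker": m,
                    "count": int(self.counts.iloc[i][m]),
                    "area_mm2": self.band_areas_mm2[i],
                    "density_per_mm2": dens.iloc[i][m],
                })
        return pd.DataFrame(rows)


def band_area(geometry: TumorGeometry, d_lo: float,
              d_hi: float) -> tuple[float, bool]:
    """Area (mm^2) of the signed-distance band ``(d_lo, d_hi]``."""
    return geometry.band_area(d_lo, d_hi)


def band_histogram(cells: pd.DataFrame, geometry: TumorGeometry,
                   band_width_um: float = 20.0,
                   extent_um: float = 100.0,
                   markers=MARKERS) -> DistanceProfile:
    """Build the distance-class density histogram around the margin.

    Counts cells of each marker in consecutive ``band_width_um`` bands of
    signed distance within ``+/-extent_um`` of the margin; densities are
    counts over band areas clipped to the field of view.  Cells beyond the
    extent are excluded and tallied in ``n_excluded``.
    """
    if band_width_um <= 0 or extent_um <= 0:
        raise GeometryError("band width and extent must be > 0")
    n_half = extent_um / band_width_um
    if abs(n_half - round(n_half)) > 1e-9:
        raise GeometryError("extent must be divisible by band width")
    edges = np.arange(-extent_um, extent_um + band_width_um / 2,
                      band_width_um)

    areas = np.empty(len(edges) - 1)
    degenerate = np.empty(len(edges) - 1, dtype=bool)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        areas[i], degenerate[i] = geometry.band_area(lo, hi)
    if degenerate.all():
        raise GeometryError("all distance bands are degenerate")

    d = signed_distance(cells, geometry)
    counts = pd.DataFrame(0, index=range(len(edges) - 1),
                          columns=list(markers))
    in_range = np.zeros(len(d), dtype=bool)
    if len(d):
        # Half-open (lo, hi] bands; the innermost band includes d == -extent.
        idx = np.searchsorted(edges, d, side="left") - 1
        idx[d == -extent_um] = 0
        in_range = (d >= -extent_um) & (d <= extent_um)
        for m in markers:
            sel = in_range & (cells["marker"].to_numpy() == m)
            if sel.any():
                counts[m] = np.bincount(idx[sel], minlength=len(edges) - 1)
    n_excluded = int(len(d) - np.count_nonzero(in_range))
    return DistanceProfile(band_edges_um=edges, counts=counts,
                           band_areas_mm2=areas, degenerate=degenerate,
                           n_excluded=n_excluded)


@dataclass(frozen=True)
class CompartmentDensities:
    """Densities and positive-cell fractions per compartment and marker."""

    densities_per_mm2: pd.DataFrame   # rows = compartments, cols = markers
    fractions_pct: pd.DataFrame       # marker share of all cells, percent
    counts: pd.DataFrame
    areas_mm2: pd.Series              # per compartment

    def density(self, marker: str, compartment: str) -> float:
        return float(self.densities_per_mm2.loc[compartment, marker])

    def fraction(self, marker: str, compartment: str) -> float:
        return float(self.fractions_pct.loc[compartment, marker])


def compartment_densities(cells: pd.DataFrame, geometry: TumorGeometry,
                          peritumoral_extent_um: float = 500.0,
                          inner_extent_um: float = 0.0,
                          markers=MARKERS) -> CompartmentDensities:
    """Marker densities (cells/mm^2) and positive fractions per compartment.

    The fraction is the marker's share of *all* nucleated cells in the
    compartment, in percent (0 when the compartment holds no cells).
    """
    intr_area = geometry.tumor_area_mm2
    if inner_extent_um > 0:
        eroded = geometry.offset_region(-inner_extent_um)
        intr_area = eroded.intersection(geometry.field_box).area / UM2_PER_MM2
    peri_area = geometry.peritumoral_region(
        peritumoral_extent_um, inner_extent_um).area / UM2_PER_MM2
    areas = pd.Series({"intratumoral": intr_area, "peritumoral": peri_area})
    if (areas <= 0).any():
        raise GeometryError("zero-area compartment")

    labels = assign_compartment(cells, geometry, peritumoral_extent_um,
                                inner_extent_um)
    counts = pd.DataFrame(0, index=["intratumoral", "peritumoral"],
                          columns=list(markers))
    for comp in counts.index:
        sel = labels == comp
        for m in markers:
            counts.loc[comp, m] = int(
                np.count_nonzero(sel & (cells["marker"].to_numpy() == m))
            ) if len(cells) else 0
    dens = counts.div(areas, axis=0)
    totals = counts.sum(axis=1)
    frac = counts.div(totals.where(totals > 0), axis=0).fillna(0.0) * 100.0
    return CompartmentDensities(densities_per_mm2=dens, fractions_pct=frac,
                                counts=counts, areas_mm2=areas)


def plot_profile(profile: DistanceProfile, path: str,
                 markers=("CD8", "CD163")) -> None:
    """Write the distance-class density histogram as an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = profile.band_edges_um
    centers = (edges[:-1] + edges[1:]) / 2.0
    dens = profile.densities
    fig, axes = plt.subplots(1, len(markers), figsize=(5 * len(markers), 3.2),
                             squeeze=False)
    width = 0.9 * (edges[1] - edges[0])
    for ax, m in zip(axes[0], markers):
        colors = np.where(centers <= 0, "forestgreen", "darkorange")
        ax.bar(centers, dens[m].to_numpy(), width=width, color=colors)
        ax.axvline(0, color="red", linestyle="--", linewidth=1)
        ax.set_xlabel("distance to margin (um)\ntumor <- 0 -> host")
        ax.set_ylabel("cells / mm$^2$")
        ax.set_title(m)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
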