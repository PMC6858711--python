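"""Cell records: the atomic unit of all spatial computation.

A "cell" is a point in slide coordinates (micrometres, image convention:
origin top-left, x rightward, y downward) carrying a marker label.  Because
each slide is stained for a single immune marker, the label set is the
slide's marker (``CD8`` or ``CD163``) for chromogen-positive cells plus
``NEG`` for hematoxylin-only (counterstained, marker-negative) cells.

Cell collections flow through the package as :class:`pandas.DataFrame`
objects with columns ``x_um``, ``y_um``, ``marker`` (and optionally
``source``); :class:`CellRecord` is the scalar view of one row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CellTableError

#: Allowed marker labels.
MARKERS = ("CD8", "CD163", "NEG")

#: Positive (chromogen-stained) markers.
POSITIVE_MARKERS = ("CD8", "CD163")

CELL_COLUMNS = ("x_um", "y_um", "marker")


@dataclass(frozen=True)
class CellRecord:
    """One detected or simulated cell."""

    x_um: float
    y_um: float
    marker: str
    source: str = "simulated"  # or "detected"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise CellTableError("cell coordinates must be finite")
        if self.marker not in MARKERS:
            raise CellTableError(
                f"unknown marker {self.marker!r}; expected one of {MARKERS}"
            )


def empty_cell_table() -> pd.DataFrame:
    """Return an empty cell table with the canonical columns."""
    return pd.DataFrame({"x_um": pd.Series(dtype=float),
                         "y_um": pd.Series(dtype=float),
                         "marker": pd.Series(dtype=object)})


def make_cell_table(x_um, y_um, marker) -> pd.DataFrame:
    """Assemble and validate a cell table from coordinate/label arrays."""
    df = pd.DataFrame({
        "x_um": np.asarray(x_um, dtype=float),
        "y_um": np.asarray(y_um, dtype=float),
        "marker": np.asarray(marker, dtype=object),
    })
    validate_cell_table(df)
    return df


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical schema; raise :class:`CellTableError` on failure."""
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"cell table missing columns: {missing}")
    if len(df):
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise CellTableError(f"non-finite coordinates at row {bad}")
        bad_marker = ~df["marker"].isin(MARKERS)
        if bad_marker.any():
            i = int(np.flatnonzero(bad_marker.to_numpy())[0])
            raise CellTableError(
                f"unknown marker {df['marker'].iloc[i]!r} at row {i}"
            )
    return df


def cells_to_records(df: pd.DataFrame, source: str = "simulated") -> list[CellRecord]:
    """Convert a cell table to a list of :class:`CellRecord`."""
    return [CellRecord(float(r.x_um), float(r.y_um), str(r.marker), source)
            for r in df.itertuples(index=False)]


def records_to_cells(records: Iterable[CellRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return empty_cell_table()
    return make_cell_table([r.x_um for r in records],
                           [r.y_um for r in records],
                           [r.marker for r in records])
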