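"""Dimensionless RBC shape descriptors computed from size measures.

Given per-cell size measures (area A, perimeter P, convex-hull area C,
caliper length L and breadth B) the six classical descriptors are

    ellipticity   = L / B                     (>= 1 for L >= B)
    elongation    = (L - B) / (L + B)         (0 for a circle)
    solidity      = A / C                     (1 for convex outlines)
    roundness     = 4 A / (pi L^2)            (1 for a circle)
    form factor   = 4 pi A / P^2              (1 for a circle)
    contour index = P / sqrt(A)               (2 sqrt(pi) for a circle)

``roundness`` uses the caliper length as the major axis.  Values are never
clamped into their theoretical ranges: rasterization can push a descriptor
slightly outside, and that is reported, not hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ShapeIndices", "compute_indices", "add_shape_columns", "SHAPE_COLUMNS"]

#: Column names appended to per-cell tables, in fixed order.
SHAPE_COLUMNS = (
    "roundness",
    "form_factor",
    "contour_index",
    "elongation",
    "ellipticity",
    "solidity",
)

#: Theoretical minimum of the contour index, attained by a circle.
CONTOUR_INDEX_MIN = 2.0 * math.sqrt(math.pi)


@dataclass(frozen=True)
class ShapeIndices:
    ellipticity: float
    elongation: float
    solidity: float
    roundness: float
    form_factor: float
    contour_index: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SHAPE_COLUMNS}


def compute_indices(m) -> ShapeIndices:
    """Compute the six shape descriptors from a cell's size measures.

    ``m`` needs attributes ``area``, ``outline``, ``convex``, ``length`` and
    ``breadth`` (a :class:`~erymorph.morphometry.CellMeasurement` or any
    object shaped like one), all strictly positive.
    """
    area, outline = m.area, m.outline
    convex, length, breadth = m.convex, m.length, m.breadth
    for name, v in (
        ("area", area),
        ("outline", outline),
        ("convex", convex),
        ("length", length),
        ("breadth", breadth),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return ShapeIndices(
        ellipticity=length / breadth,
        elongation=(length - breadth) / (length + breadth),
        solidity=area / convex,
        roundness=4.0 * area / (math.pi * length**2),
        form_factor=4.0 * math.pi * area / outline**2,
        contour_index=outline / math.sqrt(area),
    )


def add_shape_columns(cells: pd.DataFrame) -> pd.DataFrame:
    """Append the six shape-index columns to a per-cell measurement table.

    Vectorized equivalent of :func:`compute_indices` row by row; returns a
    new frame, input untouched.
    """
    required = ("area", "outline", "convex", "length", "breadth")
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise KeyError(f"measurement columns missing: {missing}")
    sub = cells[list(required)].to_numpy(dtype=float)
    if not (sub > 0).all():
        raise ValueError("all size measures must be strictly positive")
    area, outline, convex, length, breadth = sub.T
    out = cells.copy()
    out["roundness"] = 4.0 * area / (np.pi * length**2)
    out["form_factor"] = 4.0 * np.pi * area / outline**2
    out["contour_index"] = outline / np.sqrt(area)
    out["elongation"] = (length - breadth) / (length + breadth)
    out["ellipticity"] = length / breadth
    out["solidity"] = area / convex
    return out


def flag_out_of_range(cells: pd.DataFrame, tol: float = 0.03) -> pd.Series:
    """Mark cells whose descriptors exceed theoretical bounds beyond ``tol``.

    Rasterized contours can nudge form factor above 1 or the contour index
    below 2*sqrt(pi); anything outside the bound by more than the relative
    tolerance is flagged for inspection.
    """
    bad = (
        (cells["form_factor"] > 1.0 + tol)
        | (cells["solidity"] > 1.0 + tol)
        | (cells["roundness"] > 1.0 + tol)
        | (cells["contour_index"] < CONTOUR_INDEX_MIN * (1.0 - tol))
    )
    return bad.rename("shape_out_of_range")
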