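"""Segmentation of smear images and physical size measurement of cells.

Cells appear darker than the background in a stained smear.  Segmentation
thresholds the luminance (Otsu by default), fills interior holes (central
pallor), drops anything touching the image border, and extracts one
sub-pixel boundary polygon per connected component.  Fused components
(overlapping cells) and debris are removed by solidity/area rules rather
than split — only clean single cells are measured.

Measurements are reported in physical units via the um-per-pixel
calibration:

* ``area`` (um^2) and ``convex`` (um^2, convex-hull area) from the polygon;
* ``outline`` (um): perimeter of a lightly smoothed contour — raw
  marching-squares vertices overestimate the perimeter of smooth shapes, so
  boundary coordinates are circularly Gaussian-filtered first;
* ``length``: maximum Feret (caliper) diameter; ``breadth``: maximum
  caliper width perpendicular to the length axis;
* ``minimal_radius`` / ``maximal_radius``: min/max centroid-to-boundary
  distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure as skmeasure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

__all__ = [
    "CellContour",
    "CellMeasurement",
    "SegmentationConfig",
    "segment_cells",
    "filter_nonoverlapping",
    "measure_cell",
    "measure_image",
    "MEASUREMENT_COLUMNS",
]

#: Documented column order of the per-cell measurement table.
MEASUREMENT_COLUMNS = (
    "cell_id",
    "sheep_id",
    "area",
    "outline",
    "convex",
    "min_radius",
    "max_radius",
    "length",
    "breadth",
)


class MeasurementError(ValueError):
    """Raised for degenerate contours that cannot be measured."""


@dataclass(frozen=True)
class CellContour:
    """Closed boundary polygon of one segmented cell, pixel coordinates.

    ``vertices`` is an (n, 2) array of (x, y) points tracing the boundary
    once; the polygon is implicitly closed.  Must be simple and have at
    least 8 vertices.
    """

    cell_id: int
    vertices: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 8:
            raise ValueError("contour needs an (n>=8, 2) vertex array")
        object.__setattr__(self, "vertices", verts)
        if not Polygon(verts).is_simple:
            raise ValueError("contour polygon must be simple")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class CellMeasurement:
    """Seven size measures of one cell, physical units (um / um^2)."""

    cell_id: int
    area: float
    outline: float
    convex: float
    minimal_radius: float
    maximal_radius: float
    length: float
    breadth: float
    sheep_id: int | str = ""

    def __post_init__(self) -> None:
        vals = (
            self.area, self.outline, self.convex,
            self.minimal_radius, self.maximal_radius,
            self.length, self.breadth,
        )
        if not all(v > 0 for v in vals):
            raise MeasurementError("all size measures must be positive")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding, border and exclusion rules.

    ``threshold=None`` means Otsu on the luminance; a float in [0, 1] fixes
    it.  ``min_area_um2`` is the debris floor; ``max_area_um2`` and
    ``min_solidity`` exclude fused (overlapping) components.  Defaults suit
    ovine cells of roughly 10-30 um^2.
    """

    threshold: float | None = None
    min_area_um2: float = 6.0
    max_area_um2: float = 32.0
    min_solidity: float = 0.95
    max_concavity_um: float = 0.2
    smooth_sigma: float = 2.0  # contour-coordinate Gaussian, in vertices

    def __post_init__(self) -> None:
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("fixed threshold must lie in [0, 1]")


def _luminance(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
    elif img.ndim != 2:
        raise ValueError("expected a grayscale or RGB image")
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def _smooth_closed(verts: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return verts
    return np.column_stack(
        [
            ndimage.gaussian_filter1d(verts[:, 0], sigma, mode="wrap"),
            ndimage.gaussian_filter1d(verts[:, 1], sigma, mode="wrap"),
        ]
    )


def segment_cells(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    image_id: str = "",
) -> list[CellContour]:
    """Extract one boundary contour per interior connected component.

    Components touching the image border are dropped (they cannot be fully
    measured).  An image with no foreground yields an empty list.
    """
    config = config or SegmentationConfig()
    img = _luminance(image)
    thr = config.threshold if config.threshold is not None else threshold_otsu(img)
    mask = img < thr  # stained cells are darker than the background
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    mask = clear_border(mask)
    labels, n = ndimage.label(mask)
    contours: list[CellContour] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        # pad so find_contours closes the ring even at the mask edge
        padded = np.pad(comp, 1).astype(float)
        rings = skmeasure.find_contours(padded, 0.5)
        if not rings:
            continue
        ring = max(rings, key=len) - 1.0  # undo padding offset
        if len(ring) < 8:
            continue
        verts = ring[:-1] if np.allclose(ring[0], ring[-1]) else ring
        verts = _smooth_closed(verts, config.smooth_sigma)
        xy = np.column_stack([verts[:, 1], verts[:, 0]])  # (row,col) -> (x,y)
        try:
            contours.append(
                CellContour(cell_id=len(contours), vertices=xy, image_id=image_id)
            )
        except ValueError:
            continue  # self-intersecting sliver after smoothing
    return contours


def filter_nonoverlapping(
    contours: list[CellContour],
    calibration: float,
    config: SegmentationConfig | None = None,
) -> list[CellContour]:
    """Keep only clean single cells.

    Removes components below the debris-area floor, above the single-cell
    area ceiling, with solidity below the fused-component threshold, or
    with a concavity (maximum distance from the boundary to its convex
    hull) deeper than ``max_concavity_um`` — a single cell is convex up to
    discretization, while fused cells always carry a concave neck.
    """
    config = config or SegmentationConfig()
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    kept = []
    for c in contours:
        poly = c.polygon()
        area_um2 = poly.area * calibration**2
        if area_um2 < config.min_area_um2 or area_um2 > config.max_area_um2:
            continue
        hull = poly.convex_hull
        if hull.area <= 0 or poly.area / hull.area < config.min_solidity:
            continue
        concavity = poly.exterior.hausdorff_distance(hull.exterior)
        if concavity * calibration > config.max_concavity_um:
            continue
        kept.append(c)
    return kept


def _feret(hull_pts: np.ndarray) -> tuple[float, float]:
    """Maximum Feret diameter and the caliper width perpendicular to it,
    from convex-hull vertices (pixel units)."""
    d = hull_pts[:, None, :] - hull_pts[None, :, :]
    dist2 = (d**2).sum(-1)
    i, j = np.unravel_index(np.argmax(dist2), dist2.shape)
    length = float(np.sqrt(dist2[i, j]))
    axis = (hull_pts[j] - hull_pts[i]) / length
    perp = np.array([-axis[1], axis[0]])
    proj = hull_pts @ perp
    breadth = float(proj.max() - proj.min())
    return length, breadth


def measure_cell(
    contour: CellContour,
    calibration: float,
    sheep_id: int | str = "",
) -> CellMeasurement:
    """Measure the seven size parameters of one cell in um / um^2."""
    if calibration <= 0:
        raise ValueError("calibration must be positive (um per pixel)")
    poly = contour.polygon()
    if poly.area <= 0:
        raise MeasurementError("degenerate zero-area contour")
    hull = poly.convex_hull
    hull_pts = np.asarray(hull.exterior.coords)[:-1]
    length_px, breadth_px = _feret(hull_pts)
    centroid = np.array([poly.centroid.x, poly.centroid.y])
    radii = np.hypot(*(contour.vertices - centroid).T)
    return CellMeasurement(
        cell_id=contour.cell_id,
        sheep_id=sheep_id,
        area=poly.area * calibration**2,
        outline=poly.length * calibration,
        convex=hull.area * calibration**2,
        minimal_radius=float(radii.min()) * calibration,
        maximal_radius=float(radii.max()) * calibration,
        length=length_px * calibration,
        breadth=breadth_px * calibration,
    )


def measure_image(
    image: np.ndarray,
    calibration: float,
    config: SegmentationConfig | None = None,
    sheep_id: int | str = "",
    image_id: str = "",
) -> pd.DataFrame:
    """Segment, filter and measure every clean cell of one image.

    Returns a table in :data:`MEASUREMENT_COLUMNS` order.
    """
    contours = segment_cells(image, config, image_id=image_id)
    contours = filter_nonoverlapping(contours, calibration, config)
    rows = []
    for c in contours:
        m = measure_cell(c, calibration, sheep_id=sheep_id)
        rows.append(
            {
                "cell_id": m.cell_id,
                "sheep_id": m.sheep_id,
                "area": m.area,
                "outline": m.outline,
                "convex": m.convex,
                "min_radius": m.minimal_radius,
                "max_radius": m.maximal_radius,
                "length": m.length,
                "breadth": m.breadth,
            }
        )
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
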