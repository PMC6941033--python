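"""Synthetic smear images and morphometric tables with known ground truth.

Real ovine smears are not redistributable, so every downstream stage is
exercised against synthetic data whose truth is known exactly:

* :func:`generate_smear_image` draws darker elliptical cells (optionally
  with a brighter central pallor, mimicking discocytes) on a lighter noisy
  background, plus small irregular debris blobs, and returns exact per-cell
  geometry including overlap flags computed by polygon intersection.
* :func:`generate_feature_table` samples per-cell morphometric rows from a
  three-component mixture whose outline/roundness/elongation parameters
  default to the published ovine subpopulation structure (ES1/ES3/ES2), and
  derives the remaining eight variables from those three latents through
  the same formula identities the measurement stages use, so one size block
  and two shape blocks emerge in a factor analysis.
* :func:`generate_sheep_panel` attaches cells to sheep whose haematological
  indices straddle every grouping cut-off by construction.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from . import published

__all__ = [
    "ImageGroundTruth",
    "ImageSpec",
    "MixtureComponent",
    "MixtureSpec",
    "PlacementError",
    "generate_smear_image",
    "generate_feature_table",
    "generate_sheep_panel",
    "ellipse_polygon",
]

#: Fixed order of the 11 morphometric variables used everywhere downstream.
FEATURE_COLUMNS = (
    "outline",
    "convex",
    "area",
    "length",
    "breadth",
    "roundness",
    "form_factor",
    "contour_index",
    "elongation",
    "ellipticity",
    "solidity",
)


class PlacementError(RuntimeError):
    """Raised when the requested cell density cannot be placed."""


@dataclass(frozen=True)
class ImageGroundTruth:
    """Exact geometry of one drawn object (cell or debris blob)."""

    cell_id: int
    center: tuple[float, float]  # (x, y) in um
    semi_major: float  # um
    semi_minor: float  # um
    orientation: float  # radians
    overlaps_other: bool
    is_debris: bool

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic smear field.

    Defaults give a 1024 px square field at 0.05 um/px (51.2 um across) with
    ~20 ovine-sized cells (radii 2.0-2.9 um, i.e. ~40-58 px) so that
    discretization error on any single cell stays small.
    """

    width_px: int = 1024
    height_px: int = 1024
    calibration: float = 0.05  # um per pixel
    n_cells: int = 20
    overlap_fraction: float = 0.0  # fraction of cells placed overlapping
    n_debris: int = 0
    radius_um: tuple[float, float] = (2.0, 2.9)  # semi-minor axis range
    axis_ratio: tuple[float, float] = (1.0, 1.25)
    background_level: int = 220
    cell_level: int = 100
    pallor: bool = True
    pallor_level: int = 150
    pallor_fraction: float = 0.5
    noise_sigma: float = 0.05  # fraction of the 0-255 dynamic range
    margin_um: float = 0.5  # clearance between disjoint cells and the border
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive (um per pixel)")
        if self.n_cells < 0:
            raise ValueError("cell count must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def ellipse_polygon(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    orientation: float,
    n_vertices: int = 128,
) -> Polygon:
    """Polygonal outline of an ellipse in um coordinates."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = semi_major * np.cos(t)
    y = semi_minor * np.sin(t)
    c, s = math.cos(orientation), math.sin(orientation)
    xr = center[0] + c * x - s * y
    yr = center[1] + s * x + c * y
    return Polygon(np.column_stack([xr, yr]))


def _place_cells(
    spec: ImageSpec, rng: np.random.Generator
) -> list[tuple[float, float, float, float, float]]:
    """Rejection-sample (cx, cy, a, b, theta) in um; first the disjoint
    cells, then overlapping ones attached to an existing cell."""
    w_um = spec.width_px * spec.calibration
    h_um = spec.height_px * spec.calibration
    n_overlap = int(round(spec.overlap_fraction * spec.n_cells))
    n_disjoint = spec.n_cells - n_overlap
    placed: list[tuple[float, float, float, float, float]] = []

    def draw_axes() -> tuple[float, float, float]:
        b = rng.uniform(*spec.radius_um)
        a = b * rng.uniform(*spec.axis_ratio)
        theta = rng.uniform(0.0, np.pi)
        return a, b, theta

    for _ in range(n_disjoint):
        for _attempt in range(spec.max_attempts):
            a, b, theta = draw_axes()
            lo = a + spec.margin_um
            if 2 * lo >= min(w_um, h_um):
                continue
            cx = rng.uniform(lo, w_um - lo)
            cy = rng.uniform(lo, h_um - lo)
            ok = all(
                math.hypot(cx - px, cy - py) > a + pa + spec.margin_um
                for px, py, pa, _pb, _pt in placed
            )
            if ok:
                placed.append((cx, cy, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_cells} cells at this density"
            )
    for _ in range(n_overlap):
        if not placed:
            raise PlacementError("overlap requested but no host cell placed")
        for _attempt in range(spec.max_attempts):
            host = placed[rng.integers(len(placed))]
            a, b, theta = draw_axes()
            phi = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.55, 0.85) * (host[2] + a)
            cx = host[0] + dist * math.cos(phi)
            cy = host[1] + dist * math.sin(phi)
            if a < cx < w_um - a and a < cy < h_um - a:
                placed.append((cx, cy, a, b, theta))
                break
        else:
            raise PlacementError("could not attach an overlapping cell")
    return placed


def _debris_blob(
    spec: ImageSpec,
    rng: np.random.Generator,
    occupied: list[Polygon],
) -> tuple[tuple[float, float], np.ndarray]:
    """A small irregular star-shaped blob well below half the minimum cell
    area, placed on free background (debris is extracellular junk), and
    returned as (center um, vertices um)."""
    w_um = spec.width_px * spec.calibration
    h_um = spec.height_px * spec.calibration
    for _attempt in range(spec.max_attempts):
        r0 = rng.uniform(0.25, 0.55)  # um; area << half of pi*r_min^2
        cx = rng.uniform(2 * r0, w_um - 2 * r0)
        cy = rng.uniform(2 * r0, h_um - 2 * r0)
        t = np.sort(rng.uniform(0.0, 2.0 * np.pi, 9))
        r = r0 * rng.uniform(0.5, 1.3, t.size)
        verts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
        poly = Polygon(verts)
        if not any(poly.intersects(o) for o in occupied):
            occupied.append(poly)
            return (cx, cy), verts
    raise PlacementError("could not place debris on free background")


def generate_smear_image(
    spec: ImageSpec, seed: int
) -> tuple[np.ndarray, list[ImageGroundTruth]]:
    """Render one synthetic smear field.

    Returns an 8-bit grayscale image (height x width) and the exact ground
    truth for every drawn object.  Overlap flags are computed by exact
    polygon intersection of the drawn outlines (debris included).
    """
    rng = np.random.default_rng(seed)
    img = np.full((spec.height_px, spec.width_px), float(spec.background_level))
    cal = spec.calibration

    cells = _place_cells(spec, rng)
    cell_polys = [
        ellipse_polygon((cx, cy), a, b, th) for cx, cy, a, b, th in cells
    ]
    occupied = list(cell_polys)
    debris = [
        _debris_blob(spec, rng, occupied) for _ in range(spec.n_debris)
    ]

    polys: list[Polygon] = cell_polys + [Polygon(v) for _c, v in debris]
    n_obj = len(polys)
    overlaps = [False] * n_obj
    for i in range(n_obj):
        for j in range(i + 1, n_obj):
            if polys[i].intersects(polys[j]):
                overlaps[i] = overlaps[j] = True

    for cx, cy, a, b, th in cells:
        # skimage uses (row, col) = (y, x) and rotation about the row axis
        rr, cc = draw_ellipse(
            cy / cal, cx / cal, b / cal, a / cal,
            shape=img.shape, rotation=-th,
        )
        img[rr, cc] = spec.cell_level
        if spec.pallor:
            rr, cc = draw_ellipse(
                cy / cal, cx / cal,
                spec.pallor_fraction * b / cal,
                spec.pallor_fraction * a / cal,
                shape=img.shape, rotation=-th,
            )
            img[rr, cc] = spec.pallor_level
    for _center, verts in debris:
        rr, cc = draw_polygon(verts[:, 1] / cal, verts[:, 0] / cal, img.shape)
        img[rr, cc] = spec.cell_level

    img += rng.normal(0.0, spec.noise_sigma * 255.0, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = [
        ImageGroundTruth(
            cell_id=i,
            center=(cells[i][0], cells[i][1]),
            semi_major=cells[i][2],
            semi_minor=cells[i][3],
            orientation=cells[i][4],
            overlaps_other=overlaps[i],
            is_debris=False,
        )
        for i in range(len(cells))
    ]
    for k, (center, verts) in enumerate(debris):
        i = len(cells) + k
        radii = np.hypot(verts[:, 0] - center[0], verts[:, 1] - center[1])
        truth.append(
            ImageGroundTruth(
                cell_id=i,
                center=center,
                semi_major=float(radii.max()),
                semi_minor=float(radii.min()),
                orientation=0.0,
                overlaps_other=overlaps[i],
                is_debris=True,
            )
        )
    return img, truth


def ground_truth_frame(truth: list[ImageGroundTruth]) -> pd.DataFrame:
    """Ground truth as a flat table (one row per drawn object)."""
    return pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truth],
            "center_x_um": [t.center[0] for t in truth],
            "center_y_um": [t.center[1] for t in truth],
            "semi_major_um": [t.semi_major for t in truth],
            "semi_minor_um": [t.semi_minor for t in truth],
            "orientation_rad": [t.orientation for t in truth],
            "overlaps_other": [t.overlaps_other for t in truth],
            "is_debris": [t.is_debris for t in truth],
        }
    )


@dataclass(frozen=True)
class MixtureComponent:
    """One subpopulation: Gaussian latents for outline (um), roundness and
    elongation; the remaining eight variables are derived."""

    proportion: float
    outline_mean: float
    outline_sd: float
    roundness_mean: float
    roundness_sd: float
    elongation_mean: float
    elongation_sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("proportion must lie in (0, 1)")
        for sd in (self.outline_sd, self.roundness_sd, self.elongation_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")


def _default_components() -> tuple[MixtureComponent, ...]:
    return tuple(
        MixtureComponent(
            proportion=c["proportion"],
            outline_mean=c["outline"][0],
            outline_sd=c["outline"][1],
            roundness_mean=c["roundness"][0],
            roundness_sd=c["roundness"][1],
            elongation_mean=c["elongation"][0],
            elongation_sd=c["elongation"][1],
        )
        for c in published.SUBPOPULATION_COMPONENTS
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture of subpopulations plus the deterministic relations mapping
    the three latent variables to the other eight morphometric columns.

    Cells are modelled as mildly irregular ellipses.  Three latents drive
    each cell: outline o (size, mixture component), elongation e (mixture
    component) and a boundary-irregularity factor q.  For an exact ellipse
    roundness equals breadth/length, so realized roundness is

        roundness = q * (1 - e) / (1 + e)

    with per-component q parameters derived so the realized roundness mean
    and SD match the component's configured values.  The remaining columns
    follow from the defining formula identities, which therefore hold
    exactly on every generated row:

        form_factor   = linear response to q + noise   (boundary roughness)
        area          = form_factor * outline^2 / (4 pi)
        contour_index = sqrt(4 pi / form_factor)
        solidity      = linear response to q + noise   (clipped below 1)
        convex        = area / solidity (plus independent hull jitter)
        length        = sqrt(4 area / (pi roundness))
        ellipticity   = (1 + e) / (1 - e)
        breadth       = length / ellipticity

    The response coefficients are configuration, with defaults chosen so
    the correlation structure splits into one size factor and two shape
    factors with exactly three eigenvalues above 1 and the factor anchors
    at outline, roundness and elongation.
    """

    components: tuple[MixtureComponent, ...] = field(
        default_factory=_default_components
    )
    ff_mean: float = 0.882
    ff_sd: float = 0.035
    ff_irregularity_corr: float = 0.95
    solidity_mean: float = 0.985
    solidity_sd: float = 0.008
    solidity_irregularity_corr: float = 0.7
    convex_jitter_rel: float = 0.005  # independent hull-area measurement noise
    area_jitter_rel: float = 0.0  # independent area measurement noise

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component required")
        total = sum(c.proportion for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c.proportion for c in self.components])

    def min_outline_separation_sd(self) -> float:
        """Smallest gap between adjacent component outline means, in units
        of the larger of the two component SDs."""
        comps = sorted(self.components, key=lambda c: c.outline_mean)
        gaps = [
            (b.outline_mean - a.outline_mean) / max(a.outline_sd, b.outline_sd)
            for a, b in zip(comps, comps[1:])
        ]
        return min(gaps)

    def with_planted_cluster(
        self,
        proportion: float = 0.015,
        outline_mean: float = 23.5,
        outline_sd: float = 0.4,
    ) -> "MixtureSpec":
        """Add a tiny extra component (for exercising the merge step)."""
        scale = 1.0 - proportion
        comps = tuple(
            replace(c, proportion=c.proportion * scale) for c in self.components
        ) + (
            MixtureComponent(
                proportion=proportion,
                outline_mean=outline_mean,
                outline_sd=outline_sd,
                roundness_mean=0.82,
                roundness_sd=0.058,
                elongation_mean=0.058,
                elongation_sd=0.027,
            ),
        )
        return replace(self, components=comps)


def generate_feature_table(
    mix: MixtureSpec, n_cells: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a per-cell 11-variable morphometric table from the mixture.

    Returns the feature table (``cell_id`` plus :data:`FEATURE_COLUMNS`) and
    the true component label (0-based index into ``mix.components``) of each
    row.  Latents are clipped to physically admissible ranges (roundness,
    form factor and solidity <= 1; elongation >= 0), so every row satisfies
    the measurement invariants.
    """
    if n_cells < len(mix.components):
        raise ValueError("need at least one cell per mixture component")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(mix.components), size=n_cells, p=mix.proportions)

    o_mean = np.array([c.outline_mean for c in mix.components])[labels]
    o_sd = np.array([c.outline_sd for c in mix.components])[labels]
    r_mean = np.array([c.roundness_mean for c in mix.components])[labels]
    r_sd = np.array([c.roundness_sd for c in mix.components])[labels]
    e_mean = np.array([c.elongation_mean for c in mix.components])[labels]
    e_sd = np.array([c.elongation_sd for c in mix.components])[labels]

    outline = rng.normal(o_mean, o_sd)
    elongation = np.clip(np.abs(rng.normal(e_mean, e_sd)), 0.0, 0.40)

    # irregularity latent q: roundness = q * (1 - e)/(1 + e); choose q's
    # per-component mean/SD so realized roundness matches the component's
    # configured mean/SD (first-order delta method in e)
    ellipse_round = (1.0 - e_mean) / (1.0 + e_mean)
    q_mean = r_mean / ellipse_round
    e_part_sd = q_mean * 2.0 / (1.0 + e_mean) ** 2 * e_sd
    q_var = np.maximum(r_sd**2 - e_part_sd**2, (0.25 * r_sd) ** 2)
    q_sd = np.sqrt(q_var) / ellipse_round
    q = rng.normal(q_mean, q_sd)
    roundness = np.clip(q * (1.0 - elongation) / (1.0 + elongation),
                        0.40, 0.9995)

    q_sd_ref = float(np.mean(q_sd))
    q_ref = float(np.mean(q_mean))
    ff_slope = mix.ff_irregularity_corr * mix.ff_sd / q_sd_ref
    ff_noise = mix.ff_sd * math.sqrt(1.0 - mix.ff_irregularity_corr**2)
    form_factor = np.clip(
        mix.ff_mean
        + ff_slope * (q - q_ref)
        + rng.normal(0.0, ff_noise, n_cells),
        0.40,
        0.9995,
    )
    sol_slope = mix.solidity_irregularity_corr * mix.solidity_sd / q_sd_ref
    sol_noise = mix.solidity_sd * math.sqrt(
        1.0 - mix.solidity_irregularity_corr**2
    )
    solidity = np.clip(
        mix.solidity_mean
        + sol_slope * (q - q_ref)
        + rng.normal(0.0, sol_noise, n_cells),
        0.85,
        0.9995,
    )

    area = form_factor * outline**2 / (4.0 * np.pi)
    if mix.area_jitter_rel > 0:
        # independent planimetry error; realized form factor follows so the
        # identity form_factor = 4 pi area / outline^2 stays exact per row
        area *= np.exp(rng.normal(0.0, mix.area_jitter_rel, n_cells))
        form_factor = np.clip(4.0 * np.pi * area / outline**2, 0.40, 0.9995)
        area = form_factor * outline**2 / (4.0 * np.pi)
    contour_index = np.sqrt(4.0 * np.pi / form_factor)
    # the hull-area measurement carries its own small independent error;
    # solidity is recomputed from the jittered hull so the defining
    # identity solidity = area / convex stays exact per row
    convex = area / solidity
    if mix.convex_jitter_rel > 0:
        convex *= np.exp(rng.normal(0.0, mix.convex_jitter_rel, n_cells))
        np.minimum(convex, area / 0.85, out=convex)
        np.maximum(convex, area / 0.9995, out=convex)
        solidity = area / convex
    length = np.sqrt(4.0 * area / (np.pi * roundness))
    ellipticity = (1.0 + elongation) / (1.0 - elongation)
    breadth = length / ellipticity

    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "outline": outline,
            "convex": convex,
            "area": area,
            "length": length,
            "breadth": breadth,
            "roundness": roundness,
            "form_factor": form_factor,
            "contour_index": contour_index,
            "elongation": elongation,
            "ellipticity": ellipticity,
            "solidity": solidity,
        }
    )
    return table, labels


#: Per-parameter (low-side range, high-side range) around each grouping
#: cut-off, used to synthesize sheep haematology on both sides of every
#: cut-off; spans sit inside or near the published reference intervals.
PANEL_RANGES = {
    "HGB": ((78.0, 90.0), (90.5, 112.0)),
    "HCT": ((0.24, 0.27), (0.272, 0.31)),
    "MCV": ((28.0, 30.0), (30.1, 33.0)),
    "MCH": ((8.5, 10.0), (10.1, 11.5)),
    "MCHC": ((315.0, 339.9), (340.0, 365.0)),
    "RDW": ((18.0, 22.0), (22.1, 24.0)),
}


def generate_sheep_panel(
    n_sheep: int,
    cells_per_sheep: int,
    seed: int,
    mix: MixtureSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Synthesize a sheep panel with cells attached to each sheep.

    Sheep alternate between a low-side and a high-side haematological
    profile, so for every grouping cut-off both groups are non-empty
    whenever ``n_sheep >= 2``.  Cells are drawn i.i.d. from ``mix`` (default:
    the published three-subpopulation structure).

    Returns ``(sheep_records, feature_table, true_component_labels)``; the
    feature table carries ``sheep_id`` in addition to the 11 variables.
    """
    if n_sheep < 2:
        raise ValueError("need at least two sheep")
    if mix is None:
        mix = MixtureSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sheep):
        side = i % 2
        rec = {"sheep_id": i + 1}
        for param, ranges in PANEL_RANGES.items():
            lo, hi = ranges[side]
            rec[param] = float(rng.uniform(lo, hi))
        rec["age"] = float(rng.uniform(2.0, 5.0))
        rows.append(rec)
    sheep = pd.DataFrame(rows)

    cells, labels = generate_feature_table(
        mix, n_sheep * cells_per_sheep, seed=int(rng.integers(2**31))
    )
    cells.insert(1, "sheep_id", np.repeat(sheep["sheep_id"].to_numpy(),
                                          cells_per_sheep))
    return sheep, cells, labels
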