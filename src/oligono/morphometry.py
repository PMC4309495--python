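"""Oligodendrocyte territory morphometry.

An oligodendrocyte's degree of arborization is scored by the diameter of the
circle enclosing the area its processes occupy. Here that is made
reproducible: cells are segmented from a marker channel by thresholding and
8-connected component labeling, each cell's territory is the minimal
enclosing circle of its pixel centers, and cells are classified as compact
or arborized at a diameter cutoff (70 um by convention). Fields are sampled
on a coverslip in the five-field pattern: one central field plus four fields
two field-widths out along two perpendicular axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import (
    GeometryError,
    InvalidParameterError,
    UndefinedSummaryError,
)

__all__ = [
    "FieldImage",
    "Territory",
    "MorphometrySummary",
    "select_fields",
    "segment_cells",
    "min_enclosing_circle",
    "measure_territories",
    "classify_and_summarize",
]


@dataclass
class FieldImage:
    """One imaged field: a single marker channel with pixel calibration.

    ``field_origin`` locates the field's (x, y) corner on the coverslip in um;
    pixel (row, col) maps to physical (x, y) = origin + (col, row)*pixel_size.
    """

    intensities: np.ndarray
    pixel_size: float  # um / pixel
    field_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise InvalidParameterError("field image must be 2-D")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("intensities must be non-negative")
        if not self.pixel_size > 0:
            raise InvalidParameterError("pixel_size must be > 0")


@dataclass(frozen=True)
class Territory:
    """One cell's enclosing-circle measurement (center and diameter in um)."""

    cell_id: int
    pixel_count: int
    circle_center: tuple[float, float]
    circle_diameter: float
    touches_border: bool = False


@dataclass(frozen=True)
class MorphometrySummary:
    """Field- or coverslip-level aggregation against the diameter cutoff."""

    n_cells: int
    cutoff: float  # um
    pct_above_cutoff: float
    mean_diameter_above_cutoff: float | None
    per_field_counts: list


def select_fields(coverslip_diameter: float, field_side: float) -> list[tuple[float, float]]:
    """Centers of the five sampling fields on a circular coverslip.

    Units are whatever the caller uses consistently (mm in practice). The
    first field sits at the coverslip center; the other four are two
    field-widths away along two perpendicular axes. Raises
    :class:`GeometryError` if any field corner falls outside the coverslip.
    """
    if not field_side > 0 or not coverslip_diameter > 0:
        raise InvalidParameterError("diameter and field side must be > 0")
    s = field_side
    centers = [(0.0, 0.0), (2 * s, 0.0), (-2 * s, 0.0), (0.0, 2 * s), (0.0, -2 * s)]
    r = coverslip_diameter / 2.0
    for cx, cy in centers:
        corner = math.hypot(abs(cx) + s / 2.0, abs(cy) + s / 2.0)
        if corner > r + 1e-12:
            raise GeometryError(
                f"field at ({cx}, {cy}) extends beyond the coverslip "
                f"(corner radius {corner:.3f} > {r:.3f})"
            )
    return centers


def segment_cells(
    field: FieldImage, threshold: float, min_pixels: int = 20
) -> list[np.ndarray]:
    """Connected components of the above-threshold mask.

    8-connectivity is used so that diagonally-running thin processes stay
    attached to their cell; components smaller than ``min_pixels`` are
    discarded as debris. Returns one (n, 2) array of (row, col) pixel indices
    per cell, ordered by each component's first pixel in row-major order.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    if min_pixels < 1:
        raise InvalidParameterError("min_pixels must be >= 1")
    mask = field.intensities > threshold
    labels = measure.label(mask, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        if region.num_pixels >= min_pixels:
            comps.append(region.coords)
    comps.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
    return comps


# ---------------------------------------------------------------------------
# Minimal enclosing circle (Welzl's incremental algorithm)


def _circle_two(p, q):
    cx, cy = (p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return (cx, cy), r


def _circumcircle(a, b, c):
    """Circumcircle of a triangle, or None when (nearly) collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax - cx), abs(ay - cy), abs(bx - cx), abs(by - cy), 1.0)
    if abs(d) < 1e-12 * scale * scale:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return (ux, uy), r


def _contains(center, r, p, eps):
    return math.hypot(p[0] - center[0], p[1] - center[1]) <= r + eps


def _circle_three(a, b, c):
    """Smallest circle through/around three points (handles obtuse and
    collinear cases by falling back to the widest two-point circle)."""
    best = None
    for p, q in ((a, b), (a, c), (b, c)):
        center, r = _circle_two(p, q)
        third = [x for x in (a, b, c) if x is not p and x is not q][0]
        if _contains(center, r, third, 1e-9):
            if best is None or r < best[1]:
                best = (center, r)
    if best is not None:
        return best
    cc = _circumcircle(a, b, c)
    if cc is None:  # collinear beyond tolerance: widest pair covers all
        pairs = [(_circle_two(p, q), (p, q)) for p, q in ((a, b), (a, c), (b, c))]
        return max(pairs, key=lambda t: t[0][1])[0]
    return cc


def min_enclosing_circle(points) -> tuple[tuple[float, float], float]:
    """Smallest circle containing every point; returns (center, diameter).

    Welzl's randomized incremental algorithm, expected O(n); the shuffle is
    seeded from the input size so identical inputs give identical output.
    Every input point lies inside or on the returned circle within 1e-9
    (same length unit as the input).
    """
    arr = np.asarray(points, dtype=float).reshape(-1, 2)
    if arr.size == 0:
        raise InvalidParameterError("min_enclosing_circle needs at least one point")
    if len(arr) > 50:  # only hull vertices can lie on the circle
        try:
            from scipy.spatial import ConvexHull, QhullError

            arr = arr[ConvexHull(arr).vertices]
        except QhullError:
            pass  # collinear/degenerate input: run Welzl on everything
    pts = [(float(p[0]), float(p[1])) for p in arr]
    rng = np.random.default_rng(len(pts))
    order = rng.permutation(len(pts))
    pts = [pts[i] for i in order]
    eps = 1e-10

    center, r = pts[0], 0.0
    for i in range(1, len(pts)):
        p = pts[i]
        if _contains(center, r, p, eps):
            continue
        # p is on the boundary of the circle of pts[:i+1]
        center, r = p, 0.0
        for j in range(i):
            q = pts[j]
            if _contains(center, r, q, eps):
                continue
            center, r = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if _contains(center, r, s, eps):
                    continue
                center, r = _circle_three(p, q, s)
    return (center, 2.0 * r)


def measure_territories(
    field: FieldImage, threshold: float, min_pixels: int = 20
) -> list[Territory]:
    """Segment a field and measure each cell's minimal enclosing circle.

    Pixel indices are mapped to physical um via the field's pixel size and
    origin; cells whose pixels touch the image border are flagged (their
    territory is truncated by the field of view).
    """
    comps = segment_cells(field, threshold, min_pixels)
    h, w = field.intensities.shape
    ox, oy = field.field_origin
    out = []
    for cid, coords in enumerate(comps):
        rows, cols = coords[:, 0], coords[:, 1]
        touches = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        xy = np.column_stack([ox + cols * field.pixel_size, oy + rows * field.pixel_size])
        center, diam = min_enclosing_circle(xy)
        out.append(
            Territory(
                cell_id=cid,
                pixel_count=int(len(coords)),
                circle_center=(float(center[0]), float(center[1])),
                circle_diameter=float(diam),
                touches_border=touches,
            )
        )
    return out


def classify_and_summarize(
    territories,
    cutoff: float = 70.0,
    include_border: bool = False,
    per_field_counts: list | None = None,
) -> MorphometrySummary:
    """Split territories at the diameter cutoff and aggregate.

    "Above" is strict: a cell whose diameter equals the cutoff counts as not
    above. Border-touching cells are excluded unless ``include_border`` is
    set. Raises :class:`UndefinedSummaryError` when no cell remains.
    """
    if not cutoff > 0:
        raise InvalidParameterError("cutoff must be > 0")
    kept = [t for t in territories if include_border or not t.touches_border]
    if not kept:
        raise UndefinedSummaryError("no territories to summarize")
    diams = np.array([t.circle_diameter for t in kept])
    above = diams[diams > cutoff]
    return MorphometrySummary(
        n_cells=len(kept),
        cutoff=float(cutoff),
        pct_above_cutoff=float(100.0 * len(above) / len(kept)),
        mean_diameter_above_cutoff=float(above.mean()) if len(above) else None,
        per_field_counts=per_field_counts if per_field_counts is not None else [len(kept)],
    )
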