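"""Synthetic microscopy data with exact ground truth.

Two generators provide the inputs the analysis stages assume, so every
imaging operation can be validated without any real acquisition:

* :func:`generate_coloc_stack` builds a two-channel z-stack in which a
  controlled fraction rho of channel-A intensity lies over B-positive pixels.
  The overlap is arranged by construction (colocalized A objects are placed
  inside B objects, the rest well away from any B signal), and the realized
  intensity-weighted fraction is recomputed from the noiseless scene and
  recorded exactly in the ground truth before any blur or noise is applied.

* :func:`generate_arbor_field` builds a 2-D field of branched cells: each
  cell is a soma disk plus radial processes whose tips lie on a circle of the
  cell's sampled territory diameter, so the minimal enclosing circle of its
  pixels recovers that diameter to within ~2 pixels. Diameters are drawn from
  a compact/arborized mixture around the 70 um convention.

Both generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line

from .colocalization import ImageStack
from .errors import GenerationError, InvalidParameterError
from .morphometry import FieldImage

__all__ = [
    "ColocSceneSpec",
    "ArborFieldSpec",
    "GroundTruth",
    "generate_coloc_stack",
    "generate_arbor_field",
]


@dataclass(frozen=True)
class ColocSceneSpec:
    """Recipe for a two-channel stack with a known colocalization fraction.

    ``overlap_fraction`` is the target intensity-weighted fraction rho of
    channel-A intensity over B-positive pixels. ``noise_sd`` is the noise
    standard deviation at full signal; noise scales with local intensity
    (photon shot noise), so a dark background stays dark. ``blur_sd`` is an
    in-plane Gaussian blur in pixels, applied after ground truth is recorded.
    """

    shape: tuple[int, int, int] = (8, 128, 128)  # (z, y, x); channels are fixed at 2
    n_objects: int = 12
    object_radius: float = 6.0  # px
    overlap_fraction: float = 0.5
    signal_level: float = 100.0
    noise_sd: float = 0.0
    blur_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise InvalidParameterError("overlap_fraction must lie in [0, 1]")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise InvalidParameterError("shape must be positive (z, y, x)")
        if self.n_objects < 1:
            raise InvalidParameterError("n_objects must be >= 1")
        if not self.object_radius > 0 or not self.signal_level > 0:
            raise InvalidParameterError("object_radius and signal_level must be > 0")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise InvalidParameterError("noise_sd and blur_sd must be >= 0")


@dataclass(frozen=True)
class ArborFieldSpec:
    """Recipe for a field of branched cells with a known diameter mixture.

    Defaults mimic a 1 mm^2 culture field. ``frac_large`` is the probability
    that a cell's territory diameter is drawn from ``large_diam_range``
    (strictly above 70 um) rather than ``small_diam_range`` (strictly below).
    Cells are placed so their territory circles neither overlap each other
    nor cross the field border.
    """

    field_side: float = 1000.0  # um
    pixel_size: float = 2.0  # um / px
    n_cells: int = 40
    frac_large: float = 0.28
    small_diam_range: tuple[float, float] = (25.0, 60.0)
    large_diam_range: tuple[float, float] = (75.0, 120.0)
    processes_per_cell: int = 6
    soma_radius: float = 6.0  # um
    signal_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_large <= 1.0:
            raise InvalidParameterError("frac_large must lie in [0, 1]")
        if not (0 < self.small_diam_range[0] <= self.small_diam_range[1] < 70.0):
            raise InvalidParameterError("small_diam_range must lie strictly below 70 um")
        if not (70.0 < self.large_diam_range[0] <= self.large_diam_range[1]):
            raise InvalidParameterError("large_diam_range must lie strictly above 70 um")
        if self.processes_per_cell < 2:
            raise InvalidParameterError("need at least 2 processes to span the territory")
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        if not self.field_side > 0 or not self.pixel_size > 0:
            raise InvalidParameterError("field_side and pixel_size must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, recorded before blur and noise.

    ``objects`` holds per-object records (positions; colocalization
    membership or true territory diameters). ``realized_overlap_fraction`` /
    ``realized_frac_large`` are recomputed from the noiseless scene, not
    copied from the request, so recovery tests compare against exact values.
    """

    objects: list = dc_field(default_factory=list)
    realized_overlap_fraction: float | None = None
    realized_frac_large: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "objects": self.objects,
            "realized_overlap_fraction": self.realized_overlap_fraction,
            "realized_frac_large": self.realized_frac_large,
            "seed": self.seed,
        }


def _place_disjoint(rng, n, radius, ny, nx, margin, max_tries=20000):
    """Random non-overlapping disk centers with a clearance margin."""
    centers: list[tuple[int, int]] = []
    lo_y, hi_y = radius + 1, ny - radius - 1
    lo_x, hi_x = radius + 1, nx - radius - 1
    if hi_y <= lo_y or hi_x <= lo_x:
        raise GenerationError("objects do not fit in the frame")
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} objects of radius {radius} in ({ny}, {nx})"
            )
        cy = int(rng.integers(lo_y, hi_y))
        cx = int(rng.integers(lo_x, hi_x))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * radius + margin) ** 2 for y, x in centers):
            centers.append((cy, cx))
    return centers


def _shot_noise(img, rng, noise_sd, signal_level):
    """Signal-proportional Gaussian noise: sd = noise_sd at full signal."""
    if noise_sd == 0:
        return img
    sd = noise_sd * (img / signal_level)
    return np.clip(img + rng.normal(0.0, 1.0, img.shape) * sd, 0.0, None)


def generate_coloc_stack(spec: ColocSceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Build a two-channel stack with a known intensity-weighted overlap.

    Channel A holds ``n_objects`` disks replicated through z (columnar
    structures); round(rho * n_objects) of them sit inside larger channel-B
    disks, the rest are kept clear of all B signal, and a few B-only disks
    are added so B is not just the colocalized set. Returns the stack (after
    blur and noise) and the exact ground truth of the noiseless scene.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    r = spec.object_radius
    b_extra_r = r + 2.0  # B disks enclose their A partner with margin
    n_in = int(round(spec.overlap_fraction * spec.n_objects))
    n_b_only = max(2, spec.n_objects // 4)

    # Clearance > 3*blur_sd keeps blurred A tails from crossing B boundaries.
    margin = 3.0 * spec.blur_sd + 4.0
    centers = _place_disjoint(rng, spec.n_objects + n_b_only, b_extra_r, ny, nx, margin)
    a_centers = centers[: spec.n_objects]
    b_only_centers = centers[spec.n_objects :]

    plane_a = np.zeros((ny, nx))
    plane_b = np.zeros((ny, nx))
    objects = []
    for i, (cy, cx) in enumerate(a_centers):
        coloc = i < n_in
        rr, cc = disk((cy, cx), r, shape=(ny, nx))
        plane_a[rr, cc] = spec.signal_level
        if coloc:
            rr, cc = disk((cy, cx), b_extra_r, shape=(ny, nx))
            plane_b[rr, cc] = spec.signal_level
        objects.append({"channel": "A", "center": (cy, cx), "colocalized": coloc})
    for cy, cx in b_only_centers:
        rr, cc = disk((cy, cx), r, shape=(ny, nx))
        plane_b[rr, cc] = spec.signal_level
        objects.append({"channel": "B", "center": (cy, cx), "colocalized": False})

    # Exact intensity bookkeeping on the noiseless, unblurred scene.
    total_a = plane_a.sum()
    realized = float(plane_a[plane_b > 0].sum() / total_a) if total_a > 0 else None
    truth = GroundTruth(
        objects=objects, realized_overlap_fraction=realized, seed=spec.seed
    )

    stack = np.stack(
        [np.broadcast_to(plane_a, (nz, ny, nx)).copy(),
         np.broadcast_to(plane_b, (nz, ny, nx)).copy()]
    )
    if spec.blur_sd > 0:
        for c in range(2):
            for z in range(nz):
                stack[c, z] = gaussian_filter(stack[c, z], spec.blur_sd, truncate=3.0)
    stack[0] = _shot_noise(stack[0], rng, spec.noise_sd, spec.signal_level)
    stack[1] = _shot_noise(stack[1], rng, spec.noise_sd, spec.signal_level)

    image = ImageStack(
        intensities=stack, channel_labels=["A", "B"], pixel_size=0.2, z_step=1.0
    )
    return image, truth


def _draw_cell(img, rng, cy_px, cx_px, diam_um, spec: ArborFieldSpec):
    """Rasterize one cell: soma disk plus radial processes to the territory rim."""
    ny, nx = img.shape
    px = spec.pixel_size
    r_px = (diam_um / 2.0) / px
    soma_px = max(spec.soma_radius / px, 1.5)
    rr, cc = disk((cy_px, cx_px), soma_px, shape=(ny, nx))
    img[rr, cc] = spec.signal_level
    k = spec.processes_per_cell
    phase = rng.uniform(0.0, 2.0 * math.pi)
    for j in range(k):
        ang = phase + 2.0 * math.pi * j / k
        ty = int(round(cy_px + r_px * math.sin(ang)))
        tx = int(round(cx_px + r_px * math.cos(ang)))
        ty = min(max(ty, 0), ny - 1)
        tx = min(max(tx, 0), nx - 1)
        rr, cc = line(int(round(cy_px)), int(round(cx_px)), ty, tx)
        img[rr, cc] = spec.signal_level


def generate_arbor_field(spec: ArborFieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Build one field of branched cells with known territory diameters.

    Territory circles are placed by rejection sampling without mutual overlap
    and wholly inside the field; an overcrowded request raises
    :class:`GenerationError`. Ground truth records each cell's sampled
    diameter and size class, plus the realized fraction of large cells.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.field_side / spec.pixel_size))
    img = np.zeros((n_px, n_px))

    is_large = rng.random(spec.n_cells) < spec.frac_large
    diams = np.where(
        is_large,
        rng.uniform(*spec.large_diam_range, spec.n_cells),
        rng.uniform(*spec.small_diam_range, spec.n_cells),
    )
    # place big territories first: rejection sampling packs better that way
    order = np.argsort(-diams)

    placed: list[tuple[float, float, float]] = []  # (x_um, y_um, radius_um)
    objects = []
    gap = 2.5 * spec.pixel_size  # keeps neighboring pixel sets 8-disconnected
    max_tries = 4000
    for idx in order:
        d = float(diams[idx])
        radius = d / 2.0
        lo, hi = radius + gap, spec.field_side - radius - gap
        if hi <= lo:
            raise GenerationError("territory larger than the field")
        for attempt in range(max_tries):
            x = rng.uniform(lo, hi)
            y = rng.uniform(lo, hi)
            if all(
                math.hypot(x - px0, y - py0) >= radius + pr + gap
                for px0, py0, pr in placed
            ):
                placed.append((x, y, radius))
                objects.append(
                    {
                        "cell": int(idx),
                        "center_um": (x, y),
                        "diameter_um": d,
                        "large": bool(is_large[idx]),
                    }
                )
                break
        else:
            raise GenerationError(
                f"field overcrowded: placed {len(placed)} of {spec.n_cells} cells"
            )

    for obj in objects:
        x, y = obj["center_um"]
        _draw_cell(
            img, rng, y / spec.pixel_size, x / spec.pixel_size, obj["diameter_um"], spec
        )

    realized = float(np.mean(is_large)) if spec.n_cells else None
    truth = GroundTruth(objects=objects, realized_frac_large=realized, seed=spec.seed)

    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)

    return FieldImage(intensities=img, pixel_size=spec.pixel_size), truth
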