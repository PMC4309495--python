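"""Two-channel colocalization scoring on confocal z-stacks.

Two procedures are provided, matching standard ImageJ practice:

* Manders' M1 coefficient computed on the average z-projection: the fraction
  of channel-A intensity that lies in pixels where channel B is above its
  threshold. 1.0 means all A intensity sits on B-positive pixels.
* AND-overlap counting: each channel is binarized at a fixed threshold, the
  binary images are combined with a logical AND per z-slice, and the
  coincident (true) pixels are counted.

Plus a small helper for marker-positive cell-fraction percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ChannelLookupError,
    InvalidParameterError,
    ShapeMismatchError,
    UndefinedSummaryError,
)

__all__ = [
    "ImageStack",
    "ColocResult",
    "average_projection",
    "manders_m1",
    "and_overlap_count",
    "positive_cell_fraction",
]


@dataclass
class ImageStack:
    """A multi-channel confocal z-stack with physical pixel calibration.

    ``intensities`` is indexed ``(channel, z, y, x)`` and must be
    non-negative; ``pixel_size`` is the isotropic in-plane pixel size in um
    and ``z_step`` the axial section spacing in um (ignored for single-plane
    stacks).
    """

    intensities: np.ndarray
    channel_labels: list[str]
    pixel_size: float  # um / pixel
    z_step: float = 1.0  # um

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise InvalidParameterError(
                f"intensities must be 4-D (channel, z, y, x), got {self.intensities.ndim}-D"
            )
        c, z = self.intensities.shape[:2]
        if c < 1 or z < 1:
            raise InvalidParameterError("need at least one channel and one z-plane")
        if len(self.channel_labels) != c:
            raise InvalidParameterError("one label per channel required")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("intensities must be non-negative")
        if not self.pixel_size > 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if z > 1 and not self.z_step > 0:
            raise InvalidParameterError("z_step must be > 0 for multi-plane stacks")

    def channel(self, label: str) -> np.ndarray:
        """The (z, y, x) sub-array for one named channel."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise ChannelLookupError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.intensities[i]


@dataclass(frozen=True)
class ColocResult:
    """Outcome of one colocalization measurement.

    ``m1`` is None when undefined (no A intensity); ``mode`` records whether
    the measurement was taken on the projection or per z-slice.
    """

    m1: float | None
    coincident_pixels: int
    above_threshold_a: int
    above_threshold_b: int
    thresholds: dict = field(default_factory=dict)
    mode: str = "per-slice"

    def __post_init__(self):
        if self.m1 is not None and not (0.0 <= self.m1 <= 1.0):
            raise InvalidParameterError(f"m1 must lie in [0, 1], got {self.m1}")
        if self.coincident_pixels > min(self.above_threshold_a, self.above_threshold_b):
            raise InvalidParameterError(
                "coincident pixels cannot exceed either channel's positive count"
            )


def average_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Per-pixel arithmetic mean over z for one channel; shape (y, x)."""
    return stack.channel(channel).mean(axis=0)


def manders_m1(img_a: np.ndarray, img_b: np.ndarray, threshold_b: float = 0.0) -> float | None:
    """Manders' M1: sum of A intensity over B-positive pixels / total A intensity.

    A pixel is B-positive when its B intensity is strictly greater than
    ``threshold_b``. Returns None when channel A carries no intensity (the
    coefficient is then undefined). Swap the arguments for M2.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if threshold_b < 0:
        raise InvalidParameterError("threshold_b must be >= 0")
    total = a.sum()
    if total == 0:
        return None
    # clamp: summation order can spill a hair past [0, 1] in floating point
    return float(min(max(a[b > threshold_b].sum() / total, 0.0), 1.0))


def and_overlap_count(
    stack: ImageStack,
    channel_a: str,
    channel_b: str,
    threshold_a: float,
    threshold_b: float,
    mode: str = "per-slice",
) -> ColocResult:
    """Binarize both channels, AND them, and count coincident pixels.

    With ``mode="per-slice"`` (the default) each z-slice is binarized and
    ANDed independently and the counts summed; ``mode="projection"`` applies
    the same procedure to the average projections instead. Thresholding is
    strictly-greater-than; the thresholds used are recorded in the result.
    """
    if threshold_a < 0 or threshold_b < 0:
        raise InvalidParameterError("thresholds must be >= 0")
    if mode == "per-slice":
        a, b = stack.channel(channel_a), stack.channel(channel_b)
    elif mode == "projection":
        a = average_projection(stack, channel_a)
        b = average_projection(stack, channel_b)
    else:
        raise InvalidParameterError(f"mode must be 'per-slice' or 'projection', got {mode!r}")
    pos_a = a > threshold_a
    pos_b = b > threshold_b
    return ColocResult(
        m1=None,
        coincident_pixels=int(np.count_nonzero(pos_a & pos_b)),
        above_threshold_a=int(np.count_nonzero(pos_a)),
        above_threshold_b=int(np.count_nonzero(pos_b)),
        thresholds={channel_a: threshold_a, channel_b: threshold_b},
        mode=mode,
    )


def positive_cell_fraction(total_cells: int, positive_cells: int) -> float:
    """Percentage of marker-positive cells among total counted cells."""
    if total_cells <= 0:
        raise UndefinedSummaryError("fraction undefined for zero total cells")
    if not 0 <= positive_cells <= total_cells:
        raise InvalidParameterError("need 0 <= positive_cells <= total_cells")
    return 100.0 * positive_cells / total_cells
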