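"""Image pre-processing chain of the detection subroutine.

The sensor works relatively, not absolutely: each frame's intensity
histogram yields an estimate of the floor (background) temperature, a fixed
temperature shift above that floor becomes the Background Color Threshold
(BCT), pixels strictly above the BCT are foreground, a morphological filter
suppresses small nuisance particles, and the surviving foreground is both
counted (Colored Pixels, CP) and measured as connected particles.  The
per-frame histogram step is what makes the sensor immune to the camera's
absolute-temperature error: a global offset moves floor and hen together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage import measure, morphology

from henmon.frame_io import BinaryMask, TemperatureCalibration, ThermalFrame

__all__ = [
    "IntensityHistogram",
    "BackgroundEstimate",
    "Particle",
    "BctLevel",
    "compute_histogram",
    "estimate_floor",
    "compute_bct",
    "binarize",
    "filter_small_particles",
    "count_colored_pixels",
    "label_particles",
]


@dataclass(frozen=True)
class IntensityHistogram:
    """Frequency distribution of the 256 grey levels of one frame."""

    counts: np.ndarray  # shape (256,), non-negative ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got {arr.shape}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BackgroundEstimate:
    """Estimated floor (background) temperature of the room for one frame."""

    floor_temperature: float
    floor_intensity: int
    method: str  # "mode" | "trimmed-mean"


class BctLevel(NamedTuple):
    """Background Color Threshold as a grey level, plus a saturation flag.

    A saturated BCT (clamped at 255) makes detection impossible for that
    frame; callers must warn rather than fail so a monitoring run survives
    a hot-floor frame.
    """

    level: int
    saturated: bool


@dataclass(frozen=True)
class Particle:
    """A connected foreground component with its shape measurements.

    ``ellipse_major``/``ellipse_minor`` are the axes of the ellipse with the
    same normalized second central moments as the component;
    ``rect_long``/``rect_short`` are the extents of the component projected
    onto its principal axes (an oriented bounding rectangle).  Orientation
    is the principal-axis angle in degrees, measured counter-clockwise from
    the column (horizontal) axis, in (-90, 90].
    """

    pixel_count: int
    centroid: tuple[float, float]
    ellipse_major: float
    ellipse_minor: float
    rect_long: float
    rect_short: float
    orientation: float


def compute_histogram(frame: ThermalFrame) -> IntensityHistogram:
    """Exact 256-bin grey-level histogram of a frame."""
    counts = np.bincount(frame.pixels.ravel(), minlength=256)
    return IntensityHistogram(counts=counts)


def estimate_floor(frame: ThermalFrame, method: str = "mode") -> BackgroundEstimate:
    """Estimate the mean floor temperature from the intensity histogram.

    The background dominates the frame, so its intensity distribution is
    approximately normal around the floor temperature.  ``method`` selects
    the statistic:

    - ``"mode"``: grey level with the highest count (ties resolved to the
      lowest level).  Robust when warm bodies occupy a large image fraction.
    - ``"trimmed-mean"``: mean grey level over the central 80% of the
      histogram mass (10% trimmed off each tail), rounded to the nearest
      level.

    Both coincide for the idealized normal background.
    """
    hist = compute_histogram(frame)
    counts = hist.counts
    if method == "mode":
        level = int(np.argmax(counts))
    elif method == "trimmed-mean":
        total = counts.sum()
        cum = np.cumsum(counts)
        lo_mass, hi_mass = 0.1 * total, 0.9 * total
        # per-level mass retained after trimming 10% off each tail
        kept = np.minimum(cum, hi_mass) - np.maximum(cum - counts, lo_mass)
        kept = np.maximum(kept, 0)
        level = int(round(float(np.dot(np.arange(256), kept) / kept.sum())))
    else:
        raise ValueError(f"unknown floor statistic {method!r}")
    return BackgroundEstimate(
        floor_temperature=frame.calibration.temperature_of(level),
        floor_intensity=level,
        method=method,
    )


def compute_bct(
    bg: BackgroundEstimate, shift: float, cal: TemperatureCalibration
) -> BctLevel:
    """Background Color Threshold: floor temperature + shift, as a grey level.

    ``shift`` (degC) must be strictly positive; the sensor set-up swept
    shifts of 1, 2 and 3 degC.
    """
    if not shift > 0:
        raise ValueError(f"temperature shift must be > 0, got {shift}")
    level, saturated = cal.intensity_of(bg.floor_temperature + shift)
    return BctLevel(level, saturated or level == 255)


def binarize(frame: ThermalFrame, bct: int) -> BinaryMask:
    """Foreground mask: 1 where the pixel strictly overcomes the BCT."""
    if not 0 <= bct <= 255:
        raise ValueError(f"BCT must be in [0, 255], got {bct}")
    return BinaryMask(pixels=(frame.pixels > bct).astype(np.uint8))


def filter_small_particles(
    mask: BinaryMask, min_area: int = 30, opening_radius: int = 1
) -> BinaryMask:
    """Suppress small nuisance particles (noise specks, residual imprints).

    Morphological opening with a disc of ``opening_radius`` followed by
    removal of 8-connected components smaller than ``min_area`` pixels.
    Output area never exceeds input area; the operation is idempotent.
    """
    if min_area < 0 or opening_radius < 0:
        raise ValueError("min_area and opening_radius must be >= 0")
    out = mask.pixels.astype(bool)
    if opening_radius > 0:
        out = morphology.opening(out, morphology.disk(opening_radius))
    if min_area > 1:
        # remove components of area < min_area (i.e. <= min_area - 1)
        out = morphology.remove_small_objects(out, max_size=min_area - 1, connectivity=2)
    return BinaryMask(pixels=out.astype(np.uint8))


def count_colored_pixels(mask: BinaryMask) -> int:
    """Total amount of Colored Pixels (CP): foreground pixels in the mask."""
    return mask.area()


def _principal_extents(coords: np.ndarray) -> tuple[float, float, float]:
    """Oriented-rectangle sides and angle from a component's pixel coords.

    Pixels are unit squares; projecting their centers onto the principal
    axes and adding 1 gives the extent of the covered span.  Returns
    (long, short, orientation_deg).
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) == 1:
        return 1.0, 1.0, 0.0
    cov = np.cov(centered, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    # eigh returns ascending eigenvalues; principal axis is the last column
    axes = eigvecs[:, ::-1]
    proj = centered @ axes
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    long_side, short_side = float(extents[0]), float(extents[1])
    if long_side < short_side:
        long_side, short_side = short_side, long_side
    # principal axis direction in (row, col) coords -> angle from col axis,
    # counter-clockwise positive (image rows grow downward)
    drow, dcol = axes[0, 0], axes[1, 0]
    angle = float(np.degrees(np.arctan2(-drow, dcol)))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return long_side, short_side, angle


def label_particles(mask: BinaryMask) -> list[Particle]:
    """Identify and measure all 8-connected foreground particles.

    Each particle carries the moments-equivalent ellipse axes and the
    principal-axes oriented rectangle sides used by template calibration.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    particles: list[Particle] = []
    for region in measure.regionprops(labels):
        coords = region.coords.astype(float)
        rect_long, rect_short, angle = _principal_extents(coords)
        particles.append(
            Particle(
                pixel_count=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                ellipse_major=float(region.axis_major_length),
                ellipse_minor=float(region.axis_minor_length),
                rect_long=rect_long,
                rect_short=rect_short,
                orientation=angle,
            )
        )
    return particles
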