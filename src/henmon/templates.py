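"""Hen templates: rasterization and geometry calibration.

The matcher compares each frame's foreground mask against a binary "hen
template".  At a floor shift of 1 degC almost the whole hen body is visible
and an ellipse fits it; at 2-3 degC only the head remains visible and a small
triangle fits better.  Template geometry is calibrated from single-hen
frames: segmentation is run per frame, the largest particle (the hen) is
measured, and the per-feature means become the template dimensions.  The
calibration report carries mean, standard error, 95% confidence interval
(Student t) and a one-sample t-test p-value per feature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from henmon.frame_io import (
    BinaryMask,
    TemperatureCalibration,
    ThermalFrame,
    read_frame,
    write_frame,
)
from henmon import segmentation

__all__ = [
    "Template",
    "GeometryStats",
    "make_ellipse_template",
    "make_triangle_template",
    "calibrate_template",
    "save_template",
    "load_template",
    "geometry_stats_table",
]


@dataclass(frozen=True)
class Template:
    """Binary matching template with its shape metadata.

    ``dims`` is (primary, secondary): (major, minor) axes for an ellipse,
    (base, height) for a triangle, in pixels.  ``shift_association`` records
    the floor-temperature shift (degC) the template was calibrated for.
    """

    mask: BinaryMask
    shape: str  # "ellipse" | "triangle"
    dims: tuple[int, int]
    shift_association: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "triangle"):
            raise ValueError(f"unknown template shape {self.shape!r}")
        if self.mask.area() < 1:
            raise ValueError("template mask must contain at least one pixel")

    @property
    def default_angles(self) -> tuple[float, ...]:
        """Rotation grid for matching: 15-degree steps over the shape's symmetry."""
        if self.shape == "ellipse":  # 180-degree symmetric
            return tuple(float(a) for a in range(0, 180, 15))
        return tuple(float(a) for a in range(0, 360, 15))


@dataclass(frozen=True)
class GeometryStats:
    """Summary statistics for one calibrated geometric feature."""

    feature: str
    mean: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def make_ellipse_template(major: int, minor: int) -> Template:
    """Filled axis-aligned ellipse in a tight (minor+1) x (major+1) mask.

    A pixel belongs to the ellipse when its center lies inside the ellipse
    of the given axes centered in the mask.
    """
    if not (major >= minor >= 3):
        raise ValueError(f"need major >= minor >= 3, got {major} x {minor}")
    h, w = minor + 1, major + 1
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = major / 2.0, minor / 2.0
    inside = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0
    return Template(
        mask=BinaryMask(inside.astype(np.uint8)), shape="ellipse", dims=(major, minor)
    )


def make_triangle_template(base: int, height: int) -> Template:
    """Filled isosceles triangle, base horizontal at the bottom, apex up.

    Row r (0 = apex row) spans a centered width of base*(r+1)/height, so the
    rasterized area approaches base*height/2.  Mirror-symmetric about the
    vertical centerline by construction.
    """
    if base < 3 or height < 3:
        raise ValueError(f"need base >= 3 and height >= 3, got {base} x {height}")
    h, w = height, base
    rr, cc = np.mgrid[0:h, 0:w]
    cx = (w - 1) / 2.0
    # continuous triangle width at this row's pixel centers; a pixel is in
    # when its unit-square center column falls inside that span
    half_width = base * (rr + 0.5) / (2.0 * height)
    inside = np.abs(cc - cx) <= half_width
    if not inside[0].any():  # keep the apex represented at small widths
        inside[0] = np.abs(cc[0] - cx) <= 0.5
    return Template(
        mask=BinaryMask(inside.astype(np.uint8)), shape="triangle", dims=(base, height)
    )


def _feature_stats(feature: str, values: Sequence[float]) -> GeometryStats:
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    mean = float(vals.mean())
    if n >= 2:
        se = float(vals.std(ddof=1) / math.sqrt(n))
    else:
        se = 0.0
    if se > 0:
        tq = float(stats.t.ppf(0.975, n - 1))
        ci = (mean - tq * se, mean + tq * se)
        p = float(stats.ttest_1samp(vals, 0.0).pvalue)
    else:
        ci = (mean, mean)
        p = float("nan")
    return GeometryStats(feature=feature, mean=mean, se=se, ci95=ci, p_value=p, n=n)


def calibrate_template(
    frames: Iterable[ThermalFrame],
    shift: float,
    *,
    floor_method: str = "mode",
    min_particle_area: int = 30,
    opening_radius: int = 1,
    warn: Callable[[str], None] | None = None,
) -> tuple[Template, list[GeometryStats]]:
    """Calibrate template geometry from annotated single-hen frames.

    Every frame is assumed to contain exactly one hen.  Segmentation is run
    at the given floor shift, the largest particle per frame is taken as
    the hen, and its measurements are accumulated: moments-equivalent
    ellipse axes for a 1 degC shift (whole body visible), oriented-rectangle
    sides for larger shifts (head only).  Returns the rounded-mean template
    (ellipse for shift <= 1, triangle otherwise) and the per-feature stats.

    Frames with no particle are skipped with a warning; fewer than two
    usable frames is a calibration error.
    """
    use_ellipse = shift <= 1.0
    primary: list[float] = []
    secondary: list[float] = []
    for frame in frames:
        bg = segmentation.estimate_floor(frame, method=floor_method)
        bct = segmentation.compute_bct(bg, shift, frame.calibration)
        mask = segmentation.binarize(frame, bct.level)
        mask = segmentation.filter_small_particles(mask, min_particle_area, opening_radius)
        particles = segmentation.label_particles(mask)
        if not particles:
            if warn is not None:
                warn(f"frame {frame.frame_id!r}: no particle at shift {shift}; skipped")
            continue
        hen = max(particles, key=lambda p: p.pixel_count)
        if use_ellipse:
            primary.append(hen.ellipse_major)
            secondary.append(hen.ellipse_minor)
        else:
            primary.append(hen.rect_long)
            secondary.append(hen.rect_short)
    if len(primary) < 2:
        raise ValueError(
            f"calibration needs at least 2 usable frames, got {len(primary)}"
        )

    if use_ellipse:
        names = ("ellipse major axis", "ellipse minor axis")
    else:
        names = ("rectangle long side", "rectangle short side")
    stats_out = [
        _feature_stats(names[0], primary),
        _feature_stats(names[1], secondary),
    ]
    dims = (int(round(stats_out[0].mean)), int(round(stats_out[1].mean)))
    if use_ellipse:
        template = make_ellipse_template(*dims)
    else:
        template = make_triangle_template(*dims)
    template = Template(
        mask=template.mask, shape=template.shape, dims=dims, shift_association=shift
    )
    return template, stats_out


def geometry_stats_table(
    stats_list: Sequence[GeometryStats], shift: float, shape: str
) -> str:
    """TSV calibration report: one row per feature, with mean +/- SE, CI, p."""
    lines = [
        "shift_c\tshape\tfeature\tmean_px\tse_px\tci95_low_px\tci95_high_px\tp_value\tn"
    ]
    for s in stats_list:
        p_txt = "nan" if math.isnan(s.p_value) else f"{s.p_value:.3g}"
        lines.append(
            f"{shift:g}\t{shape}\t{s.feature}\t{s.mean:.1f}\t{s.se:.1f}"
            f"\t{s.ci95[0]:.1f}\t{s.ci95[1]:.1f}\t{p_txt}\t{s.n}"
        )
    return "\n".join(lines) + "\n"


def save_template(template: Template, path: str | Path) -> None:
    """Persist a template as a PNG mask plus a JSON sidecar with metadata."""
    path = Path(path)
    frame = ThermalFrame(pixels=template.mask.pixels * 255)
    write_frame(frame, path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": template.shape,
                "dims": list(template.dims),
                "shift_association": template.shift_association,
            },
            indent=2,
        )
        + "\n"
    )


def load_template(path: str | Path) -> Template:
    """Load a template saved by :func:`save_template`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    frame = read_frame(path, TemperatureCalibration())
    mask = BinaryMask((frame.pixels > 0).astype(np.uint8))
    return Template(
        mask=mask,
        shape=meta["shape"],
        dims=tuple(meta["dims"]),
        shift_association=meta.get("shift_association"),
    )
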