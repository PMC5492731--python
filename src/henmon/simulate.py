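"""Synthetic thermographic scene generator with ground truth.

Emulates the sensor's operating scene so the whole pipeline runs without
hardware: a closed-room floor at 5-13 degC ambient (8 degC typical) with
per-pixel Gaussian camera noise at the sensor's 0.04 degC sensitivity, hens
rendered as rotated warm ellipses (nominal 135 x 63 px at this camera
geometry) with a hotter head disc at one end, and the three nuisance
artifact classes a floor accumulates: foot imprints left by a standing
hen (+0.5 degC discs), eggs laid outside the nest (discs at hen body
temperature), and intrinsically warm floor patches (+1.5 degC blobs).

The camera's absolute-temperature error (rated +/-2 degC) can be modelled as
a per-sequence constant offset; because the detector thresholds relative
to the per-frame floor estimate, enabling it must not change any decision.

Determinism: every frame's randomness derives from (scene.seed,
slot_index), so a given slot renders bit-identically regardless of
rendering order or batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np

from henmon.frame_io import TemperatureCalibration, ThermalFrame, write_frame

__all__ = [
    "SceneConfig",
    "HenTruth",
    "GroundTruth",
    "render_frame",
    "render_sequence",
    "simulate_frames",
    "block_schedule",
    "random_schedule",
]

#: anchor for synthetic timestamps (field trials ran November mornings)
_EPOCH = datetime(2016, 11, 7, 11, 0, 0)

TRUTH_COLUMNS = (
    "slot",
    "occupancy",
    "n_hens",
    "hen_row",
    "hen_col",
    "hen_major",
    "hen_minor",
    "hen_angle",
    "artifacts",
)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic closed-room scene.

    ``hen_delta_t`` is the hen body surface contrast above the floor in
    degC: a (low, high) pair samples uniformly per hen, a single float
    fixes it.  The head disc is ``head_extra_t`` hotter than the body.
    """

    raster: tuple[int, int] = (240, 320)
    floor_temp: float = 8.0
    floor_noise_sd: float = 0.04
    hen_axes: tuple[float, float] = (135.0, 63.0)
    hen_axes_jitter_sd: float = 0.0
    hen_delta_t: float | tuple[float, float] = (1.0, 4.0)
    head_extra_t: float = 1.0
    head_radius: float = 10.0
    footprint_rate: float = 0.05
    egg_rate: float = 0.02
    hot_patch_rate: float = 0.02
    occupancy_schedule: tuple[int, ...] | None = None
    global_offset_c: float = 0.0
    slot_seconds: float = 2.0
    calibration: TemperatureCalibration = field(default_factory=TemperatureCalibration)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_noise_sd < 0:
            raise ValueError("floor_noise_sd must be >= 0")
        for name in ("footprint_rate", "egg_rate", "hot_patch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo = self.hen_delta_t[0] if isinstance(self.hen_delta_t, tuple) else self.hen_delta_t
        if not lo > 0:
            raise ValueError("hen_delta_t must be > 0")


@dataclass(frozen=True)
class HenTruth:
    centroid: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    delta_t: float


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame truth: occupancy flag, hen geometry, artifact inventory."""

    slot: int
    occupancy: int
    hens: tuple[HenTruth, ...]
    artifacts: tuple[str, ...]


def block_schedule(n_slots: int, start: int, end: int) -> tuple[int, ...]:
    """Occupancy 1 on slots [start, end] inclusive, 0 elsewhere."""
    return tuple(1 if start <= i <= end else 0 for i in range(n_slots))


def random_schedule(n_slots: int, p_occupied: float, seed: int) -> tuple[int, ...]:
    """Independent per-slot occupancy with probability ``p_occupied``."""
    rng = np.random.default_rng([seed, 0xC0C0])
    return tuple(int(x) for x in (rng.random(n_slots) < p_occupied))


def _sample_delta(scene: SceneConfig, rng: np.random.Generator) -> float:
    if isinstance(scene.hen_delta_t, tuple):
        lo, hi = scene.hen_delta_t
        return float(rng.uniform(lo, hi))
    return float(scene.hen_delta_t)


def _paint_disc(
    temps: np.ndarray, center: tuple[float, float], radius: float, value: float
) -> None:
    """Set pixels within ``radius`` of ``center`` to at least ``value``."""
    h, w = temps.shape
    r0 = max(0, int(center[0] - radius) - 1)
    r1 = min(h, int(center[0] + radius) + 2)
    c0 = max(0, int(center[1] - radius) - 1)
    c1 = min(w, int(center[1] + radius) + 2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    region = temps[r0:r1, c0:c1]
    region[inside] = np.maximum(region[inside], value)


def _paint_ellipse(
    temps: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float,
    value: float,
) -> None:
    """Set pixels inside a rotated filled ellipse to at least ``value``."""
    h, w = temps.shape
    a, b = axes[0] / 2.0, axes[1] / 2.0
    half = a + 2
    r0 = max(0, int(center[0] - half))
    r1 = min(h, int(center[0] + half) + 1)
    c0 = max(0, int(center[1] - half))
    c1 = min(w, int(center[1] + half) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    th = np.radians(angle_deg)
    dr, dc = rr - center[0], cc - center[1]
    # major axis direction (cos th, sin th) in (col, -row) image terms
    u = dc * np.cos(th) - dr * np.sin(th)
    v = dc * np.sin(th) + dr * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = temps[r0:r1, c0:c1]
    region[inside] = np.maximum(region[inside], value)


def _place_hen(
    scene: SceneConfig, rng: np.random.Generator
) -> HenTruth:
    """Sample one hen's geometry, fully inside the raster; retries bounded."""
    h, w = scene.raster
    major = scene.hen_axes[0] + rng.normal(0, scene.hen_axes_jitter_sd)
    minor = scene.hen_axes[1] + rng.normal(0, scene.hen_axes_jitter_sd)
    major = max(major, 8.0)
    minor = float(np.clip(minor, 6.0, major))
    margin = major / 2.0 + 2
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"hen axes {major:.0f}x{minor:.0f} cannot be placed in raster {scene.raster}"
        )
    row = float(rng.uniform(margin, h - margin))
    col = float(rng.uniform(margin, w - margin))
    angle = float(rng.uniform(0.0, 180.0))
    delta = _sample_delta(scene, rng)
    return HenTruth(centroid=(row, col), axes=(major, minor), angle=angle, delta_t=delta)


def render_frame(
    scene: SceneConfig,
    slot_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[ThermalFrame, GroundTruth]:
    """Render one slot's thermographic frame plus its ground truth.

    Layers, bottom to top: noisy floor, artifacts (footprints, egg, hot
    patch, each drawn with per-frame probability), then the scheduled hens
    with their head discs.  The temperature field is quantized through the
    scene calibration into 8-bit grey levels.
    """
    if rng is None:
        rng = np.random.default_rng([scene.seed, slot_index])
    h, w = scene.raster
    base = scene.floor_temp + scene.global_offset_c
    temps = base + rng.normal(0.0, scene.floor_noise_sd, size=(h, w))

    artifacts: list[str] = []
    if rng.random() < scene.footprint_rate:
        row = rng.uniform(15, h - 15)
        col = rng.uniform(15, w - 15)
        for k in (-1, 1):
            r = rng.uniform(3, 5)
            _paint_disc(temps, (row + k * 6, col + rng.uniform(-3, 3)), r, base + 0.5)
        artifacts.append("footprint")
    if rng.random() < scene.egg_rate:
        r = rng.uniform(8, 12)
        center = (rng.uniform(r + 2, h - r - 2), rng.uniform(r + 2, w - r - 2))
        _paint_disc(temps, center, r, base + _sample_delta(scene, rng))
        artifacts.append("egg")
    if rng.random() < scene.hot_patch_rate:
        axes = (rng.uniform(20, 40), rng.uniform(12, 25))
        half = axes[0] / 2 + 2
        center = (rng.uniform(half, h - half), rng.uniform(half, w - half))
        _paint_ellipse(temps, center, axes, rng.uniform(0, 180), base + 1.5)
        artifacts.append("hot-patch")

    n_hens = 0
    if scene.occupancy_schedule is not None and slot_index < len(scene.occupancy_schedule):
        n_hens = int(scene.occupancy_schedule[slot_index])
    hens: list[HenTruth] = []
    for _ in range(n_hens):
        hen = _place_hen(scene, rng)
        _paint_ellipse(temps, hen.centroid, hen.axes, hen.angle, base + hen.delta_t)
        # head disc near one end of the major axis, fully inside the body
        th = np.radians(hen.angle)
        d = 0.4 * hen.axes[0]
        head = (
            hen.centroid[0] - d * np.sin(th),
            hen.centroid[1] + d * np.cos(th),
        )
        radius = min(scene.head_radius, hen.axes[1] / 2.5)
        _paint_disc(temps, head, radius, base + hen.delta_t + scene.head_extra_t)
        hens.append(hen)

    pixels = scene.calibration.field_to_levels(temps)
    frame = ThermalFrame(
        pixels=pixels,
        calibration=scene.calibration,
        timestamp=_EPOCH + timedelta(seconds=slot_index * scene.slot_seconds),
        frame_id=f"sim-{slot_index:06d}",
    )
    truth = GroundTruth(
        slot=slot_index,
        occupancy=int(len(hens) > 0),
        hens=tuple(hens),
        artifacts=tuple(artifacts),
    )
    return frame, truth


def simulate_frames(
    scene: SceneConfig, n_slots: int
) -> Iterator[tuple[ThermalFrame, GroundTruth]]:
    """Lazily render ``n_slots`` consecutive frames (one per slot)."""
    for slot in range(n_slots):
        yield render_frame(scene, slot)


def _truth_row(t: GroundTruth) -> str:
    if t.hens:
        hen = t.hens[0]
        geom = (
            f"{hen.centroid[0]:.1f}\t{hen.centroid[1]:.1f}"
            f"\t{hen.axes[0]:.1f}\t{hen.axes[1]:.1f}\t{hen.angle:.1f}"
        )
    else:
        geom = "NA\tNA\tNA\tNA\tNA"
    return (
        f"{t.slot}\t{t.occupancy}\t{len(t.hens)}\t{geom}\t{';'.join(t.artifacts)}"
    )


def render_sequence(
    scene: SceneConfig,
    n_slots: int,
    out_dir: str | Path,
    image_format: str = "png",
) -> tuple[list[Path], Path]:
    """Write ``n_slots`` frames plus an aligned ``truth.tsv``.

    Frames are named with their synthetic ``YYYYMMDD-HHMMSS`` timestamps
    (suffixed with the slot index to stay unique at sub-second slots).
    Returns (frame paths, truth path).
    """
    if n_slots < 0:
        raise ValueError("n_slots must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    truth_path = out_dir / "truth.tsv"
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for slot in range(n_slots):
            frame, truth = render_frame(scene, slot)
            stamp = frame.timestamp.strftime("%Y%m%d-%H%M%S")
            path = out_dir / f"{stamp}_{slot:06d}.{image_format}"
            write_frame(frame, path)
            paths.append(path)
            fh.write(_truth_row(truth) + "\n")
    return paths, truth_path
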