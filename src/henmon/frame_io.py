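"""Grey-scale thermal frame I/O and the intensity<->temperature calibration.

A thermographic camera delivers 8-bit grey frames in which each intensity
level corresponds to a measured temperature.  The mapping is modelled as a
linear calibration (offset + slope) carried alongside every frame; the
default of 0.0 degC at level 0 and 0.1 degC per level spans 0-25.5 degC, which
covers the 5-13 degC ambient range of an unheated housing room in autumn with
headroom for hen body surfaces.  Under this default a 1 degC temperature
shift is exactly a 10-level intensity shift.

Coordinate convention: row-major, origin at top-left, 0-based, (row, col)
order everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image

#: Nominal camera raster (rows, cols) == 240 x 320 pixels.
NOMINAL_RASTER = (240, 320)

#: Filename timestamp pattern, e.g. "20161107-110002.png".
_TIMESTAMP_RE = re.compile(r"(\d{8})-(\d{6})")


class IntensityLevel(NamedTuple):
    """Grey level plus a flag telling whether clamping occurred."""

    level: int
    saturated: bool


@dataclass(frozen=True)
class TemperatureCalibration:
    """Linear map between grey levels [0, 255] and degrees Celsius.

    Parameters
    ----------
    t_at_zero:
        Temperature (degC) mapped to intensity 0.
    degrees_per_level:
        Temperature step (degC) per grey level; strictly positive.
    """

    t_at_zero: float = 0.0
    degrees_per_level: float = 0.1

    def __post_init__(self) -> None:
        if not self.degrees_per_level > 0:
            raise ValueError(
                f"degrees_per_level must be > 0, got {self.degrees_per_level}"
            )

    @property
    def t_max(self) -> float:
        """Temperature mapped to intensity 255 (top of the representable range)."""
        return self.t_at_zero + 255 * self.degrees_per_level

    def intensity_of(self, t: float) -> IntensityLevel:
        """Nearest grey level for temperature ``t``, clamped to [0, 255]."""
        raw = round((t - self.t_at_zero) / self.degrees_per_level)
        level = min(255, max(0, raw))
        return IntensityLevel(int(level), raw != level)

    def temperature_of(self, level: int) -> float:
        """Temperature at grey ``level``; raises on levels outside [0, 255]."""
        if not 0 <= level <= 255:
            raise ValueError(f"grey level must be in [0, 255], got {level}")
        return self.t_at_zero + level * self.degrees_per_level

    def field_to_levels(self, temperatures: np.ndarray) -> np.ndarray:
        """Vectorized quantization of a temperature field into uint8 levels."""
        raw = np.rint((np.asarray(temperatures) - self.t_at_zero) / self.degrees_per_level)
        return np.clip(raw, 0, 255).astype(np.uint8)


def intensity_of(t: float, cal: TemperatureCalibration) -> IntensityLevel:
    """Grey level for temperature ``t`` under ``cal`` (clamped + saturation flag)."""
    return cal.intensity_of(t)


def temperature_of(level: int, cal: TemperatureCalibration) -> float:
    """Temperature for grey ``level`` under ``cal``."""
    return cal.temperature_of(level)


@dataclass
class ThermalFrame:
    """A calibrated 8-bit grey-scale thermographic frame.

    ``pixels`` is a (height, width) uint8 array; ``calibration`` maps its
    levels to temperatures; ``timestamp`` is the acquisition instant;
    ``frame_id`` is an opaque label (usually the source filename stem).
    """

    pixels: np.ndarray
    calibration: TemperatureCalibration = field(default_factory=TemperatureCalibration)
    timestamp: datetime = field(default_factory=datetime.now)
    frame_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"pixels must be a 2-D non-empty grid, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError("pixel values must be integers in [0, 255]")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def temperatures(self) -> np.ndarray:
        """Per-pixel temperature field (degC) under this frame's calibration."""
        return self.calibration.t_at_zero + self.pixels * self.calibration.degrees_per_level


@dataclass
class BinaryMask:
    """A {0,1} foreground mask on the same raster as its source frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            arr = arr.astype(np.uint8)
        if arr.max(initial=0) > 1:
            raise ValueError("mask values must be 0 or 1")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area(self) -> int:
        return int(self.pixels.sum())


def _timestamp_from_name(path: Path) -> datetime | None:
    m = _TIMESTAMP_RE.search(path.stem)
    if m is None:
        return None
    try:
        return datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")
    except ValueError:
        return None


def read_frame(path: str | Path, calibration: TemperatureCalibration) -> ThermalFrame:
    """Read an 8-bit grey BMP/PNG into a :class:`ThermalFrame`.

    Multi-channel images are accepted only when all channels are equal
    (a grey image stored as RGB); unequal channels signal a non-grey
    source and raise ``ValueError``.  The timestamp is parsed from a
    ``YYYYMMDD-HHMMSS`` filename pattern when present, else taken as the
    load time.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ValueError(f"{path}: channels differ; not a grey-scale frame")
        arr = rgb[..., 0]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")

    ts = _timestamp_from_name(path) or datetime.now()
    return ThermalFrame(pixels=arr, calibration=calibration, timestamp=ts, frame_id=path.stem)


def write_frame(frame: ThermalFrame, path: str | Path) -> None:
    """Write a frame as an 8-bit grey image; format chosen from the extension."""
    Image.fromarray(frame.pixels, mode="L").save(Path(path))
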