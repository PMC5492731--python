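"""Detection orchestration: per-frame decision, slot loop, TSV log.

Each frame runs the full subroutine: histogram -> floor estimate -> BCT at
the configured shift -> binarization -> small-particle filter -> colored
pixel (CP) count -> template pattern recognition.  The Hens Detected (HD)
flag is raised on a positive pattern match, or — as a fallback for hens
whose pose defeats the template — when CP strictly overcomes the Colored
Pixels Threshold (CPT), a count proportional to one hen's visible thermal
imprint.

A monitoring run groups time-ordered frames into fixed-duration slots
(2 s by default); a slot is positive if any of its frames is, and each
closed slot appends one record to a UTF-8 tab-separated log with ISO-8601
timestamps and the set-up echo, so runs are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

from henmon.frame_io import TemperatureCalibration, ThermalFrame
from henmon import segmentation
from henmon.matching import MatchResult, match_template
from henmon.templates import Template, make_ellipse_template

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "MonitoringRecord",
    "decide_hd",
    "detect_frame",
    "run_monitoring",
    "read_log",
    "LOG_COLUMNS",
]

LOG_COLUMNS = (
    "slot_start",
    "slot_end",
    "hd",
    "cp",
    "bct",
    "shift_c",
    "template_id",
    "ncc_score",
    "warnings",
)


def _default_template() -> Template:
    return make_ellipse_template(135, 63)


@dataclass
class DetectorConfig:
    """Full set-up of the detection sensor.

    Defaults mirror the final field set-up: 1 degC floor shift, elliptical
    135 x 63 template, CPT of 1736 pixels, 2-second monitoring slots.
    """

    shift: float = 1.0
    template: Template = field(default_factory=_default_template)
    ncc_threshold: float = 0.5
    cpt: int = 1736
    min_particle_area: int = 30
    opening_radius: int = 1
    floor_method: str = "mode"
    slot_seconds: float = 2.0
    calibration: TemperatureCalibration = field(default_factory=TemperatureCalibration)
    angles: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.shift > 0:
            raise ValueError("shift must be > 0")
        if not self.cpt > 0:
            raise ValueError("cpt must be > 0")
        if not self.slot_seconds > 0:
            raise ValueError("slot_seconds must be > 0")

    @property
    def template_id(self) -> str:
        return f"{self.template.shape}-{self.template.dims[0]}x{self.template.dims[1]}"


@dataclass(frozen=True)
class DetectionResult:
    """Per-frame decision with its provenance."""

    hd: int
    matched: bool
    cp: int
    bct: int
    match: MatchResult
    frame_id: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MonitoringRecord:
    """One closed monitoring slot, as written to the log."""

    slot_start: datetime
    slot_end: datetime
    hd: int
    cp: int
    bct: int
    shift_c: float
    template_id: str
    ncc_score: float
    warnings: tuple[str, ...] = ()


def decide_hd(matched: bool, cp: int, cpt: int) -> int:
    """HD flag logic: positive match, else CP strictly overcoming CPT."""
    return 1 if (matched or cp > cpt) else 0


def detect_frame(frame: ThermalFrame, config: DetectorConfig) -> DetectionResult:
    """Run the full detection subroutine on a single frame."""
    warnings: list[str] = []
    bg = segmentation.estimate_floor(frame, method=config.floor_method)
    bct = segmentation.compute_bct(bg, config.shift, frame.calibration)
    if bct.saturated:
        warnings.append("saturated-bct")
    mask = segmentation.binarize(frame, bct.level)
    mask = segmentation.filter_small_particles(
        mask, config.min_particle_area, config.opening_radius
    )
    cp = segmentation.count_colored_pixels(mask)
    if cp == 0:
        # empty foreground: every NCC window is constant, so the score
        # surface is identically 0 — skip the transform
        match = MatchResult(found=False, score=0.0, location=(0, 0), angle=0.0)
    else:
        match = match_template(
            mask, config.template, config.ncc_threshold, config.angles
        )
    hd = decide_hd(match.found, cp, config.cpt)
    return DetectionResult(
        hd=hd,
        matched=match.found,
        cp=cp,
        bct=bct.level,
        match=match,
        frame_id=frame.frame_id,
        warnings=tuple(warnings),
    )


def _format_record(rec: MonitoringRecord) -> str:
    return "\t".join(
        [
            rec.slot_start.isoformat(),
            rec.slot_end.isoformat(),
            str(rec.hd),
            str(rec.cp),
            str(rec.bct),
            repr(rec.shift_c),
            rec.template_id,
            repr(rec.ncc_score),
            ";".join(rec.warnings),
        ]
    )


def run_monitoring(
    frames: Iterable[ThermalFrame],
    config: DetectorConfig,
    log_path: str | Path,
) -> list[MonitoringRecord]:
    """Process a time-ordered frame stream slot by slot, logging each slot.

    Slots are consecutive ``slot_seconds`` intervals anchored at the first
    frame's timestamp; a slot's HD is 1 if any of its frames detects a hen.
    The slot's logged CP and NCC score are the maxima over its frames and
    the BCT that of its first frame.  Records are flushed to ``log_path``
    as they are produced; an empty source yields a header-only log.
    """
    log_path = Path(log_path)
    records: list[MonitoringRecord] = []
    slot_len = timedelta(seconds=config.slot_seconds)

    with log_path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(LOG_COLUMNS) + "\n")
        fh.flush()

        window_start: datetime | None = None
        slot_index: int | None = None
        slot_results: list[DetectionResult] = []
        slot_errors: list[str] = []

        def close_slot() -> None:
            nonlocal slot_results, slot_errors
            assert window_start is not None and slot_index is not None
            start = window_start + slot_index * slot_len
            warnings: list[str] = list(slot_errors)
            if slot_results:
                hd = max(r.hd for r in slot_results)
                cp = max(r.cp for r in slot_results)
                score = max(r.match.score for r in slot_results)
                bct = slot_results[0].bct
                for r in slot_results:
                    warnings.extend(r.warnings)
            else:
                hd, cp, score, bct = 0, 0, 0.0, 0
                warnings.append("no-frames")
            rec = MonitoringRecord(
                slot_start=start,
                slot_end=start + slot_len,
                hd=hd,
                cp=cp,
                bct=bct,
                shift_c=config.shift,
                template_id=config.template_id,
                ncc_score=score,
                warnings=tuple(dict.fromkeys(warnings)),
            )
            records.append(rec)
            fh.write(_format_record(rec) + "\n")
            fh.flush()
            slot_results = []
            slot_errors = []

        for frame in frames:
            if window_start is None:
                window_start = frame.timestamp
                slot_index = 0
            idx = int((frame.timestamp - window_start) / slot_len)
            while idx > slot_index:
                close_slot()
                slot_index += 1
            try:
                slot_results.append(detect_frame(frame, config))
            except Exception as exc:  # unreadable/degenerate frame: flag, continue
                slot_errors.append(f"frame-error:{exc}")
        if window_start is not None:
            close_slot()
    return records


def read_log(log_path: str | Path) -> list[MonitoringRecord]:
    """Parse a monitoring log back into records (round-trips every field)."""
    lines = Path(log_path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != list(LOG_COLUMNS):
        raise ValueError(f"{log_path}: not a monitoring log")
    records = []
    for line in lines[1:]:
        f = line.split("\t")
        records.append(
            MonitoringRecord(
                slot_start=datetime.fromisoformat(f[0]),
                slot_end=datetime.fromisoformat(f[1]),
                hd=int(f[2]),
                cp=int(f[3]),
                bct=int(f[4]),
                shift_c=float(f[5]),
                template_id=f[6],
                ncc_score=float(f[7]),
                warnings=tuple(w for w in f[8].split(";") if w),
            )
        )
    return records
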