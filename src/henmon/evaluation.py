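"""Detector scoring: confusion counts and the four accuracy metrics.

Slot decisions are compared one-to-one against ground-truth occupancy
(manual video review in the field; the simulator's truth table on
synthetic data) and tallied into TP/FP/TN/FN.  The standard rates follow:

    sensitivity [%] = 100 * TP / (FN + TP)
    specificity [%] = 100 * TN / (FP + TN)
    error rate  [%] = 100 * FP / (FP + TP)
    accuracy    [%] = 100 * (TP + TN) / (TP + TN + FP + FN)

Reported values are rounded half-up to one decimal; full precision is
retained internally.  A metric whose denominator is zero is undefined and
reported as absent (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from henmon.detector import MonitoringRecord

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "tally",
    "metrics",
    "read_truth",
    "write_report",
    "round_half_up",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies over aligned slots."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The four rates in percent; ``None`` marks an undefined metric."""

    sensitivity: float | None
    specificity: float | None
    error_rate: float | None
    accuracy: float | None

    def rounded(self) -> "MetricReport":
        """Copy with every defined metric rounded half-up to one decimal."""
        return MetricReport(
            *(None if v is None else round_half_up(v, 1) for v in (
                self.sensitivity, self.specificity, self.error_rate, self.accuracy
            ))
        )


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (7.25 -> 7.3), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def tally(
    records: Sequence[MonitoringRecord] | Sequence[int],
    truth: Sequence[int],
) -> ConfusionCounts:
    """Confusion counts from aligned per-slot decisions and occupancy flags.

    ``records`` may be monitoring records or bare 0/1 decisions; ``truth``
    holds the 0/1 occupancy flag per slot, in the same order.
    """
    if len(records) != len(truth):
        raise ValueError(
            f"records ({len(records)}) and truth ({len(truth)}) must align one-to-one"
        )
    tp = fp = tn = fn = 0
    for rec, occ in zip(records, truth):
        hd = rec.hd if isinstance(rec, MonitoringRecord) else int(rec)
        if occ:
            if hd:
                tp += 1
            else:
                fn += 1
        else:
            if hd:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, error rate and accuracy (percent)."""
    if c.total < 1:
        raise ValueError("cannot compute metrics on empty counts")

    def rate(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return MetricReport(
        sensitivity=rate(c.tp, c.fn + c.tp),
        specificity=rate(c.tn, c.fp + c.tn),
        error_rate=rate(c.fp, c.fp + c.tp),
        accuracy=rate(c.tp + c.tn, c.total),
    )


def read_truth(path: str | Path) -> list[int]:
    """Read a per-slot occupancy TSV (columns: slot index, occupancy flag).

    Extra columns are ignored; rows must be sorted by slot index and
    contiguous from 0.
    """
    flags: list[int] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines:
        if not line.strip() or line.startswith(("#", "slot")):
            continue
        parts = line.split("\t")
        idx, occ = int(parts[0]), int(parts[1])
        if idx != len(flags):
            raise ValueError(f"truth slots must be contiguous from 0; got {idx}")
        if occ not in (0, 1):
            raise ValueError(f"occupancy flag must be 0/1, got {occ}")
        flags.append(occ)
    return flags


def write_report(
    counts: ConfusionCounts, report: MetricReport, path: str | Path
) -> None:
    """Write a TSV report: a counts block then a metrics block."""
    rep = report.rounded()
    lines = [
        "block\tname\tvalue",
        f"counts\ttp\t{counts.tp}",
        f"counts\tfp\t{counts.fp}",
        f"counts\ttn\t{counts.tn}",
        f"counts\tfn\t{counts.fn}",
        f"counts\ttotal\t{counts.total}",
    ]
    for name, value in (
        ("sensitivity_pct", rep.sensitivity),
        ("specificity_pct", rep.specificity),
        ("error_rate_pct", rep.error_rate),
        ("accuracy_pct", rep.accuracy),
    ):
        lines.append(f"metrics\t{name}\t{'NA' if value is None else value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
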