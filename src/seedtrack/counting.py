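"""Line-crossing classified counting of tracked planting holes.

Each tracked target carries a marker point — the midpoint of its bounding
box's lower edge. The first time a confirmed track's marker crosses a
virtual counting line, the counter for its class (seedling-planted or
missed-planting) is incremented, and the track identity is remembered so
the same target is never counted twice. The missed transplanting rate is
the missed-planting share of all counted holes, in percent:

    rate = 100 * T_missed / (T_planted + T_missed)

Both crossing directions count; a marker landing exactly on the line does
not trigger until it reaches a strictly opposite side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .boxes import BoundingBox

__all__ = [
    "CountingLine",
    "CountLedger",
    "marker_point",
    "signed_side",
    "ledger_step",
    "missed_rate",
    "UndefinedRateError",
    "PLANTED",
    "MISSED",
]

PLANTED = 0  # seedling-planted hole ("tobacco")
MISSED = 1  # missed-planting hole ("missing")


class UndefinedRateError(ZeroDivisionError):
    """Raised when no holes have been counted, so the rate has no value."""


@dataclass(frozen=True)
class CountingLine:
    """Virtual counting line through two distinct image points."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("counting line endpoints must be distinct")

    @classmethod
    def horizontal(cls, y: float, width: float) -> "CountingLine":
        return cls((0.0, y), (width, y))


@dataclass
class CountLedger:
    """Per-class crossing counts plus the identities already credited."""

    t1_count: int = 0  # seedling-planted crossings
    t2_count: int = 0  # missed-planting crossings
    counted_ids: set[int] = field(default_factory=set)
    last_side: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.t1_count + self.t2_count


def marker_point(box: BoundingBox) -> tuple[float, float]:
    """Midpoint of the box's lower edge — the target's ground-contact point."""
    return ((box.x_min + box.x_max) / 2.0, box.y_max)


def signed_side(point: tuple[float, float], line: CountingLine) -> float:
    """2D cross product (p1-p0) x (point-p0); zero iff the point is on the line."""
    (x0, y0), (x1, y1) = line.p0, line.p1
    px, py = point
    return (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)


def ledger_step(
    ledger: CountLedger,
    track_id: int,
    class_id: int,
    marker: tuple[float, float],
    line: CountingLine,
    confirmed: bool = True,
) -> CountLedger:
    """Advance the ledger by one observation of one track.

    A count fires only when the stored side and the current side have
    strictly opposite signs, the track is confirmed, and this identity has
    not been counted before. The stored side is always refreshed (including
    for unconfirmed tracks, which never fire).
    """
    if class_id not in (PLANTED, MISSED):
        raise ValueError(f"unknown class_id {class_id}")
    if not all(math.isfinite(c) for c in marker):
        raise ValueError(f"marker must be finite, got {marker}")
    side = signed_side(marker, line)
    prev = ledger.last_side.get(track_id)
    if (
        confirmed
        and prev is not None
        and prev * side < 0.0
        and track_id not in ledger.counted_ids
    ):
        if class_id == PLANTED:
            ledger.t1_count += 1
        else:
            ledger.t2_count += 1
        ledger.counted_ids.add(track_id)
    # a marker exactly on the line (side == 0) keeps the previous side so a
    # grazing trajectory cannot fire twice
    if side != 0.0 or prev is None:
        ledger.last_side[track_id] = side
    return ledger


def missed_rate(ledger: CountLedger) -> float:
    """Missed transplanting rate in percent: 100 * Tn / TN.

    Tn is the missed-planting count and TN the total count. Raises
    :class:`UndefinedRateError` when nothing has been counted — an
    undefined rate is never silently reported as zero.
    """
    if ledger.total == 0:
        raise UndefinedRateError("no crossings counted; missed rate is undefined")
    return 100.0 * ledger.t2_count / ledger.total
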