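"""Shared domain types for LC-MS point data.

An LC-MS run is modelled as a cloud of centroided MS1 data points, each a
triple (m/z, retention time, intensity) optionally tagged with mutable
segmentation metadata: membership in an extracted-ion chromatogram (trace)
and in an isotopic envelope. Retention time is kept in seconds throughout;
scan times tagged in minutes are converted on import. Trace and envelope
id 0 is the reserved "unassigned" sentinel so that rows without
segmentation round-trip through CSV.

Query windows are half-open rectangles ``lo <= x < hi`` on both axes, so
that a path of adjacent windows tiles the plane without duplicate returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "MsPoint",
    "DataBounds",
    "QueryWindow",
    "ValidationError",
    "validate_point",
    "extent",
]


class ValidationError(ValueError):
    """A domain invariant was violated; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class MsPoint:
    """One centroided MS1 datum.

    Parameters
    ----------
    id : int
        Non-negative record index; unique within one store and equal to the
        point's position in the binary point file.
    mz : float
        Mass-to-charge ratio, Thomson.
    rt : float
        Retention time, seconds.
    intensity : float
        Non-negative abundance, arbitrary units.
    trace_id : int
        Extracted-ion-chromatogram (XIC) membership; 0 = unassigned.
    envelope_id : int
        Isotopic-envelope membership; 0 = unassigned.
    """

    id: int
    mz: float
    rt: float
    intensity: float
    trace_id: int = 0
    envelope_id: int = 0

    def with_segmentation(self, trace_id: int, envelope_id: int) -> "MsPoint":
        return replace(self, trace_id=trace_id, envelope_id=envelope_id)

    def with_id(self, new_id: int) -> "MsPoint":
        return replace(self, id=new_id)


@dataclass(frozen=True)
class DataBounds:
    """Closed rectangular extent of a point set (Thomson x seconds)."""

    min_mz: float
    max_mz: float
    min_rt: float
    max_rt: float

    def __post_init__(self) -> None:
        if self.min_mz > self.max_mz:
            raise ValidationError("mz", "min_mz exceeds max_mz")
        if self.min_rt > self.max_rt:
            raise ValidationError("rt", "min_rt exceeds max_rt")

    def union(self, other: "DataBounds") -> "DataBounds":
        return DataBounds(
            min(self.min_mz, other.min_mz),
            max(self.max_mz, other.max_mz),
            min(self.min_rt, other.min_rt),
            max(self.max_rt, other.max_rt),
        )


@dataclass(frozen=True)
class QueryWindow:
    """Half-open m/z x RT rectangle with an optional point budget.

    Membership is ``lo <= x < hi`` on both axes. ``n`` is the maximum
    result cardinality; ``None`` means return every stored point in the
    window.
    """

    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.mz_lo <= self.mz_hi):
            raise ValidationError("mz", "mz_lo exceeds mz_hi")
        if not (self.rt_lo <= self.rt_hi):
            raise ValidationError("rt", "rt_lo exceeds rt_hi")
        if self.n is not None and self.n < 1:
            raise ValidationError("n", "point budget must be positive")

    def contains(self, p: MsPoint) -> bool:
        return (
            self.mz_lo <= p.mz < self.mz_hi
            and self.rt_lo <= p.rt < self.rt_hi
        )

    def intersects(self, b: DataBounds) -> bool:
        """Whether this half-open window overlaps closed bounds ``b``."""
        return (
            self.mz_lo <= b.max_mz
            and b.min_mz < self.mz_hi
            and self.rt_lo <= b.max_rt
            and b.min_rt < self.rt_hi
        )

    def with_budget(self, n: Optional[int]) -> "QueryWindow":
        return QueryWindow(self.mz_lo, self.mz_hi, self.rt_lo, self.rt_hi, n)

    @classmethod
    def covering(cls, bounds: DataBounds, n: Optional[int] = None) -> "QueryWindow":
        """A window containing every point inside ``bounds``.

        The upper edges are nudged one ULP past the maxima so the half-open
        window admits points sitting exactly on the boundary.
        """
        return cls(
            bounds.min_mz,
            math.nextafter(bounds.max_mz, math.inf),
            bounds.min_rt,
            math.nextafter(bounds.max_rt, math.inf),
            n,
        )


def validate_point(p: MsPoint) -> MsPoint:
    """Return ``p`` unchanged if every field invariant holds.

    Raises :class:`ValidationError` naming the first offending field.
    """
    if not isinstance(p.id, int) or p.id < 0:
        raise ValidationError("id", f"must be a non-negative integer, got {p.id!r}")
    if not math.isfinite(p.mz):
        raise ValidationError("mz", f"must be finite, got {p.mz!r}")
    if not math.isfinite(p.rt):
        raise ValidationError("rt", f"must be finite, got {p.rt!r}")
    if not math.isfinite(p.intensity) or p.intensity < 0:
        raise ValidationError(
            "intensity", f"must be finite and non-negative, got {p.intensity!r}"
        )
    if not isinstance(p.trace_id, int) or p.trace_id < 0:
        raise ValidationError("trace_id", f"must be a non-negative integer, got {p.trace_id!r}")
    if not isinstance(p.envelope_id, int) or p.envelope_id < 0:
        raise ValidationError(
            "envelope_id", f"must be a non-negative integer, got {p.envelope_id!r}"
        )
    return p


def extent(points: Iterable[MsPoint]) -> DataBounds:
    """Coordinate-wise min/max bounds over a non-empty point sequence."""
    it = iter(points)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("extent of an empty point sequence is undefined") from None
    min_mz = max_mz = first.mz
    min_rt = max_rt = first.rt
    for p in it:
        if p.mz < min_mz:
            min_mz = p.mz
        elif p.mz > max_mz:
            max_mz = p.mz
        if p.rt < min_rt:
            min_rt = p.rt
        elif p.rt > max_rt:
            max_rt = p.rt
    return DataBounds(min_mz, max_mz, min_rt, max_rt)
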