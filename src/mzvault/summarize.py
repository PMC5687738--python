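"""Weighted striding: deterministic intensity-weighted subsampling.

Given an ordered window of points and a requested sample size ``k``, the
accumulation threshold is ``T = (sum of intensities) / k``. The point array
is walked in a strided visit order, accumulating intensity; each time the
accumulator reaches ``T`` the current point is recruited into the sample
and the excess (``accumulator - T``) is carried into the next iteration.
The walk wraps around the array, skipping already-selected points, until
``k`` points are recruited. The procedure contains no stochastic element:
repeated calls with identical inputs return identical subsamples, and every
returned point is an input point verbatim (no derived/averaged points).

High-intensity points reach the threshold sooner and are therefore
promoted, yet the carryover lets low-intensity points in as well, so the
sample preserves the mix of high and low intensity of the window.

A stride length s > 1 spreads the recruitment over multiple interleaved
passes of the array; the default stride is 42.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

from .model import MsPoint

__all__ = [
    "DEFAULT_STRIDE",
    "StrideParams",
    "compute_threshold",
    "weighted_stride",
    "stride_indices",
]

#: Default visit-order stride for summarization.
DEFAULT_STRIDE = 42


@dataclass(frozen=True)
class StrideParams:
    """Resolved parameters of one weighted-striding run."""

    sample_size: int
    stride_length: int
    threshold: float
    total_intensity: float


def compute_threshold(points: Sequence[MsPoint], sample_size: int) -> float:
    """Accumulation threshold ``T = total_intensity / sample_size``."""
    if sample_size < 1:
        raise ValueError("sample_size must be a positive integer")
    return sum(p.intensity for p in points) / sample_size


def _coprime_stride(stride: int, n: int) -> int:
    """Smallest integer >= stride coprime with n (full-cycle visit order)."""
    s = max(1, stride)
    while math.gcd(s, n) != 1:
        s += 1
    return s


def stride_indices(n: int, stride: int) -> List[int]:
    """The strided visit order: ``(j * s') mod n`` for ``j = 0..n-1``.

    ``s'`` is the smallest integer >= ``stride`` coprime with ``n``, which
    makes the walk a full permutation of ``0..n-1`` and coincides with the
    natural order for stride 1.
    """
    s = _coprime_stride(stride, n)
    return [(j * s) % n for j in range(n)]


def weighted_stride(
    points: Sequence[MsPoint],
    sample_size: int,
    stride_length: int = DEFAULT_STRIDE,
) -> List[MsPoint]:
    """Deterministic intensity-weighted subsample of ``points``.

    Returns ``min(sample_size, len(points))`` distinct input points in
    ascending original-index order. ``sample_size = 0`` or an empty input
    yields an empty list. Selection is scale-invariant: multiplying every
    intensity by the same positive constant leaves the chosen index set
    unchanged.
    """
    n = len(points)
    if sample_size <= 0 or n == 0:
        return []
    if stride_length < 1:
        raise ValueError("stride_length must be >= 1")
    k = min(sample_size, n)
    if k == n:
        return list(points)

    total = math.fsum(p.intensity for p in points)
    threshold = total / k
    if threshold <= 0.0:
        # Degenerate all-zero window: fall back to uniform index striding.
        step = -(-n // k)  # ceil(n / k)
        return [points[i * step] for i in range(k)]

    order = stride_indices(n, stride_length)
    selected = [False] * n
    chosen: List[int] = []
    acc = 0.0
    pos = 0  # cursor into the visit order, wraps modulo n
    pass_gain = 0.0  # intensity accumulated during the current full pass
    seen_in_pass = 0  # unselected points visited in the current pass
    while len(chosen) < k:
        idx = order[pos]
        pos += 1
        if pos == n:
            # Completed one wrap of the visit order; if a whole pass over
            # the surviving points cannot raise the accumulator by T, the
            # loop would never terminate (floating-point shortfall near the
            # end) -- fill the remaining slots greedily by intensity.
            pos = 0
            if seen_in_pass > 0 and pass_gain < threshold and acc < threshold:
                remaining = sorted(
                    (i for i in range(n) if not selected[i]),
                    key=lambda i: (-points[i].intensity, i),
                )
                chosen.extend(remaining[: k - len(chosen)])
                break
            pass_gain = 0.0
            seen_in_pass = 0
        if selected[idx]:
            continue
        seen_in_pass += 1
        gain = points[idx].intensity
        acc += gain
        pass_gain += gain
        if acc >= threshold:
            selected[idx] = True
            chosen.append(idx)
            acc -= threshold
    chosen.sort()
    return [points[i] for i in chosen]
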