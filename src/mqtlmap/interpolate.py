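"""Piecewise-linear (homothetic) coordinate transfer between maps.

A position is transferred between two coordinate systems through a set of
anchor points known in both: inside the anchored span it is scaled linearly
between its flanking anchors,

    out = y1 + (pos - x1) * (y2 - y1) / (x2 - x1),

and outside the span the nearest interval's ratio is extended (flagged as
extrapolation).  This one primitive serves map merging, QTL projection and
genetic<->physical conversion.
"""

from __future__ import annotations

import bisect
from typing import Sequence


class DegenerateIntervalError(ValueError):
    """Two anchors share the same source coordinate; no ratio is defined."""


def piecewise_transfer(
    pos: float, xs: Sequence[float], ys: Sequence[float]
) -> tuple[float, bool]:
    """Map ``pos`` from the x-system to the y-system through anchor pairs.

    ``xs`` must be strictly increasing.  Returns ``(value, extrapolated)``;
    ``extrapolated`` is True when ``pos`` lies outside ``[xs[0], xs[-1]]``.
    """
    if len(xs) != len(ys):
        raise ValueError("anchor coordinate lists differ in length")
    if len(xs) < 2:
        raise ValueError("need at least two anchors")
    for a, b in zip(xs, xs[1:]):
        if b <= a:
            raise DegenerateIntervalError(
                f"anchor x-coordinates not strictly increasing ({a} -> {b})"
            )
    if pos <= xs[0]:
        i = 0
        extrapolated = pos < xs[0]
    elif pos >= xs[-1]:
        i = len(xs) - 2
        extrapolated = pos > xs[-1]
    else:
        i = bisect.bisect_right(xs, pos) - 1
        extrapolated = False
    x1, x2 = xs[i], xs[i + 1]
    y1, y2 = ys[i], ys[i + 1]
    return y1 + (pos - x1) * (y2 - y1) / (x2 - x1), extrapolated


def strictly_increasing_pairs(
    xs: Sequence[float], ys: Sequence[float]
) -> tuple[list[float], list[float]]:
    """Drop pairs whose x collides with the previous kept x (keep the first)."""
    kept_x: list[float] = []
    kept_y: list[float] = []
    for x, y in zip(xs, ys):
        if not kept_x or x > kept_x[-1]:
            kept_x.append(x)
            kept_y.append(y)
    return kept_x, kept_y
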