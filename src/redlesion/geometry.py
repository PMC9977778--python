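"""Circle-quarter geometry for curved-boundary probing.

The detector tests, around each pixel ``(i, j)``, four quarter-circle arcs
(top-right, top-left, bottom-left, bottom-right).  Along every probe angle
``theta`` within a quarter it pairs an *inner* point at radius ``a0`` with an
*outer* point at radius ``a0 + d``; a red lesion whose roundish boundary runs
between the two radii produces a dark-to-light intensity step from the inner
to the outer point for most angles of the quarter.

Conventions
-----------
* Image coordinates are 0-based, row-major, with the row index increasing
  downward, so "top" means a smaller row index.
* ``theta`` is measured from the horizontal axis in quarters 1 and 3 and from
  the vertical axis in quarters 2 and 4 (this is how the sin/cos components
  are placed in the quarter formulas; no re-normalisation is applied).
* The bracket operation mapping real offsets to pixels is round-to-nearest
  with halves away from zero; see :func:`round_half_away`.  A floor variant
  would be a one-line change here and nowhere else.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import NamedTuple

import numpy as np

HALF_PI = math.pi / 2.0

#: Quarter indices: 1 = top-right, 2 = top-left, 3 = bottom-left,
#: 4 = bottom-right.
QUARTERS = (1, 2, 3, 4)

# quarter -> (row sign, col sign, row component uses sin)
_QUARTER_LAYOUT = {
    1: (-1, +1, True),
    2: (-1, -1, False),
    3: (+1, -1, True),
    4: (+1, +1, False),
}


class PointPair(NamedTuple):
    """Inner/outer probe points for one angle of one quarter."""

    inner: tuple[int, int]
    outer: tuple[int, int]


def default_angles(e_theta: float = math.pi / 12.0,
                   theta_max: float = HALF_PI) -> tuple[float, ...]:
    """Uniform angle ladder over ``[0, theta_max]`` with step ``e_theta``.

    The last rung is pinned to ``theta_max`` exactly; at the default step of
    pi/12 this yields the seven angles 0, pi/12, pi/6, pi/4, pi/3, 5pi/12,
    pi/2.
    """
    if e_theta <= 0 or theta_max <= 0:
        raise ValueError("e_theta and theta_max must be positive")
    n_steps = int(round(theta_max / e_theta))
    if n_steps < 1 or abs(n_steps * e_theta - theta_max) > 1e-9:
        raise ValueError("theta_max must be an integer multiple of e_theta")
    return tuple(i * e_theta for i in range(n_steps)) + (theta_max,)


#: Tie tolerance for the bracket: products such as 13*sin(pi/6) are exactly
#: 6.5 in exact arithmetic but land a few ulp on either side of it in
#: floating point, which would make mirror-symmetric angle pairs round to
#: different pixels.  Values within this distance below a half are treated
#: as the half itself.
_TIE_EPS = 1e-9


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    A value within ``1e-9`` of a tie is rounded as the tie, so that
    floating-point representations of exact halves behave like the exact
    value (see ``_TIE_EPS``).
    """
    if x >= 0:
        return int(math.floor(x + 0.5 + _TIE_EPS))
    return -int(math.floor(-x + 0.5 + _TIE_EPS))


@lru_cache(maxsize=4096)
def point_offset(theta: float, k: int, radius: float) -> tuple[int, int]:
    """Integer (row, col) offset of the probe point at ``radius`` for angle
    ``theta`` in quarter ``k``, relative to the centre pixel."""
    try:
        row_sign, col_sign, row_uses_sin = _QUARTER_LAYOUT[k]
    except KeyError:
        raise ValueError(f"quarter index must be in {QUARTERS}, got {k!r}") from None
    s = round_half_away(radius * math.sin(theta))
    c = round_half_away(radius * math.cos(theta))
    dr, dc = (s, c) if row_uses_sin else (c, s)
    return row_sign * dr, col_sign * dc


def corresponding_points(i: int, j: int, theta: float, k: int,
                         a0: float, d: float) -> PointPair:
    """The inner (radius ``a0``) and outer (radius ``a0 + d``) probe pixels
    for angle ``theta`` of quarter ``k`` centred at ``(i, j)``.

    Raises ``ValueError`` for an invalid quarter or non-positive radii; the
    caller is responsible for clipping to image bounds.
    """
    if a0 < 1 or d < 1:
        raise ValueError("require a0 >= 1 and d >= 1")
    if not (-1e-9 <= theta <= HALF_PI + 1e-9):
        raise ValueError("theta must lie in [0, pi/2]")
    dr0, dc0 = point_offset(theta, k, float(a0))
    dr1, dc1 = point_offset(theta, k, float(a0) + float(d))
    return PointPair(inner=(i + dr0, j + dc0), outer=(i + dr1, j + dc1))


@lru_cache(maxsize=256)
def quarter_disc_offsets(k: int, a0: int) -> tuple[np.ndarray, np.ndarray]:
    """All integer offsets ``(dr, dc)`` within Euclidean distance ``a0`` of
    the centre that lie in quarter ``k``'s closed quadrant.

    The quadrant axes are included in both adjacent quarters, so the four
    quarters together cover the full disc with the axes double-counted.
    Returned as two parallel int arrays (rows, cols) for fast indexing.
    """
    try:
        row_sign, col_sign, _ = _QUARTER_LAYOUT[k]
    except KeyError:
        raise ValueError(f"quarter index must be in {QUARTERS}, got {k!r}") from None
    a0 = int(a0)
    drs, dcs = [], []
    for dr in range(-a0, a0 + 1):
        if dr * row_sign < 0:
            continue
        for dc in range(-a0, a0 + 1):
            if dc * col_sign < 0:
                continue
            if dr * dr + dc * dc <= a0 * a0:
                drs.append(dr)
                dcs.append(dc)
    return np.asarray(drs, dtype=np.intp), np.asarray(dcs, dtype=np.intp)


def quarter_pixel_set(i: int, j: int, k: int, a0: int) -> set[tuple[int, int]]:
    """The pixel set of quarter ``k``'s closed quarter-disc of radius ``a0``
    centred at ``(i, j)`` (not clipped to any image)."""
    drs, dcs = quarter_disc_offsets(k, int(a0))
    return {(i + int(dr), j + int(dc)) for dr, dc in zip(drs, dcs)}
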