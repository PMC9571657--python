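"""Exact arithmetic on the 45-degree sector grid.

Directions that matter in a floral diagram are discretized to multiples of
45 degrees.  Sums of unit vectors pointing along those directions live in the
ring Z + Z*(sqrt(2)/2): each component is ``a + b/sqrt(2)`` with integer
``a`` and ``b``.  Because sqrt(2) is irrational, such a component is exactly
zero iff ``a == b == 0`` — so cancellation (a dichasium offsetting itself)
is decided without any floating-point tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_SQRT2_HALF = math.sqrt(2.0) / 2.0

#: cos/sin of k*45 degrees as (a, b) pairs meaning a + b/sqrt(2)
_COS = {0: (1, 0), 1: (0, 1), 2: (0, 0), 3: (0, -1), 4: (-1, 0), 5: (0, -1), 6: (0, 0), 7: (0, 1)}
_SIN = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (0, 1), 4: (0, 0), 5: (0, -1), 6: (-1, 0), 7: (0, -1)}


def on_grid(angle_deg: float, tol: float = 1e-9) -> bool:
    """True if *angle_deg* is a multiple of 45 degrees (mod 360)."""
    return abs(angle_deg / 45.0 - round(angle_deg / 45.0)) < tol


@dataclass(frozen=True)
class Exact:
    """An exact value a + b/sqrt(2)."""

    a: int = 0
    b: int = 0

    def __add__(self, other: "Exact") -> "Exact":
        return Exact(self.a + other.a, self.b + other.b)

    def is_zero(self) -> bool:
        return self.a == 0 and self.b == 0

    def __float__(self) -> float:
        return self.a + self.b * _SQRT2_HALF


@dataclass(frozen=True)
class ExactVec:
    """Exact 2-vector in the (dv, ml) transverse plane."""

    dv: Exact
    ml: Exact

    def __add__(self, other: "ExactVec") -> "ExactVec":
        return ExactVec(self.dv + other.dv, self.ml + other.ml)

    def is_zero(self) -> bool:
        return self.dv.is_zero() and self.ml.is_zero()

    def to_floats(self) -> tuple[float, float]:
        return float(self.dv), float(self.ml)


ZERO_VEC = ExactVec(Exact(), Exact())


def unit(angle_deg: float) -> ExactVec:
    """Unit vector for a direction: exact when on the sector grid.

    Angle convention: 0 = +dv (adaxial), counter-clockwise positive, so the
    dv component is cos(angle) and the ml component is sin(angle).  Raises
    ValueError off the grid; callers fall back to float arithmetic there.
    """
    if not on_grid(angle_deg):
        raise ValueError(f"angle {angle_deg} is not on the 45-degree grid")
    k = int(round(angle_deg / 45.0)) % 8
    return ExactVec(Exact(*_COS[k]), Exact(*_SIN[k]))


def vec_sum(angles_deg: list[float]) -> tuple[float, float]:
    """Resultant (dv, ml) of unit influence vectors; exact cancellation on grid.

    On-grid inputs use exact ring arithmetic, so an offsetting dichasium sums
    to a true (0.0, 0.0).  Off-grid inputs use floats with a 1e-9 snap.
    """
    if all(on_grid(a) for a in angles_deg):
        v = ZERO_VEC
        for ang in angles_deg:
            v = v + unit(ang)
        return v.to_floats()
    dv = sum(math.cos(math.radians(a)) for a in angles_deg)
    ml = sum(math.sin(math.radians(a)) for a in angles_deg)
    if abs(dv) < 1e-9:
        dv = 0.0
    if abs(ml) < 1e-9:
        ml = 0.0
    return dv, ml
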