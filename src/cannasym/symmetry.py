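"""The asymmetry-factor (AF) vector model of floral symmetry.

Floral symmetry in *Canna* is predicted from the flower's position in the
branching system.  Two transverse influence vectors act on a developing
flower:

* **AF1** — from the preceding order: zero for a solitary or top flower
  (the primordium arises vertically), a unit adaxial vector for every
  lateral (axillary) flower.
* **AF2** — from the proceeding order: the resultant of unit vectors toward
  all next-order branches (their bracts), normalized when nonzero.  An
  offsetting dichasium cancels exactly.

The combination ``SUM_AF`` counts the transverse axes (dorsoventral,
mediolateral) that carry influence: 0 predicts actinomorphy, 1 zygomorphy
about the unloaded axis's mirror plane (recorded as the loaded axis),
2 asymmetry.  An axis counts as loaded when AF1 *or* AF2 has a nonzero
component on it — an influence along an axis breaks the orthogonal mirror
plane even if the two factors' signed components happen to cancel.

An independent brute-force mirror-plane oracle is provided for
verification: it reflects the typed influence multiset about the candidate
anatomical mirror planes and checks invariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._sector import vec_sum
from .topology import FlorescenceNode, flanking_bracts, is_lateral

ACTINOMORPHIC = "actinomorphic"
ZYGOMORPHIC = "zygomorphic"
ASYMMETRIC = "asymmetric"

_TOL = 1e-9


@dataclass(frozen=True)
class AsymmetryVector:
    """Signed transverse influence vector; dv positive = adaxial, ml positive = left."""

    dv: float
    ml: float
    source: str  # AF1 | AF2 | net

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dv, self.ml)

    @property
    def loaded_axes(self) -> frozenset[str]:
        axes = set()
        if abs(self.dv) > _TOL:
            axes.add("dorsoventral")
        if abs(self.ml) > _TOL:
            axes.add("mediolateral")
        return frozenset(axes)


@dataclass(frozen=True)
class SumAF:
    value: int  # 0, 1 or 2
    net: AsymmetryVector
    loaded_axes: frozenset[str]


def af1(tree: FlorescenceNode, flower_id: str) -> AsymmetryVector:
    """Preceding-order asymmetry factor: 0 for solitary/top flowers, unit adaxial otherwise.

    The sign convention (adaxial-positive) never changes SUM_AF; it only
    pins down deterministic orientations downstream.
    """
    if is_lateral(tree, flower_id):
        return AsymmetryVector(dv=1.0, ml=0.0, source="AF1")
    return AsymmetryVector(dv=0.0, ml=0.0, source="AF1")


def af2(tree: FlorescenceNode, flower_id: str) -> AsymmetryVector:
    """Proceeding-order asymmetry factor: normalized resultant of branch directions.

    Sums unit vectors toward every proceeding-order bract (including bracts
    of aborted branches — the meristem exerted its influence), with exact
    cancellation on the 45-degree grid; a zero resultant stays zero,
    otherwise the resultant is normalized to unit magnitude.
    """
    angles = [b.angle_deg for b in flanking_bracts(tree, flower_id)]
    dv, ml = vec_sum(angles)
    norm = math.hypot(dv, ml)
    if norm < _TOL:
        return AsymmetryVector(dv=0.0, ml=0.0, source="AF2")
    return AsymmetryVector(dv=dv / norm, ml=ml / norm, source="AF2")


def sum_af(a1: AsymmetryVector, a2: AsymmetryVector) -> SumAF:
    """Combine AF1 and AF2 into the axis-count SUM_AF and the net vector.

    SUM_AF = number of transverse axes on which either factor carries a
    nonzero component (0, 1 or 2).  The net vector is the plain componentwise
    sum; when the factors are collinear and opposed the net component can be
    zero while the axis still counts once.
    """
    loaded = a1.loaded_axes | a2.loaded_axes
    net = AsymmetryVector(dv=a1.dv + a2.dv, ml=a1.ml + a2.ml, source="net")
    return SumAF(value=len(loaded), net=net, loaded_axes=loaded)


def predict_symmetry(s: SumAF) -> tuple[str, str | None]:
    """Map SUM_AF to a symmetry class and (for zygomorphy) the loaded axis.

    0 -> actinomorphic; 1 -> zygomorphic with zygomorphy_axis = the single
    loaded axis; 2 -> asymmetric.
    """
    if s.value == 0:
        return ACTINOMORPHIC, None
    if s.value == 1:
        (axis,) = s.loaded_axes
        return ZYGOMORPHIC, axis
    return ASYMMETRIC, None


def predict_symmetry_for_flower(tree: FlorescenceNode, flower_id: str) -> tuple[str, str | None, SumAF]:
    """Run the full AF chain for one flower of a tree."""
    s = sum_af(af1(tree, flower_id), af2(tree, flower_id))
    cls, axis = predict_symmetry(s)
    return cls, axis, s


# ---------------------------------------------------------------------------
# independent verification oracle


def _reflect_angle(angle: float, axis_deg: float) -> float:
    return (2.0 * axis_deg - angle) % 360.0


def _invariant(influences: list[tuple[float, str]], axis_deg: float, tol: float) -> bool:
    remaining = list(influences)
    for angle, kind in influences:
        target = _reflect_angle(angle, axis_deg)
        hit = next(
            (
                item
                for item in remaining
                if item[1] == kind
                and min(abs(item[0] - target), 360.0 - abs(item[0] - target)) <= tol
            ),
            None,
        )
        if hit is None:
            return False
        remaining.remove(hit)
    return True


def mirror_plane_oracle(
    influence_angles: list[float],
    attachment_angle: float | None = None,
    tol: float = 1e-6,
) -> str:
    """Brute-force symmetry classification of a flower's influence arrangement.

    *influence_angles* are the directions (flower's frame, degrees) of all
    proceeding-order attachments; *attachment_angle* is the direction of the
    preceding-order attachment for a lateral flower (None for solitary/top
    flowers).  Candidate mirror planes are the two anatomical axes of the
    floral diagram — dorsoventral (0-180) and mediolateral (90-270); a
    reflection must map attachments to attachments and branches to branches.

    No influences, or invariance under every candidate axis, is classed
    actinomorphic; invariance under at least one axis zygomorphic; under
    none, asymmetric.
    """
    influences: list[tuple[float, str]] = [(a % 360.0, "branch") for a in influence_angles]
    if attachment_angle is not None:
        influences.append((attachment_angle % 360.0, "attachment"))
    if not influences:
        return ACTINOMORPHIC
    surviving = [axis for axis in (0.0, 90.0) if _invariant(influences, axis, tol)]
    if len(surviving) == 2:
        return ACTINOMORPHIC
    if surviving:
        return ZYGOMORPHIC
    return ASYMMETRIC


def oracle_for_flower(tree: FlorescenceNode, flower_id: str) -> str:
    """Apply the mirror-plane oracle to a flower's influence set in a tree."""
    angles = [b.angle_deg for b in flanking_bracts(tree, flower_id)]
    attachment = 0.0 if is_lateral(tree, flower_id) else None
    return mirror_plane_oracle(angles, attachment_angle=attachment)
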