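"""The androecial petaloidy rule: stamen form from next-higher-order bracts.

The inner dorsal androecium member of *Canna* can be fully fertile (two
thecae), half fertile (one theca plus a petaloid appendage) or fully
petaloid (no thecae).  Which form develops is read off the flower's
flanking next-higher-order bracts:

* no flanking bract  -> fully fertile stamen (2 thecae), no appendage;
* one flanking bract -> half-fertile stamen (1 theca); the petaloid
  appendage sits on the half of the dorsal stamen **distal** to the bract,
  the theca on the proximal half;
* two or three flanking bracts (dichasium/trichasium, both lateral sides
  occupied) -> fully petaloid, no thecae.

More than three flanking bracts is outside the observed typology and raises
:class:`OutOfModelError`.
"""

from __future__ import annotations

from .morphology import FloralPhenotype, OrganState
from .symmetry import predict_symmetry_for_flower
from .topology import BractPlacement, FlorescenceNode, MATURE, flanking_bracts
from ._sector import on_grid, unit

_TOL = 1e-9


class OutOfModelError(ValueError):
    """The configuration is outside the 0-3 flanking-bract typology."""


def predict_theca_count(flanking: list[BractPlacement]) -> int:
    """Thecae of the dorsal stamen from the number of flanking bracts (2/1/0)."""
    n = len(flanking)
    if n == 0:
        return 2
    if n == 1:
        return 1
    if n in (2, 3):
        return 0
    raise OutOfModelError(f"{n} flanking bracts: the rule covers 0-3 only")


def appendage_angle(bract: BractPlacement) -> float:
    """Direction of the petaloid appendage: opposite (distal to) the bract."""
    return (bract.angle_deg + 180.0) % 360.0


def side_of_angle(angle_deg: float) -> str:
    """Side label for a direction in the local frame.

    Mediolateral component decides left/right; a direction exactly on the
    dorsoventral axis is labelled adaxial (0) or abaxial (180) instead —
    thyrse-type placements can put the appendage on the dv axis.
    """
    if on_grid(angle_deg):
        v = unit(angle_deg)
        ml = float(v.ml)
        dv = float(v.dv)
    else:
        import math

        ml = math.sin(math.radians(angle_deg))
        dv = math.cos(math.radians(angle_deg))
    if abs(ml) > _TOL:
        return "left" if ml > 0 else "right"
    return "adaxial" if dv > 0 else "abaxial"


def predict_appendage_side(flanking: list[BractPlacement]) -> str:
    """Appendage side for a half-fertile stamen (exactly one flanking bract)."""
    if len(flanking) != 1:
        raise ValueError(
            f"appendage orientation is defined for exactly one flanking bract, got {len(flanking)}"
        )
    return side_of_angle(appendage_angle(flanking[0]))


def predict_flower_phenotype(tree: FlorescenceNode, flower_id: str) -> FloralPhenotype:
    """Full model prediction for one flower: stamen form plus symmetry class.

    Merosity (sepal/petal/locule counts) and style form are observed
    covariates the model does not predict; those fields stay unset.
    """
    node = tree.find(flower_id)
    if node.status != MATURE:
        raise ValueError(f"flower {flower_id!r} is not mature; the model predicts mature flowers")
    flanking = flanking_bracts(tree, flower_id)
    theca = predict_theca_count(flanking)
    symmetry, axis, _ = predict_symmetry_for_flower(tree, flower_id)
    organ_states: list[OrganState] = []
    if theca == 2:
        side = "none"
        organ_states.append(
            OrganState(whorl="inner_androecium", identity="fertile_stamen", state="fertile", position_deg=0.0)
        )
    elif theca == 1:
        side = predict_appendage_side(flanking)
        # the theca develops on the half proximal to the bract
        organ_states.append(
            OrganState(
                whorl="inner_androecium",
                identity="fertile_stamen",
                state="half_fertile",
                position_deg=flanking[0].angle_deg,
            )
        )
        organ_states.append(
            OrganState(
                whorl="inner_androecium",
                identity="stamen_appendage",
                state="petaloid",
                position_deg=appendage_angle(flanking[0]),
            )
        )
    else:
        side = "none"
        organ_states.append(
            OrganState(whorl="inner_androecium", identity="fertile_stamen", state="petaloid", position_deg=0.0)
        )
    return FloralPhenotype(
        theca_count=theca,
        appendage_side=side,
        symmetry=symmetry,
        zygomorphy_axis=axis,
        organ_states=organ_states,
    )


def predict_all(tree: FlorescenceNode) -> dict[str, FloralPhenotype]:
    """Predictions for every mature flower of a tree, keyed by flower id."""
    return {f.id: predict_flower_phenotype(tree, f.id) for f in tree.flowers(status=MATURE)}
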