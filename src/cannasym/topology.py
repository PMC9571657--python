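"""Inflorescence branching trees for *Canna* partial florescences.

A partial florescence (PF) is one lateral unit of the thyrse: the cincinnus
(or aberrant cyme/thyrse) in the axil of a primary bract on the main
florescence axis.  Trees are rooted at a stub of the main axis (kind
``axis``, order 0); flowers are axillary nodes whose ``subtending_bract``
records where the bract sits, and whose children are the proceeding-order
branches (each child's bract is a "next-higher-order bract" of that flower).

Angle convention, used everywhere in the package: bract angles are degrees
in the local transverse frame of the flower they flank — 0 = adaxial
(toward the subtending axis; for thyrse pair members, toward the pair
midline), counter-clockwise positive viewed from the distal pole, so +90 is
the flower's left.  Packaged fixtures and the generator stay on multiples
of 45 degrees, which keeps cancellation arithmetic exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

AXIS = "axis"
FLOWER = "flower"
MATURE = "mature"
ABORTED = "aborted"
SINISTRORSE = "sinistrorse"
DEXTRORSE = "dextrorse"

PF_LABELS = (
    "single_flower",
    "cincinnus",
    "cyme_1f",
    "cyme_2f",
    "cyme_3f",
    "cyme_4f",
    "thyrse_2f",
    "thyrse_3f",
    "thyrse_4f",
)


@dataclass
class BractPlacement:
    """A bract flanking a flower, in that flower's local frame.

    order_index: 1 = primary bract (b), 2 = secondary (sb), 3 = tertiary (tb).
    fused_with: node id whose bract this one is conjoined with (thyrse cases).
    """

    order_index: int
    angle_deg: float
    fused_with: Optional[str] = None


@dataclass
class FlorescenceNode:
    kind: str
    order: int
    subtending_bract: Optional[BractPlacement] = None
    status: str = MATURE
    handedness: Optional[str] = None
    children: list["FlorescenceNode"] = field(default_factory=list)
    id: str = ""

    # -- traversal helpers -------------------------------------------------
    def walk(self) -> Iterator["FlorescenceNode"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def find(self, node_id: str) -> "FlorescenceNode":
        for node in self.walk():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")

    def flowers(self, status: Optional[str] = None) -> list["FlorescenceNode"]:
        return [
            n
            for n in self.walk()
            if n.kind == FLOWER and (status is None or n.status == status)
        ]

    def parent_of(self, node_id: str) -> Optional["FlorescenceNode"]:
        for node in self.walk():
            for child in node.children:
                if child.id == node_id:
                    return node
        return None


@dataclass(frozen=True)
class FloralFrame:
    """Local transverse frame of a flower, in PF plane coordinates.

    dv_axis points adaxially (toward the subtending axis; for thyrse pair
    members, toward the pair midline); ml_axis is orthogonal, positive to
    the flower's left in polar view with adaxial up.  Under dextrorse
    handedness the ml sign flips.
    """

    dv_axis: tuple[float, float]
    ml_axis: tuple[float, float]


@dataclass(frozen=True)
class PFClass:
    label: str
    mature_flower_count: int
    reason: Optional[str] = None  # set only for label == "unclassified"


def assign_ids(tree: FlorescenceNode) -> FlorescenceNode:
    """Assign root-relative child-index path ids ('' for root, '0/1', ...)."""

    def _assign(node: FlorescenceNode, path: str) -> None:
        node.id = path
        for i, child in enumerate(node.children):
            _assign(child, f"{path}/{i}" if path else str(i))

    _assign(tree, "")
    return tree


def validate_tree(tree: FlorescenceNode) -> list[str]:
    """Structural invariant checks; one entry per violation, empty if valid."""
    violations: list[str] = []
    if tree.kind != AXIS:
        violations.append(f"root {tree.id!r}: root must be an axis, got kind={tree.kind!r}")
    if tree.order != 0:
        violations.append(f"root {tree.id!r}: root axis must have order 0, got {tree.order}")

    seen: set[str] = set()
    for node in tree.walk():
        if node.id in seen:
            violations.append(f"node {node.id!r}: duplicate id")
        seen.add(node.id)
        if node.kind not in (AXIS, FLOWER):
            violations.append(f"node {node.id!r}: unknown kind {node.kind!r}")
        if node.status not in (MATURE, ABORTED):
            violations.append(f"node {node.id!r}: unknown status {node.status!r}")
        if node.handedness is not None and node.handedness not in (SINISTRORSE, DEXTRORSE):
            violations.append(f"node {node.id!r}: unknown handedness {node.handedness!r}")
        if node.handedness is not None and node.kind != AXIS:
            violations.append(f"node {node.id!r}: handedness is recorded on axis nodes only")
        bract = node.subtending_bract
        if bract is not None:
            if not 0 <= bract.angle_deg < 360:
                violations.append(
                    f"node {node.id!r}: bract angle {bract.angle_deg} outside [0, 360)"
                )
            if bract.order_index < 1:
                violations.append(f"node {node.id!r}: bract order_index must be >= 1")
        if node.status == ABORTED:
            for desc in node.walk():
                if desc is not node and desc.status == MATURE:
                    violations.append(
                        f"node {desc.id!r}: mature descendant of aborted node {node.id!r}"
                    )
    # order bookkeeping: a bract-subtended flower sits one order above its parent
    for node in tree.walk():
        for child in node.children:
            if child.kind == FLOWER and child.subtending_bract is not None:
                if child.order != node.order + 1:
                    violations.append(
                        f"node {child.id!r}: order {child.order} != parent order {node.order} + 1"
                    )
                if child.subtending_bract.order_index != child.order:
                    violations.append(
                        f"node {child.id!r}: bract order_index "
                        f"{child.subtending_bract.order_index} != flower order {child.order}"
                    )
    return violations


def flanking_bracts(tree: FlorescenceNode, flower_id: str) -> list[BractPlacement]:
    """Next-higher-order bracts in a flower's axil region.

    These are the bracts subtending the flower's proceeding-order branches,
    expressed in the flower's own frame.  Bracts of aborted branches count:
    the bract marks the higher-order meristem whether or not its flower
    matured.  Terminal (childless) flowers return an empty list.
    """
    node = tree.find(flower_id)
    if node.kind != FLOWER:
        raise KeyError(f"{flower_id!r} is not a flower node")
    return [c.subtending_bract for c in node.children if c.subtending_bract is not None]


def is_lateral(tree: FlorescenceNode, flower_id: str) -> bool:
    """A flower is lateral (axillary) iff it has a subtending bract.

    Solitary or top flowers terminate their axis and arise from a vertical
    direction instead, contributing no transverse preceding-order influence.
    """
    return tree.find(flower_id).subtending_bract is not None


def _thyrse_members(tree: FlorescenceNode) -> list[FlorescenceNode]:
    return [c for c in tree.children if c.kind == FLOWER]


def local_frame(tree: FlorescenceNode, flower_id: str) -> FloralFrame:
    """Deterministic local frame of a flower, in PF plane coordinates.

    The PF plane is the transverse plane viewed from the distal pole, with
    the +x direction pointing at the main florescence axis.  The frame only
    fixes how local bract angles relate to the shared plane; the prediction
    rules themselves consume local angles directly.
    """
    node = tree.find(flower_id)
    if node.kind != FLOWER:
        raise KeyError(f"{flower_id!r} is not a flower node")
    hand = tree.handedness or SINISTRORSE
    sign = 1.0 if hand == SINISTRORSE else -1.0

    members = _thyrse_members(tree)
    ancestors = [node]
    parent = tree.parent_of(node.id)
    while parent is not None:
        ancestors.append(parent)
        parent = tree.parent_of(ancestors[-1].id)
    # thyrse pair member (first-order flower directly on the root with >= 2 siblings):
    # dv points toward the pair midline, which lies left of one member and
    # right of the other.
    if len(members) >= 2 and ancestors[-2] in members:
        member = ancestors[-2]
        side = members.index(member)
        toward_mid = (0.0, -1.0) if side == 0 else (0.0, 1.0)
        if ancestors[-2] is node:
            ml = (sign * -toward_mid[1], sign * toward_mid[0])
            return FloralFrame(dv_axis=toward_mid, ml_axis=ml)
        # higher-order flowers within a thyrse member: adaxial toward parent,
        # approximated by the member midline direction rotated per depth parity
        depth = node.order - 1
        flip = -1.0 if depth % 2 else 1.0
        dv = (flip * toward_mid[0], flip * toward_mid[1])
        ml = (sign * -dv[1], sign * dv[0])
        return FloralFrame(dv_axis=dv, ml_axis=ml)

    # cincinnus/cyme flowers: dv toward the subtending axis.  Successive
    # cincinnus orders alternate sides, which flips the effective ml sign.
    depth = node.order - 1  # first-order flower: 0
    flip = -1.0 if depth % 2 else 1.0
    dv = (1.0, 0.0) if flip > 0 else (-1.0, 0.0)
    ml = (0.0, sign * flip)
    return FloralFrame(dv_axis=dv, ml_axis=ml)


def classify_partial_florescence(tree: FlorescenceNode) -> PFClass:
    """Assign the partial-florescence class of the aberrant-flower typology.

    single_flower: one mature flower, no higher-order bract at all.
    cyme_Nf: dichasial/trichasial first order reverting to monochasial,
    N mature flowers in total.  thyrse_Nf: paired first-order flowers under
    conjoined primary bracts, each pair member a 1-2-flowered cincinnus.
    cincinnus: the normal monochasial chain.  Anything else is labelled
    ``unclassified`` with a reason — never a silent default.
    """
    mature = len(tree.flowers(status=MATURE))
    first_order = [c for c in tree.children if c.kind == FLOWER]
    if not first_order:
        return PFClass("unclassified", mature, reason="no first-order flower on the root axis")

    if len(first_order) >= 2:
        if len(first_order) != 2:
            return PFClass(
                "unclassified", mature, reason=f"{len(first_order)} paired first-order flowers"
            )
        if mature not in (2, 3, 4):
            return PFClass(
                "unclassified", mature, reason=f"thyrse with {mature} mature flowers"
            )
        for member in first_order:
            for n in member.walk():
                # aborted children are bract-marked meristems, not branching
                if len([c for c in n.children if c.kind == FLOWER and c.status == MATURE]) > 1:
                    return PFClass(
                        "unclassified", mature, reason=f"thyrse member branches at {n.id!r}"
                    )
        return PFClass(f"thyrse_{mature}f", mature)

    f1 = first_order[0]
    branches = [c for c in f1.children if c.kind == FLOWER]
    if not branches:
        if mature == 1:
            return PFClass("single_flower", 1)
        return PFClass("unclassified", mature, reason="childless first order but >1 mature flower")
    if len(branches) == 1:
        # monochasial throughout -> cincinnus
        node = branches[0]
        while True:
            nxt = [c for c in node.children if c.kind == FLOWER]
            if len(nxt) > 1:
                return PFClass(
                    "unclassified", mature, reason=f"monochasium re-branches at {node.id!r}"
                )
            if not nxt:
                return PFClass("cincinnus", mature)
            node = nxt[0]
    if len(branches) in (2, 3):
        # cyme: must revert to monochasial beyond the first order
        # (only mature children count as branching; aborted ones are meristems)
        for branch in branches:
            for n in branch.walk():
                if len([c for c in n.children if c.kind == FLOWER and c.status == MATURE]) > 1:
                    return PFClass(
                        "unclassified", mature, reason=f"higher order re-branches at {n.id!r}"
                    )
        if not 1 <= mature <= 4:
            return PFClass("unclassified", mature, reason=f"cyme with {mature} mature flowers")
        return PFClass(f"cyme_{mature}f", mature)
    return PFClass(
        "unclassified", mature, reason=f"first-order flower bears {len(branches)} branches"
    )


def mirror(tree: FlorescenceNode) -> FlorescenceNode:
    """Global mediolateral reflection: negate every bract angle, swap handedness."""

    def _mirror(node: FlorescenceNode) -> FlorescenceNode:
        bract = node.subtending_bract
        if bract is not None:
            bract = replace(bract, angle_deg=(360.0 - bract.angle_deg) % 360.0)
        hand = node.handedness
        if hand == SINISTRORSE:
            hand = DEXTRORSE
        elif hand == DEXTRORSE:
            hand = SINISTRORSE
        return FlorescenceNode(
            kind=node.kind,
            order=node.order,
            subtending_bract=bract,
            status=node.status,
            handedness=hand,
            children=[_mirror(c) for c in node.children],
            id=node.id,
        )

    return _mirror(tree)
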