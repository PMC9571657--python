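"""Deterministic SVG sketches of partial florescences and floral diagrams.

Visual conventions follow standard floral-diagram practice: polar view with
the adaxial direction up; flowers as circles, thecae as filled lobes on the
dorsal stamen, the petaloid appendage as an open lobe distal to the flanking
bract, bracts as arcs at their sector positions.  Output is plain SVG built
by string assembly with a fixed viewport and sorted element order, so two
renders of the same record are byte-identical.
"""

from __future__ import annotations

import math

from .fixtures import CollectionRecord
from .morphology import FloralPhenotype
from .topology import FlorescenceNode, MATURE

_W = 640.0
_H = 480.0


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # 0 deg = up (adaxial), counter-clockwise positive in diagram space
    rad = math.radians(angle_deg)
    return cx - r * math.sin(rad), cy - r * math.cos(rad)


def _layout(tree: FlorescenceNode) -> dict[str, tuple[float, float]]:
    """Depth-layered layout: orders stack top-down, siblings spread evenly."""
    positions: dict[str, tuple[float, float]] = {}
    levels: dict[int, list[str]] = {}
    depth_of: dict[str, int] = {}
    for node in tree.walk():
        if node.kind != "flower":
            continue
        depth = node.id.count("/") + 1 if node.id else 0
        depth_of[node.id] = depth
        levels.setdefault(depth, []).append(node.id)
    max_depth = max(levels, default=1)
    for depth, ids in sorted(levels.items()):
        y = 80.0 + (depth - 1) * (320.0 / max(max_depth - 1, 1) if max_depth > 1 else 0.0)
        for i, fid in enumerate(ids):
            x = _W * (i + 1) / (len(ids) + 1)
            positions[fid] = (x, y)
    return positions


def _flower_glyph(cx: float, cy: float, node: FlorescenceNode, phenotype: FloralPhenotype | None) -> list[str]:
    parts = []
    dashed = ' stroke-dasharray="4 3"' if node.status != MATURE else ""
    parts.append(
        f'<circle class="flower" cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="22" '
        f'fill="none" stroke="black"{dashed}/>'
    )
    bract = node.subtending_bract
    if bract is not None:
        bx, by = _polar(cx, cy, 30.0, bract.angle_deg)
        parts.append(
            f'<circle class="bract" cx="{_fmt(bx)}" cy="{_fmt(by)}" r="4" fill="black"/>'
        )
    if phenotype is not None and phenotype.theca_count is not None:
        for organ in sorted(phenotype.organ_states, key=lambda o: (o.whorl, o.identity, o.position_deg)):
            ox, oy = _polar(cx, cy, 14.0, organ.position_deg)
            if organ.identity == "fertile_stamen" and organ.state in ("fertile", "half_fertile"):
                parts.append(
                    f'<circle class="theca" cx="{_fmt(ox)}" cy="{_fmt(oy)}" r="5" fill="black"/>'
                )
            elif organ.identity == "stamen_appendage":
                parts.append(
                    f'<circle class="appendage" cx="{_fmt(ox)}" cy="{_fmt(oy)}" r="5" '
                    f'fill="white" stroke="black"/>'
                )
    return parts


def render_svg(record: CollectionRecord) -> str:
    """SVG scheme of a record: topology links plus per-flower diagrams.

    Records without observations render a topology-only scheme.
    """
    tree = record.topology
    positions = _layout(tree)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{int(_W)}" height="{int(_H)}" '
        f'viewBox="0 0 {int(_W)} {int(_H)}">',
        f'<title>{record.id} ({record.pf_class})</title>',
    ]
    # links parent->child, sorted by child id for stable order
    links = []
    for node in tree.walk():
        if node.kind != "flower" or node.id not in positions:
            continue
        parent = tree.parent_of(node.id)
        if parent is not None and parent.kind == "flower" and parent.id in positions:
            links.append((node.id, parent.id))
    for child_id, parent_id in sorted(links):
        x1, y1 = positions[parent_id]
        x2, y2 = positions[child_id]
        parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="gray"/>'
        )
    for fid in sorted(positions):
        node = tree.find(fid)
        x, y = positions[fid]
        parts.extend(_flower_glyph(x, y, node, record.observed.get(fid)))
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y + 38)}" font-size="10" '
            f'text-anchor="middle">{fid}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
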