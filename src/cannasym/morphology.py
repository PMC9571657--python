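"""Organ-level floral diagrams for observed and predicted *Canna* phenotypes.

The *Canna* flower is trimerous: sepals, petals, two androecial whorls of
three members each (mostly petaloid staminodes; the single fertile stamen is
normally only half fertile, one theca plus a petaloid appendage), and a
trilocular gynoecium with a laminar style.  Floral symmetry is assessed en
face at anthesis: actinomorphic, zygomorphic (one mirror plane, dorsoventral
or mediolateral), asymmetric (none), or — for observed flowers only — an
intermediate stage (one theca with petaloid appendages on both sides).

Angular positions are degrees in the flower's local frame (0 = adaxial,
counter-clockwise positive, +90 = left); fixtures stay on the 45-degree
sector grid, so phenotype equality is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

WHORLS = ("sepal", "petal", "outer_androecium", "inner_androecium", "gynoecium")
IDENTITIES = (
    "sepal",
    "petal",
    "outer_staminode",
    "inner_staminode",
    "labellum",
    "fertile_stamen",
    "stamen_appendage",
    "carpel",
)
ORGAN_STATES = ("developed", "petaloid", "half_fertile", "fertile", "aborted")
SIDES = ("left", "right", "adaxial", "abaxial", "both", "none")
SYMMETRY_CLASSES = ("actinomorphic", "zygomorphic", "asymmetric", "intermediate")
ZYGOMORPHY_AXES = ("dorsoventral", "mediolateral")

_MIRROR_SIDE = {"left": "right", "right": "left"}


@dataclass(frozen=True)
class OrganState:
    whorl: str
    identity: str
    state: str
    position_deg: float

    def __post_init__(self) -> None:
        if self.whorl not in WHORLS:
            raise ValueError(f"unknown whorl {self.whorl!r}")
        if self.identity not in IDENTITIES:
            raise ValueError(f"unknown identity {self.identity!r}")
        if self.state not in ORGAN_STATES:
            raise ValueError(f"unknown organ state {self.state!r}")
        if self.state in ("half_fertile", "fertile") and self.whorl != "inner_androecium":
            raise ValueError(
                f"state {self.state!r} is only legal for inner-androecium members"
            )


@dataclass
class FloralPhenotype:
    """Observed or predicted floral diagram.

    Predicted phenotypes fill only the fields the model speaks to
    (theca_count, appendage_side, symmetry, zygomorphy_axis); merosity
    fields stay None.  theca_count: 0 = no fertile stamen, 1 = half-fertile
    (one theca plus appendage), 2 = symmetrical fully fertile stamen, which
    carries a filamentous filament and no appendage (appendage_side 'none').
    """

    sepal_count: Optional[int] = None
    petal_count: Optional[int] = None
    organ_states: list[OrganState] = field(default_factory=list)
    theca_count: Optional[int] = None
    appendage_side: str = "none"
    locule_count: Optional[int] = None
    style_form: Optional[str] = None  # laminar | filamentous
    symmetry: Optional[str] = None
    zygomorphy_axis: Optional[str] = None

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.theca_count is not None and self.theca_count not in (0, 1, 2):
            problems.append(f"theca_count {self.theca_count} outside {{0,1,2}}")
        if self.appendage_side not in SIDES:
            problems.append(f"unknown appendage_side {self.appendage_side!r}")
        if self.theca_count == 2 and self.appendage_side != "none":
            problems.append("a fully fertile (two-theca) stamen bears no appendage")
        if self.theca_count == 1 and self.appendage_side == "none":
            problems.append("a half-fertile stamen must carry a petaloid appendage")
        if self.style_form is not None and self.style_form not in ("laminar", "filamentous"):
            problems.append(f"unknown style_form {self.style_form!r}")
        if self.symmetry is not None and self.symmetry not in SYMMETRY_CLASSES:
            problems.append(f"unknown symmetry {self.symmetry!r}")
        if self.symmetry == "zygomorphic" and self.zygomorphy_axis is None:
            problems.append("zygomorphic phenotype requires a zygomorphy_axis")
        if self.zygomorphy_axis is not None and self.zygomorphy_axis not in ZYGOMORPHY_AXES:
            problems.append(f"unknown zygomorphy_axis {self.zygomorphy_axis!r}")
        positions: dict[str, set[float]] = {}
        for organ in self.organ_states:
            pool = positions.setdefault(organ.whorl, set())
            key = organ.position_deg % 360.0
            if key in pool:
                problems.append(f"duplicate position {organ.position_deg} in whorl {organ.whorl}")
            pool.add(key)
        return problems


def reflect_phenotype(p: FloralPhenotype) -> FloralPhenotype:
    """Mediolateral reflection: left/right swap, organ positions negated mod 360.

    Counts, states and the zygomorphy axis are preserved; the operation is an
    involution.
    """
    return replace(
        p,
        appendage_side=_MIRROR_SIDE.get(p.appendage_side, p.appendage_side),
        organ_states=[
            replace(o, position_deg=(360.0 - o.position_deg) % 360.0) for o in p.organ_states
        ],
    )


def _organ_key(o: OrganState) -> tuple:
    return (o.whorl, o.identity, o.state, round(o.position_deg % 360.0, 6))


def _equal(a: FloralPhenotype, b: FloralPhenotype, tol_deg: float) -> bool:
    if (
        a.sepal_count != b.sepal_count
        or a.petal_count != b.petal_count
        or a.theca_count != b.theca_count
        or a.appendage_side != b.appendage_side
        or a.locule_count != b.locule_count
        or a.style_form != b.style_form
        or a.symmetry != b.symmetry
        or a.zygomorphy_axis != b.zygomorphy_axis
        or len(a.organ_states) != len(b.organ_states)
    ):
        return False
    remaining = [_organ_key(o) for o in b.organ_states]
    for o in a.organ_states:
        key = _organ_key(o)
        match = next(
            (
                k
                for k in remaining
                if k[:3] == key[:3]
                and min(abs(k[3] - key[3]), 360.0 - abs(k[3] - key[3])) <= tol_deg
            ),
            None,
        )
        if match is None:
            return False
        remaining.remove(match)
    return True


def is_mirror_image(a: FloralPhenotype, b: FloralPhenotype, tol_deg: float = 1e-6) -> bool:
    """True iff the reflection of *a* equals *b* (exact on the sector grid)."""
    return _equal(reflect_phenotype(a), b, tol_deg)


_STYLE_ABBREV = {"laminar": "lam", "filamentous": "fil"}
_SYM_ABBREV = {
    "actinomorphic": "act",
    "zygomorphic": "zyg",
    "asymmetric": "asym",
    "intermediate": "int",
}
_AXIS_ABBREV = {"dorsoventral": "dv", "mediolateral": "ml"}


def floral_formula(p: FloralPhenotype) -> str:
    """Deterministic plain-text formula for the counts and key organ states.

    Example: ``S4 P3 Th0 PA:none G4 Sty:fil Sym:zyg(dv)``.  Fields that are
    unset are omitted; a phenotype with nothing set yields ``(empty)``.
    Round-trippable via :func:`parse_floral_formula` for the fields encoded.
    """
    parts: list[str] = []
    if p.sepal_count is not None:
        parts.append(f"S{p.sepal_count}")
    if p.petal_count is not None:
        parts.append(f"P{p.petal_count}")
    if p.theca_count is not None:
        parts.append(f"Th{p.theca_count}")
        parts.append(f"PA:{p.appendage_side}")
    if p.locule_count is not None:
        parts.append(f"G{p.locule_count}")
    if p.style_form is not None:
        parts.append(f"Sty:{_STYLE_ABBREV[p.style_form]}")
    if p.symmetry is not None:
        sym = _SYM_ABBREV[p.symmetry]
        if p.zygomorphy_axis is not None:
            sym += f"({_AXIS_ABBREV[p.zygomorphy_axis]})"
        parts.append(f"Sym:{sym}")
    return " ".join(parts) if parts else "(empty)"


def parse_floral_formula(text: str) -> FloralPhenotype:
    """Inverse of :func:`floral_formula` for the fields the formula encodes."""
    p = FloralPhenotype()
    if text.strip() == "(empty)":
        return p
    style_rev = {v: k for k, v in _STYLE_ABBREV.items()}
    sym_rev = {v: k for k, v in _SYM_ABBREV.items()}
    axis_rev = {v: k for k, v in _AXIS_ABBREV.items()}
    for token in text.split():
        if token.startswith("S") and token[1:].isdigit():
            p.sepal_count = int(token[1:])
        elif token.startswith("P") and token[1:].isdigit():
            p.petal_count = int(token[1:])
        elif token.startswith("Th"):
            p.theca_count = int(token[2:])
        elif token.startswith("PA:"):
            p.appendage_side = token[3:]
        elif token.startswith("G") and token[1:].isdigit():
            p.locule_count = int(token[1:])
        elif token.startswith("Sty:"):
            p.style_form = style_rev[token[4:]]
        elif token.startswith("Sym:"):
            body = token[4:]
            if "(" in body:
                sym, axis = body[:-1].split("(")
                p.symmetry = sym_rev[sym]
                p.zygomorphy_axis = axis_rev[axis]
            else:
                p.symmetry = sym_rev[body]
        else:
            raise ValueError(f"unrecognized formula token {token!r}")
    return p
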