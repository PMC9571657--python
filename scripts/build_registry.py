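"""One-off dev script: construct the builtin registry and serialize it to
src/cannasym/data/collections/*.fdf.json in canonical FDF form."""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cannasym.fixtures import CollectionRecord, write_collection
from cannasym.morphology import FloralPhenotype, OrganState
from cannasym.topology import (
    ABORTED,
    BractPlacement,
    FlorescenceNode,
    MATURE,
    SINISTRORSE,
    assign_ids,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "cannasym" / "data" / "collections"

CI = "Canna indica"
CG = "Canna glauca"


def bract(order_index, angle, fused=None):
    return BractPlacement(order_index=order_index, angle_deg=float(angle), fused_with=fused)


def flower(order, br=None, status=MATURE, children=()):
    return FlorescenceNode(
        kind="flower", order=order, subtending_bract=br, status=status, children=list(children)
    )


def root(children):
    return assign_ids(
        FlorescenceNode(kind="axis", order=0, handedness=SINISTRORSE, children=list(children))
    )


def organ(whorl, identity, state, pos):
    return OrganState(whorl=whorl, identity=identity, state=state, position_deg=float(pos))


def fs_pa(theca_angle, pa_angle):
    """Half-fertile stamen with theca proximal to the bract, appendage distal."""
    return [
        organ("inner_androecium", "fertile_stamen", "half_fertile", theca_angle),
        organ("inner_androecium", "stamen_appendage", "petaloid", pa_angle),
    ]


def normal_obs(appendage_side, theca_angle, pa_angle):
    return FloralPhenotype(
        sepal_count=3,
        petal_count=3,
        theca_count=1,
        appendage_side=appendage_side,
        locule_count=3,
        style_form="laminar",
        symmetry="asymmetric",
        organ_states=fs_pa(theca_angle, pa_angle),
    )


records: list[CollectionRecord] = []

# --- normal-type cincinni --------------------------------------------------

records.append(
    CollectionRecord(
        id="Ci-normal",
        species=CI,
        pf_class="cincinnus",
        normal=True,
        figures=["3B", "3H", "12B"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180),
                    children=[flower(2, bract(2, 90), status=ABORTED)],
                )
            ]
        ),
        observed={"0": normal_obs("right", 90, 270)},
        annotations={
            "note": "1-flowered sinistrorse cincinnus; the continuation meristem is "
            "marked by its secondary bract on the flower's left",
        },
    )
)

records.append(
    CollectionRecord(
        id="Cg-normal",
        species=CG,
        pf_class="cincinnus",
        normal=True,
        figures=["3E", "3H"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180),
                    children=[
                        flower(
                            2,
                            bract(2, 90),
                            children=[flower(3, bract(3, 270), status=ABORTED)],
                        )
                    ],
                )
            ]
        ),
        observed={
            "0": normal_obs("right", 90, 270),
            "0/0": normal_obs("left", 270, 90),
        },
        annotations={
            "note": "2-flowered sinistrorse cincinnus; successive orders alternate sides, "
            "so the secondary flower shows the mirrored (dextrorse-like) morphology",
        },
    )
)

# --- single flower ---------------------------------------------------------

records.append(
    CollectionRecord(
        id="Ci-1",
        species=CI,
        pf_class="single_flower",
        figures=["4", "12A"],
        topology=root([flower(1, bract(1, 180))]),
        observed={
            "0": FloralPhenotype(
                sepal_count=2,
                petal_count=2,
                theca_count=2,
                appendage_side="none",
                locule_count=2,
                style_form="laminar",
                symmetry="zygomorphic",
                zygomorphy_axis="dorsoventral",
                organ_states=[
                    organ("outer_androecium", "outer_staminode", "petaloid", 60),
                    organ("outer_androecium", "outer_staminode", "petaloid", 180),
                    organ("outer_androecium", "outer_staminode", "petaloid", 300),
                    organ("inner_androecium", "fertile_stamen", "fertile", 0),
                    organ("inner_androecium", "inner_staminode", "petaloid", 120),
                    organ("inner_androecium", "inner_staminode", "petaloid", 240),
                ],
            )
        },
        annotations={
            "style": "only slightly laminar",
            "counts": "2 sepals, 2 petals, 3 outer + 2 inner petaloid staminodes, "
            "a dorsal fertile stamen with two thecae and a filamentous filament, 2 carpels",
        },
    )
)

# --- 1-flowered cymes ------------------------------------------------------


def one_flowered_cyme(cid, sb_angles, sepals, petals, interp):
    return CollectionRecord(
        id=cid,
        species=CI,
        pf_class="cyme_1f",
        figures=["5A", "5B", "5E", "12D"] if cid == "Ci-2" else ["5C", "5D", "5E", "12D"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180),
                    children=[
                        flower(2, bract(2, sb_angles[0]), status=ABORTED),
                        flower(2, bract(2, sb_angles[1]), status=ABORTED),
                    ],
                )
            ]
        ),
        observed={
            "0": FloralPhenotype(
                sepal_count=sepals,
                petal_count=petals,
                theca_count=0,
                appendage_side="none",
                locule_count=4,
                style_form="filamentous",
                symmetry="zygomorphic",
                zygomorphy_axis="dorsoventral",
                organ_states=[
                    organ("outer_androecium", "outer_staminode", "petaloid", 60),
                    organ("outer_androecium", "outer_staminode", "petaloid", 180),
                    organ("outer_androecium", "outer_staminode", "petaloid", 300),
                    organ("inner_androecium", "fertile_stamen", "petaloid", 0),
                    organ("inner_androecium", "inner_staminode", "petaloid", 120),
                    organ("inner_androecium", "inner_staminode", "petaloid", 240),
                ],
            )
        },
        annotations={
            "interpretive": interp,
            "counts": "six petaloid staminodes dominate the display; 4-locular ovary",
        },
    )


records.append(
    one_flowered_cyme(
        "Ci-2",
        (135, 225),
        4,
        3,
        "secondary bracts placed 'more abaxial': transcribed at the abaxial-lateral "
        "sector (135/225 degrees)",
    )
)
records.append(
    one_flowered_cyme(
        "Ci-3",
        (45, 315),
        4,
        4,
        "secondary bracts placed 'more adaxial': transcribed at the adaxial-lateral "
        "sector (45/315 degrees)",
    )
)

# --- 2-flowered cyme -------------------------------------------------------

records.append(
    CollectionRecord(
        id="Ci-4",
        species=CI,
        pf_class="cyme_2f",
        figures=["6", "12E"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180),
                    children=[
                        flower(2, bract(2, 90), status=ABORTED),
                        flower(
                            2,
                            bract(2, 270),
                            children=[flower(3, bract(3, 225), status=ABORTED)],
                        ),
                    ],
                )
            ]
        ),
        observed={
            "0": FloralPhenotype(
                sepal_count=2,
                petal_count=2,
                theca_count=0,
                appendage_side="none",
                locule_count=4,
                style_form="filamentous",
                symmetry="zygomorphic",
                zygomorphy_axis="dorsoventral",
                organ_states=[
                    organ("outer_androecium", "outer_staminode", "petaloid", 0),
                    organ("outer_androecium", "outer_staminode", "petaloid", 90),
                    organ("outer_androecium", "outer_staminode", "petaloid", 180),
                    organ("outer_androecium", "outer_staminode", "petaloid", 270),
                ],
            ),
            "0/1": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="left",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(225, 45),
            ),
        },
        annotations={
            "staminodes": "one whorl of four petaloid staminodes; both lateral ones "
            "curved and spotted like labella; the adaxial one fully developed and bifid",
            "interpretive": "the figure-view 'left abaxial' tertiary bract of the "
            "secondary flower maps to 225 degrees in that flower's own (rotated) frame",
            "secondary": "secondary flower has the normal mirrored (dextrorse-like) morphology",
        },
    )
)

# --- 3-flowered cymes ------------------------------------------------------


def cyme3_topology():
    return root(
        [
            flower(
                1,
                bract(1, 180),
                children=[
                    flower(
                        2,
                        bract(2, 90),
                        children=[flower(3, bract(3, 225), status=ABORTED)],
                    ),
                    flower(
                        2,
                        bract(2, 270),
                        children=[flower(3, bract(3, 135), status=ABORTED)],
                    ),
                ],
            )
        ]
    )


def f2_pair():
    """Mirror-image lateral secondary flowers with normal morphology."""
    left = FloralPhenotype(
        sepal_count=3,
        petal_count=3,
        theca_count=1,
        appendage_side="left",
        locule_count=3,
        style_form="laminar",
        symmetry="asymmetric",
        organ_states=fs_pa(225, 45),
    )
    right = FloralPhenotype(
        sepal_count=3,
        petal_count=3,
        theca_count=1,
        appendage_side="right",
        locule_count=3,
        style_form="laminar",
        symmetry="asymmetric",
        organ_states=fs_pa(135, 315),
    )
    return left, right


def cyme3(cid, species, figures, f1, annotations, rule_exceptions=None):
    f2l, f2r = f2_pair()
    return CollectionRecord(
        id=cid,
        species=species,
        pf_class="cyme_3f",
        figures=figures,
        topology=cyme3_topology(),
        observed={"0": f1, "0/0": f2l, "0/1": f2r},
        annotations=annotations,
        rule_exceptions=rule_exceptions or {},
    )


def cyme3_f1_petaloid(sepals=4, petals=4, style="filamentous"):
    return FloralPhenotype(
        sepal_count=sepals,
        petal_count=petals,
        theca_count=0,
        appendage_side="none",
        locule_count=4,
        style_form=style,
        symmetry="zygomorphic",
        zygomorphy_axis="dorsoventral",
    )


def cyme3_f1_intermediate(sepals, petals):
    return FloralPhenotype(
        sepal_count=sepals,
        petal_count=petals,
        theca_count=1,
        appendage_side="both",
        locule_count=4,
        style_form="laminar",
        symmetry="intermediate",
        organ_states=[
            organ("inner_androecium", "fertile_stamen", "half_fertile", 0),
            organ("inner_androecium", "stamen_appendage", "petaloid", 90),
            organ("inner_androecium", "stamen_appendage", "petaloid", 270),
        ],
    )


def cyme3_f1_halffertile(style):
    return FloralPhenotype(
        sepal_count=4,
        petal_count=4,
        theca_count=1,
        appendage_side="right",
        locule_count=4,
        style_form=style,
        symmetry="asymmetric",
        organ_states=fs_pa(90, 270),
    )


records.append(
    cyme3(
        "Ci-5",
        CI,
        ["7A", "7B", "7O", "12F"],
        cyme3_f1_petaloid(),
        {"f1": "dorsal stamen fully petaloid; zygomorphic"},
    )
)
records.append(
    cyme3(
        "Cg-1",
        CG,
        ["7C", "7D", "7O"],
        cyme3_f1_petaloid(),
        {"f1": "dorsal stamen fully petaloid; zygomorphic"},
    )
)
records.append(
    cyme3(
        "Cg-2",
        CG,
        ["7E", "7F", "7O"],
        cyme3_f1_intermediate(4, 4),
        {
            "f1": "dorsal stamen with one theca and petaloid appendages on both sides: "
            "a transition stage, not fully zygomorphic",
        },
    )
)
records.append(
    cyme3(
        "Cg-3",
        CG,
        ["7G", "7H", "7O"],
        cyme3_f1_intermediate(3, 3),
        {
            "f1": "as Cg-2 but with the normal 3+3 perianth",
        },
    )
)
records.append(
    cyme3(
        "Cg-4",
        CG,
        ["7I", "7J", "7O"],
        cyme3_f1_halffertile("filamentous"),
        {
            "f1": "half-fertile dorsal stamen; asymmetric as in normal flowers",
            "interpretive": "appendage side of the primary flower transcribed as the "
            "sinistrorse-consistent side (right)",
            "timing": "deviation attributed to delayed emergence of one secondary branch",
        },
    )
)
records.append(
    cyme3(
        "Cg-5",
        CG,
        ["7K", "7L", "7O"],
        cyme3_f1_halffertile("laminar"),
        {
            "f1": "half-fertile dorsal stamen; asymmetric as in normal flowers",
            "interpretive": "appendage side of the primary flower transcribed as the "
            "sinistrorse-consistent side (right)",
            "timing": "deviation attributed to delayed emergence of one secondary branch",
        },
    )
)
records.append(
    cyme3(
        "Cg-6",
        CG,
        ["7M", "7N", "7O"],
        cyme3_f1_halffertile("laminar"),
        {
            "f1": "half-fertile dorsal stamen; asymmetric as in normal flowers",
            "interpretive": "appendage side of the primary flower transcribed as the "
            "sinistrorse-consistent side (right)",
            "timing": "deviation attributed to delayed emergence of one secondary branch",
            "supernumerary": "in the left secondary flower the inner left petaloid "
            "staminode transforms to a second, typical-looking fertile stamen",
        },
        rule_exceptions={"0/0": True},
    )
)

# --- 4-flowered cyme -------------------------------------------------------

records.append(
    CollectionRecord(
        id="Cg-7",
        species=CG,
        pf_class="cyme_4f",
        figures=["8", "12G"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180),
                    children=[
                        flower(
                            2,
                            bract(2, 90),
                            children=[flower(3, bract(3, 225), status=ABORTED)],
                        ),
                        flower(
                            2,
                            bract(2, 270),
                            children=[flower(3, bract(3, 135), status=ABORTED)],
                        ),
                        flower(
                            2,
                            bract(2, 180),
                            children=[flower(3, bract(3, 90), status=ABORTED)],
                        ),
                    ],
                )
            ]
        ),
        observed={
            "0": FloralPhenotype(
                sepal_count=5,
                petal_count=3,
                theca_count=0,
                appendage_side="none",
                locule_count=4,
                style_form="filamentous",
                symmetry="zygomorphic",
                zygomorphy_axis="dorsoventral",
                organ_states=[
                    organ("outer_androecium", "outer_staminode", "petaloid", 60),
                    organ("outer_androecium", "outer_staminode", "petaloid", 180),
                    organ("outer_androecium", "outer_staminode", "petaloid", 300),
                    organ("inner_androecium", "fertile_stamen", "petaloid", 0),
                    organ("inner_androecium", "inner_staminode", "petaloid", 120),
                    organ("inner_androecium", "inner_staminode", "petaloid", 240),
                ],
            ),
            "0/0": f2_pair()[0],
            "0/1": f2_pair()[1],
            "0/2": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="right",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(90, 270),
            ),
        },
        annotations={
            "f1": "six petaloid staminodes, the outer abaxial one very small; ovary "
            "zygomorphic (two adaxial locules larger); style symmetrical and filamentous",
            "secondaries": "three secondary flowers (left, right, abaxial) with normal "
            "wild-type structure; third-order flowers all aborted with tertiary bracts present",
        },
    )
)

# --- thyrses ---------------------------------------------------------------


def thyrse_member_obs(side):
    """Thyrse primary flower: half-fertile stamen, anther adjacent to the midline."""
    if side == "left":  # member 0: bract at 45 -> appendage at 225 -> own-frame right
        return FloralPhenotype(
            theca_count=1,
            appendage_side="right",
            locule_count=3,
            style_form="laminar",
            symmetry="asymmetric",
            organ_states=fs_pa(45, 225),
        )
    return FloralPhenotype(
        theca_count=1,
        appendage_side="left",
        locule_count=3,
        style_form="laminar",
        symmetry="asymmetric",
        organ_states=fs_pa(315, 135),
    )


records.append(
    CollectionRecord(
        id="Ci-6",
        species=CI,
        pf_class="thyrse_2f",
        figures=["9", "12H"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180, fused="1"),
                    children=[flower(2, bract(2, 45, fused="1/0"), status=ABORTED)],
                ),
                flower(
                    1,
                    bract(1, 180, fused="0"),
                    children=[flower(2, bract(2, 315, fused="0/0"), status=ABORTED)],
                ),
            ]
        ),
        observed={"0": thyrse_member_obs("left"), "1": thyrse_member_obs("right")},
        annotations={
            "shared_sepal_count": 4,
            "shared_petal_count": 7,
            "complex": "conjoined flower pair under two fused primary bracts; the two "
            "adaxial petals fused; seven petaloid staminodes of which two are labella; "
            "two trilocular ovaries fused, styles separate and laminar",
            "stamens": "anthers (one theca each) on the abaxial side of the floral "
            "pair, petaloid appendages on the adaxial side relative to the main axis "
            "— i.e. thecae proximal and appendages distal to the fused secondary bracts",
            "interpretive": "secondary bracts transcribed at the midline-ward diagonal "
            "(45/315 degrees in the member frames, where 0 points at the pair midline)",
        },
    )
)

records.append(
    CollectionRecord(
        id="Ci-7",
        species=CI,
        pf_class="thyrse_3f",
        figures=["10", "12I"],
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180, fused="1"),
                    children=[
                        flower(
                            2,
                            bract(2, 45, fused="1/0"),
                            children=[
                                flower(3, bract(3, 90), status=ABORTED),
                                flower(3, bract(3, 270), status=ABORTED),
                            ],
                        )
                    ],
                ),
                flower(
                    1,
                    bract(1, 180, fused="0"),
                    children=[flower(2, bract(2, 315, fused="0/0"), status=ABORTED)],
                ),
            ]
        ),
        observed={
            "0": thyrse_member_obs("left"),
            "1": thyrse_member_obs("right"),
            "0/0": FloralPhenotype(
                sepal_count=4,
                petal_count=4,
                theca_count=0,
                appendage_side="none",
                locule_count=4,
                style_form="filamentous",
                symmetry="zygomorphic",
                zygomorphy_axis="dorsoventral",
                organ_states=[
                    organ("outer_androecium", "outer_staminode", "petaloid", 60),
                    organ("outer_androecium", "outer_staminode", "petaloid", 300),
                    organ("inner_androecium", "fertile_stamen", "petaloid", 0),
                    organ("inner_androecium", "labellum", "petaloid", 120),
                    organ("inner_androecium", "labellum", "petaloid", 240),
                ],
            ),
        },
        annotations={
            "pair": "primary flowers asymmetric, mirror images; fertile stamens "
            "adjacent to the pair midline",
            "f2": "the single secondary flower sits under the two fused secondary "
            "bracts and bears two lateral tertiary bracts; zygomorphic, five petaloid "
            "staminodes including two lateral labella; style symmetric, filamentous",
            "interpretive": "the fused secondary-bract pair is encoded as one bract on "
            "each member (45/315 degrees), the left member's subtending the secondary flower",
        },
    )
)


def thyrse4(cid, species, figures):
    return CollectionRecord(
        id=cid,
        species=species,
        pf_class="thyrse_4f",
        figures=figures,
        topology=root(
            [
                flower(
                    1,
                    bract(1, 180, fused="1"),
                    children=[
                        flower(
                            2,
                            bract(2, 45, fused="1/0"),
                            children=[flower(3, bract(3, 225), status=ABORTED)],
                        )
                    ],
                ),
                flower(
                    1,
                    bract(1, 180, fused="0"),
                    children=[
                        flower(
                            2,
                            bract(2, 315, fused="0/0"),
                            children=[flower(3, bract(3, 135), status=ABORTED)],
                        )
                    ],
                ),
            ]
        ),
        observed={
            "0": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="right",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(45, 225),
            ),
            "1": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="left",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(315, 135),
            ),
            "0/0": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="left",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(225, 45),
            ),
            "1/0": FloralPhenotype(
                sepal_count=3,
                petal_count=3,
                theca_count=1,
                appendage_side="right",
                locule_count=3,
                style_form="laminar",
                symmetry="asymmetric",
                organ_states=fs_pa(135, 315),
            ),
        },
        annotations={
            "structure": "two opposite 2-flowered cincinni under fused primary bracts; "
            "the two secondary bracts fused; tertiary bracts on the abaxial sides of the "
            "secondary flowers; all four flowers asymmetric with normal half-fertile "
            "stamens, each fertile stamen adjacent to the midline",
            "interpretive": "tertiary bracts transcribed at the abaxial-lateral diagonal "
            "(225/135 degrees) in the secondary flowers' own frames",
        },
    )


records.append(thyrse4("Ci-8", CI, ["11A", "11C", "11D", "12J"]))
records.append(thyrse4("Cg-8", CG, ["11B", "11C", "11D", "12J"]))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for record in records:
        problems = record.validate()
        if problems:
            raise SystemExit(f"{record.id}: " + "; ".join(problems))
        path = OUT / f"{record.id}.fdf.json"
        path.write_text(write_collection(record), encoding="utf-8")
        print(f"wrote {path.name}")
    print(f"{len(records)} records")


if __name__ == "__main__":
    main()
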