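"""Branching-tree model: validation, classification, bracts, frames, mirror."""

import pytest
from hypothesis import given, settings, strategies as st

from cannasym.synthetic import GeneratorConfig, generate_topology
from cannasym.topology import (
    BractPlacement,
    FlorescenceNode,
    assign_ids,
    classify_partial_florescence,
    flanking_bracts,
    local_frame,
    mirror,
    validate_tree,
)

from conftest import make_tree


class TestValidateTree:
    def test_builtin_trees_are_valid(self, builtin_records):
        for record in builtin_records:
            assert validate_tree(record.topology) == [], record.id

    def test_flower_root_is_a_violation(self):
        tree = assign_ids(FlorescenceNode(kind="flower", order=0))
        violations = validate_tree(tree)
        assert any("root" in v and "axis" in v for v in violations)

    def test_duplicate_ids_reported_per_duplicate(self):
        tree = make_tree([90.0, 270.0])
        for child in tree.find("0").children:
            child.id = "0/0"
        assert sum("duplicate id" in v for v in validate_tree(tree)) == 1

    def test_mature_descendant_of_aborted_node(self):
        tree = make_tree([90.0])
        tree.find("0").status = "aborted"
        assert any("mature descendant" in v for v in validate_tree(tree))

    def test_bract_angle_range(self):
        tree = make_tree([400.0])
        assert any("outside [0, 360)" in v for v in validate_tree(tree))

    def test_order_must_increment_under_a_bract(self):
        tree = make_tree([90.0])
        tree.find("0/0").order = 5
        assert any("order" in v for v in validate_tree(tree))


class TestClassify:
    @pytest.mark.parametrize(
        "cid,label",
        [
            ("Ci-1", "single_flower"),
            ("Ci-2", "cyme_1f"),
            ("Ci-3", "cyme_1f"),
            ("Ci-4", "cyme_2f"),
            ("Ci-5", "cyme_3f"),
            ("Cg-7", "cyme_4f"),
            ("Ci-6", "thyrse_2f"),
            ("Ci-7", "thyrse_3f"),
            ("Ci-8", "thyrse_4f"),
            ("Cg-8", "thyrse_4f"),
            ("Ci-normal", "cincinnus"),
            ("Cg-normal", "cincinnus"),
        ],
    )
    def test_registry_labels(self, by_id, cid, label):
        pf = classify_partial_florescence(by_id[cid].topology)
        assert pf.label == label
        assert pf.mature_flower_count == len(by_id[cid].topology.flowers(status="mature"))

    def test_unclassifiable_is_explicit_never_silent(self):
        # three paired first-order flowers is outside the typology
        root = FlorescenceNode(kind="axis", order=0)
        root.children = [
            FlorescenceNode(
                kind="flower", order=1, subtending_bract=BractPlacement(1, 180.0)
            )
            for _ in range(3)
        ]
        pf = classify_partial_florescence(assign_ids(root))
        assert pf.label == "unclassified"
        assert pf.reason

    @settings(max_examples=300, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_total_on_generator_output(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        assert classify_partial_florescence(tree).label != "unclassified"


class TestFlankingBracts:
    def test_single_flower_has_none(self, by_id):
        assert flanking_bracts(by_id["Ci-1"].topology, "0") == []

    def test_dichasial_primary_has_two_lateral(self, by_id):
        bracts = flanking_bracts(by_id["Ci-4"].topology, "0")
        assert sorted(b.angle_deg for b in bracts) == [90.0, 270.0]

    def test_trichasial_primary_has_three(self, by_id):
        bracts = flanking_bracts(by_id["Cg-7"].topology, "0")
        assert sorted(b.angle_deg for b in bracts) == [90.0, 180.0, 270.0]

    def test_unknown_id_raises(self, by_id):
        with pytest.raises(KeyError):
            flanking_bracts(by_id["Ci-1"].topology, "9/9")

    @settings(max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_terminal_mature_flowers_have_no_flanking(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        for flower in tree.flowers(status="mature"):
            if not flower.children:
                assert flanking_bracts(tree, flower.id) == []


class TestLocalFrame:
    def test_primary_flower_faces_main_axis(self, by_id):
        frame = local_frame(by_id["Ci-normal"].topology, "0")
        assert frame.dv_axis == (1.0, 0.0)
        assert frame.ml_axis == (0.0, 1.0)

    def test_dextrorse_flips_ml_sign(self, by_id):
        tree = mirror(by_id["Ci-normal"].topology)
        frame = local_frame(tree, "0")
        assert frame.dv_axis == (1.0, 0.0)
        assert frame.ml_axis == (0.0, -1.0)

    def test_thyrse_members_face_the_pair_midline(self, by_id):
        tree = by_id["Ci-7"].topology
        left = local_frame(tree, "0")
        right = local_frame(tree, "1")
        # opposite dv directions, both perpendicular to the main-axis direction
        assert left.dv_axis == (0.0, -1.0)
        assert right.dv_axis == (0.0, 1.0)

    def test_deterministic(self, by_id):
        tree = by_id["Cg-8"].topology
        assert local_frame(tree, "0/0") == local_frame(tree, "0/0")


class TestMirror:
    @settings(max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_mirror_preserves_class_and_bract_counts(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        mirrored = mirror(tree)
        assert (
            classify_partial_florescence(tree).label
            == classify_partial_florescence(mirrored).label
        )
        for flower in tree.flowers():
            assert len(flanking_bracts(tree, flower.id)) == len(
                flanking_bracts(mirrored, flower.id)
            )

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_mirror_negates_bract_angles_and_is_involutive(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        mirrored = mirror(tree)
        for node, mnode in zip(tree.walk(), mirrored.walk()):
            if node.subtending_bract is not None:
                assert mnode.subtending_bract.angle_deg == pytest.approx(
                    (360.0 - node.subtending_bract.angle_deg) % 360.0
                )
        back = mirror(mirrored)
        for node, bnode in zip(tree.walk(), back.walk()):
            if node.subtending_bract is not None:
                assert bnode.subtending_bract.angle_deg == pytest.approx(
                    node.subtending_bract.angle_deg % 360.0
                )
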