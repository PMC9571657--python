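"""AF vector model and its brute-force mirror-plane verification oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from cannasym.symmetry import (
    af1,
    af2,
    mirror_plane_oracle,
    oracle_for_flower,
    predict_symmetry,
    predict_symmetry_for_flower,
    sum_af,
)
from cannasym.synthetic import GeneratorConfig, generate_topology
from cannasym.topology import mirror

from conftest import make_tree


class TestAF1:
    def test_zero_for_solitary_or_top_flower(self):
        v = af1(make_tree([], lateral=False), "0")
        assert (v.dv, v.ml) == (0.0, 0.0)

    def test_unit_adaxial_for_lateral_flower(self):
        v = af1(make_tree([]), "0")
        assert (v.dv, v.ml) == (1.0, 0.0)

    def test_unaffected_by_handedness_mirror(self):
        tree = make_tree([90.0])
        assert af1(tree, "0") == af1(mirror(tree), "0")


class TestAF2:
    def test_zero_without_proceeding_order(self):
        v = af2(make_tree([]), "0")
        assert (v.dv, v.ml) == (0.0, 0.0)

    def test_unit_mediolateral_for_monochasium(self):
        v = af2(make_tree([90.0]), "0")
        assert v.dv == pytest.approx(0.0)
        assert v.ml == pytest.approx(1.0)

    def test_opposite_dichasium_cancels_exactly(self):
        v = af2(make_tree([90.0, 270.0]), "0")
        assert (v.dv, v.ml) == (0.0, 0.0)

    def test_diagonal_dichasium_resolves_to_the_dv_axis(self):
        v = af2(make_tree([135.0, 225.0]), "0")
        assert v.dv == pytest.approx(-1.0)
        assert v.ml == 0.0

    def test_aborted_branch_bracts_still_count(self):
        v = af2(make_tree([90.0], statuses=["aborted"]), "0")
        assert v.ml == pytest.approx(1.0)


class TestSumAFWorkedExamples:
    """The four printed configurations of the explanatory model."""

    @pytest.mark.parametrize(
        "lateral,branches,expected_sum,expected_class,expected_axis",
        [
            (False, [], 0, "actinomorphic", None),  # solitary / top flower
            (True, [], 1, "zygomorphic", "dorsoventral"),  # lateral single
            (True, [90.0], 2, "asymmetric", None),  # lateral monochasium
            (True, [90.0, 270.0], 1, "zygomorphic", "dorsoventral"),  # lateral dichasium
        ],
    )
    def test_printed_cases(self, lateral, branches, expected_sum, expected_class, expected_axis):
        tree = make_tree(branches, lateral=lateral)
        cls, axis, s = predict_symmetry_for_flower(tree, "0")
        assert s.value == expected_sum
        assert cls == expected_class
        assert axis == expected_axis

    def test_collinear_factors_count_their_shared_axis_once(self):
        # trichasium: net proceeding influence is abaxial, collinear with AF1;
        # the dv axis is loaded once -> zygomorphic, not actinomorphic
        tree = make_tree([90.0, 270.0, 180.0])
        cls, axis, s = predict_symmetry_for_flower(tree, "0")
        assert s.value == 1
        assert (cls, axis) == ("zygomorphic", "dorsoventral")
        assert s.net.dv == pytest.approx(0.0)  # signed components cancel in the net

    def test_sum_af_reports_componentwise_net(self):
        tree = make_tree([90.0])
        s = sum_af(af1(tree, "0"), af2(tree, "0"))
        assert (s.net.dv, s.net.ml) == (1.0, 1.0)
        assert s.loaded_axes == {"dorsoventral", "mediolateral"}


class TestOracle:
    def test_no_influences_is_actinomorphic(self):
        assert mirror_plane_oracle([]) == "actinomorphic"

    def test_single_abaxial_influence_is_zygomorphic(self):
        assert mirror_plane_oracle([180.0]) == "zygomorphic"

    def test_perpendicular_unbalanced_influences_are_asymmetric(self):
        assert mirror_plane_oracle([180.0, 90.0]) == "asymmetric"

    def test_balanced_opposite_pair_without_attachment_is_actinomorphic(self):
        assert mirror_plane_oracle([90.0, 270.0]) == "actinomorphic"

    def test_attachment_and_branch_are_distinct_influence_kinds(self):
        # abaxial branch opposite an adaxial attachment: the dv mirror
        # survives, the ml mirror would have to map one kind onto the other
        assert mirror_plane_oracle([180.0], attachment_angle=0.0) == "zygomorphic"


class TestOracleEquivalence:
    @settings(max_examples=400, derandomize=True)
    @given(seed=st.integers(0, 10**7))
    def test_model_matches_oracle_on_generated_trees(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        for flower in tree.flowers(status="mature"):
            cls, _, _ = predict_symmetry_for_flower(tree, flower.id)
            assert cls == oracle_for_flower(tree, flower.id), flower.id


class TestInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_symmetry_class_invariant_under_global_reflection(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        mirrored = mirror(tree)
        for flower in tree.flowers(status="mature"):
            assert (
                predict_symmetry_for_flower(tree, flower.id)[0]
                == predict_symmetry_for_flower(mirrored, flower.id)[0]
            )

    @settings(max_examples=200, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_removing_proceeding_branches_never_increases_sum(self, seed):
        tree = generate_topology(GeneratorConfig(seed=seed))
        for flower in tree.flowers(status="mature"):
            _, _, full = predict_symmetry_for_flower(tree, flower.id)
            pruned_children, flower.children = flower.children, []
            _, _, pruned = predict_symmetry_for_flower(tree, flower.id)
            flower.children = pruned_children
            assert pruned.value <= full.value
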