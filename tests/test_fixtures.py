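"""Builtin registry: sizes, labels, transcription counts, FDF round trips."""

import json

import pytest

from cannasym.fixtures import (
    COLLECTION_IDS,
    FDFError,
    load_collections,
    read_collection,
    record_to_document,
    write_collection,
)

CI = "Canna indica"
CG = "Canna glauca"


class TestRegistry:
    def test_sixteen_aberrant_records(self, aberrant_records):
        assert len(aberrant_records) == 16

    def test_eight_per_species(self, aberrant_records):
        assert sum(r.species == CI for r in aberrant_records) == 8
        assert sum(r.species == CG for r in aberrant_records) == 8

    def test_species_filter(self):
        records = load_collections("builtin", species=CG, include_normal=False)
        assert len(records) == 8
        assert all(r.species == CG for r in records)

    def test_two_normal_records_one_per_species(self, builtin_records):
        normals = [r for r in builtin_records if r.normal]
        assert sorted(r.id for r in normals) == ["Cg-normal", "Ci-normal"]
        assert {r.species for r in normals} == {CI, CG}

    def test_unique_ids(self, builtin_records):
        ids = [r.id for r in builtin_records]
        assert len(set(ids)) == len(ids) == len(COLLECTION_IDS)

    @pytest.mark.parametrize(
        "cid,pf_class",
        [
            ("Ci-1", "single_flower"),
            ("Ci-2", "cyme_1f"),
            ("Ci-3", "cyme_1f"),
            ("Ci-4", "cyme_2f"),
            ("Ci-5", "cyme_3f"),
            ("Cg-1", "cyme_3f"),
            ("Cg-2", "cyme_3f"),
            ("Cg-3", "cyme_3f"),
            ("Cg-4", "cyme_3f"),
            ("Cg-5", "cyme_3f"),
            ("Cg-6", "cyme_3f"),
            ("Cg-7", "cyme_4f"),
            ("Ci-6", "thyrse_2f"),
            ("Ci-7", "thyrse_3f"),
            ("Ci-8", "thyrse_4f"),
            ("Cg-8", "thyrse_4f"),
        ],
    )
    def test_registry_table_labels(self, by_id, cid, pf_class):
        assert by_id[cid].pf_class == pf_class

    def test_figure_cross_references_complete(self, builtin_records):
        for record in builtin_records:
            assert record.figures, record.id


class TestTranscribedCounts:
    """Each described organ count of the aberrant collections, pinned."""

    @pytest.mark.parametrize(
        "cid,fid,sepals,petals,locules,style",
        [
            # single flower: dimerous perianth, two carpels
            ("Ci-1", "0", 2, 2, 2, "laminar"),
            # 1-flowered cymes: 4+3 vs 4+4, four locules, filamentous style
            ("Ci-2", "0", 4, 3, 4, "filamentous"),
            ("Ci-3", "0", 4, 4, 4, "filamentous"),
            # 2-flowered cyme: dimerous primary, normal secondary
            ("Ci-4", "0", 2, 2, 4, "filamentous"),
            ("Ci-4", "0/1", 3, 3, 3, "laminar"),
            # 3-flowered cymes: tetramerous except Cg-3; carpels always four
            ("Ci-5", "0", 4, 4, 4, "filamentous"),
            ("Cg-1", "0", 4, 4, 4, "filamentous"),
            ("Cg-2", "0", 4, 4, 4, "laminar"),
            ("Cg-3", "0", 3, 3, 4, "laminar"),
            ("Cg-4", "0", 4, 4, 4, "filamentous"),
            ("Cg-5", "0", 4, 4, 4, "laminar"),
            ("Cg-6", "0", 4, 4, 4, "laminar"),
            # 4-flowered cyme: five sepals, three petals
            ("Cg-7", "0", 5, 3, 4, "filamentous"),
            # 3-flowered thyrse secondary flower
            ("Ci-7", "0/0", 4, 4, 4, "filamentous"),
        ],
    )
    def test_perianth_and_gynoecium_counts(self, by_id, cid, fid, sepals, petals, locules, style):
        p = by_id[cid].observed[fid]
        assert p.sepal_count == sepals
        assert p.petal_count == petals
        assert p.locule_count == locules
        assert p.style_form == style

    @pytest.mark.parametrize(
        "cid,fid,theca,side,symmetry",
        [
            ("Ci-1", "0", 2, "none", "zygomorphic"),
            ("Ci-2", "0", 0, "none", "zygomorphic"),
            ("Ci-5", "0", 0, "none", "zygomorphic"),
            ("Cg-2", "0", 1, "both", "intermediate"),
            ("Cg-3", "0", 1, "both", "intermediate"),
            ("Cg-4", "0", 1, "right", "asymmetric"),
            ("Cg-7", "0", 0, "none", "zygomorphic"),
            ("Ci-6", "0", 1, "right", "asymmetric"),
            ("Ci-7", "0/0", 0, "none", "zygomorphic"),
            ("Ci-8", "0", 1, "right", "asymmetric"),
        ],
    )
    def test_stamen_form_and_symmetry(self, by_id, cid, fid, theca, side, symmetry):
        p = by_id[cid].observed[fid]
        assert p.theca_count == theca
        assert p.appendage_side == side
        assert p.symmetry == symmetry

    def test_one_flowered_cyme_six_petaloid_staminodes(self, by_id):
        for cid in ("Ci-2", "Ci-3"):
            petaloid = [
                o
                for o in by_id[cid].observed["0"].organ_states
                if o.state == "petaloid"
                and o.whorl in ("outer_androecium", "inner_androecium")
            ]
            assert len(petaloid) == 6

    def test_ci4_primary_one_whorl_of_four_petaloid_staminodes(self, by_id):
        organs = by_id["Ci-4"].observed["0"].organ_states
        assert len(organs) == 4
        assert all(o.state == "petaloid" for o in organs)

    def test_ci7_secondary_five_staminodes_with_two_labella(self, by_id):
        organs = by_id["Ci-7"].observed["0/0"].organ_states
        assert len([o for o in organs if o.state == "petaloid"]) == 5
        assert len([o for o in organs if o.identity == "labellum"]) == 2

    def test_ci6_shared_perianth_counts(self, by_id):
        ann = by_id["Ci-6"].annotations
        assert ann["shared_sepal_count"] == 4
        assert ann["shared_petal_count"] == 7

    def test_cg6_supernumerary_stamen_is_the_flagged_exception(self, by_id):
        assert by_id["Cg-6"].rule_exceptions == {"0/0": True}
        others = [r for r in load_collections("builtin") if r.id != "Cg-6"]
        assert all(not r.rule_exceptions for r in others)

    def test_mature_flower_counts(self, by_id):
        expected = {
            "Ci-1": 1, "Ci-2": 1, "Ci-3": 1, "Ci-4": 2, "Ci-5": 3,
            "Cg-1": 3, "Cg-2": 3, "Cg-3": 3, "Cg-4": 3, "Cg-5": 3, "Cg-6": 3,
            "Cg-7": 4, "Ci-6": 2, "Ci-7": 3, "Ci-8": 4, "Cg-8": 4,
        }
        for cid, n in expected.items():
            assert len(by_id[cid].topology.flowers(status="mature")) == n, cid


class TestRoundTrip:
    def test_all_builtin_records_round_trip_byte_stable(self, builtin_records):
        for record in builtin_records:
            text = write_collection(record)
            assert write_collection(read_collection(text)) == text, record.id

    def test_contradictory_pf_class_rejected(self, by_id):
        doc = record_to_document(by_id["Ci-1"])
        doc["pf_class"] = "cyme_3f"
        with pytest.raises(FDFError, match="pf_class"):
            read_collection(json.dumps(doc))

    def test_empty_document_is_a_parse_error(self):
        with pytest.raises(FDFError):
            read_collection("")
        with pytest.raises(FDFError):
            read_collection("{not json")

    def test_parse_errors_carry_a_json_path(self, by_id):
        doc = record_to_document(by_id["Ci-1"])
        doc["topology"]["children"][0]["bract"]["angle_deg"] = "east"
        with pytest.raises(FDFError, match=r"\$\.topology\.children\[0\]\.bract\.angle_deg"):
            read_collection(json.dumps(doc))

    def test_observation_for_unknown_flower_rejected(self, by_id):
        doc = record_to_document(by_id["Ci-1"])
        doc["observed"]["5/5"] = doc["observed"]["0"]
        with pytest.raises(FDFError, match="not a mature flower"):
            read_collection(json.dumps(doc))
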