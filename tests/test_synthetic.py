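"""Synthetic generator: determinism, typology, delay noise, recovery."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cannasym.concordance import evaluate
from cannasym.fixtures import read_collection, write_collection
from cannasym.synthetic import (
    GeneratorConfig,
    estimate_delay,
    generate_phenotypes,
    generate_record,
    generate_records,
    generate_topology,
)
from cannasym.topology import classify_partial_florescence, validate_tree


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_delay=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(p_dichasium=0.6, p_trichasium=0.3, p_thyrse=0.2)
        with pytest.raises(ValueError):
            GeneratorConfig(max_depth=0)


class TestGenerateTopology:
    def test_same_seed_same_tree(self):
        a = generate_topology(GeneratorConfig(seed=31))
        b = generate_topology(GeneratorConfig(seed=31))
        assert [(n.id, n.kind, n.status) for n in a.walk()] == [
            (n.id, n.kind, n.status) for n in b.walk()
        ]

    def test_degenerate_config_yields_single_flower(self):
        config = GeneratorConfig(p_continue=0.0, p_dichasium=0.0, p_trichasium=0.0, p_thyrse=0.0, seed=1)
        tree = generate_topology(config)
        assert classify_partial_florescence(tree).label == "single_flower"

    def test_forced_dichasium_yields_three_flowered_cyme(self):
        config = GeneratorConfig(p_continue=1.0, p_dichasium=1.0, p_trichasium=0.0, p_thyrse=0.0, max_depth=2, seed=1)
        tree = generate_topology(config)
        assert classify_partial_florescence(tree).label == "cyme_3f"

    @settings(max_examples=300, derandomize=True)
    @given(seed=st.integers(0, 10**7))
    def test_generated_trees_are_valid(self, seed):
        assert validate_tree(generate_topology(GeneratorConfig(seed=seed))) == []

    def test_all_typology_classes_reachable(self):
        labels = {
            classify_partial_florescence(generate_topology(GeneratorConfig(seed=s))).label
            for s in range(4000)
        }
        assert labels == {
            "single_flower", "cincinnus", "cyme_1f", "cyme_2f", "cyme_3f",
            "cyme_4f", "thyrse_2f", "thyrse_3f", "thyrse_4f",
        }


class TestGeneratePhenotypes:
    def test_zero_delay_observations_equal_predictions(self):
        from cannasym.androecium import predict_flower_phenotype

        for seed in range(50):
            record = generate_record(GeneratorConfig(seed=seed))
            for fid, obs in record.observed.items():
                pred = predict_flower_phenotype(record.topology, fid)
                assert obs.theca_count == pred.theca_count
                assert obs.appendage_side == pred.appendage_side
                assert obs.symmetry == pred.symmetry
            assert record.annotations["delayed_flowers"] == []

    def test_full_delay_forces_half_fertile_primaries(self):
        config = GeneratorConfig(
            p_continue=1.0, p_dichasium=1.0, p_trichasium=0.0, p_thyrse=0.0,
            p_delay=1.0, max_depth=2,
        )
        rng = random.Random(0)
        for _ in range(30):
            tree = generate_topology(config, rng)
            record = generate_phenotypes(tree, config, rng)
            assert record.pf_class == "cyme_3f"
            assert record.observed["0"].theca_count == 1  # dichasium-flanked, delayed
            assert record.observed["0"].symmetry in ("asymmetric", "intermediate")
            assert "0" in record.annotations["delayed_flowers"]

    def test_seeded_record_reproducible_and_round_trips(self):
        a = generate_record(GeneratorConfig(seed=99, p_delay=0.4))
        b = generate_record(GeneratorConfig(seed=99, p_delay=0.4))
        assert write_collection(a) == write_collection(b)
        assert write_collection(read_collection(write_collection(a))) == write_collection(a)

    @settings(max_examples=150, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_generated_records_validate(self, seed):
        record = generate_record(GeneratorConfig(seed=seed, p_delay=0.5))
        assert record.validate() == []


class TestDelayRecovery:
    def test_zero_delay_estimates_zero(self):
        records = generate_records(GeneratorConfig(seed=3, p_dichasium=0.5, p_continue=0.5), 500)
        est = estimate_delay(records)
        assert est.defined
        assert est.estimate == 0.0

    def test_no_eligible_flowers_is_an_undefined_sentinel(self):
        config = GeneratorConfig(p_continue=0.0, p_dichasium=0.0, p_trichasium=0.0, p_thyrse=0.0)
        est = estimate_delay(generate_records(config, 20))
        assert not est.defined
        assert est.n_eligible == 0 and est.estimate is None

    @pytest.mark.parametrize("p_delay", [0.1, 0.3, 0.5])
    def test_recovers_within_the_99pct_binomial_interval(self, p_delay):
        config = GeneratorConfig(seed=17, p_delay=p_delay, p_dichasium=0.5, p_continue=0.5)
        est = estimate_delay(generate_records(config, 4000), confidence=0.99)
        assert est.defined and est.n_eligible >= 1000
        assert est.ci_low <= p_delay <= est.ci_high

    def test_concordance_decreases_monotonically_in_delay(self):
        rates = []
        for p_delay in (0.0, 0.3, 0.6, 0.9):
            config = GeneratorConfig(seed=23, p_delay=p_delay, p_dichasium=0.5, p_continue=0.5)
            records = generate_records(config, 1000)
            reports = [evaluate(r) for r in records]
            match = sum(r.aggregates["theca_match"] for r in reports)
            total = sum(r.aggregates["flowers"] for r in reports)
            rates.append(match / total)
        assert rates == sorted(rates, reverse=True)
        assert rates[0] == 1.0
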