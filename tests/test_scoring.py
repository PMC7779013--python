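import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetrank.ontology import expand_evidence
from targetrank.scoring import (
    REJECT,
    ScoringConfig,
    ScoringError,
    build_associations,
    datasource_association,
    datatype_association,
    harmonic_sum,
    normalized_harmonic_sum,
    overall_association,
    score_evidence,
)

from .conftest import CHAIN, make_record


def oracle_harmonic_sum(scores, cap):
    """Independent direct-summation oracle."""
    total = 0.0
    for rank, s in enumerate(sorted(scores, reverse=True), start=1):
        if rank > cap:
            break
        total += s / rank**2
    return total


DENOM_100 = oracle_harmonic_sum([1.0] * 100, 100)


class TestScoringConfig:
    def test_denominator_matches_direct_sum(self, config):
        assert abs(config.normalization_denominator - DENOM_100) < 1e-12

    def test_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            ScoringConfig(cap=0)

    def test_weight_range_enforced(self):
        with pytest.raises(ValueError):
            ScoringConfig(source_weights={"x": 1.5})

    def test_from_dict_aliases(self):
        cfg = ScoringConfig.from_dict(
            {"cap": 10, "weights": {"eva": 0.5}, "phase_scores": {"4": 0.9}}
        )
        assert cfg.cap == 10
        assert cfg.source_weights["eva"] == 0.5
        assert cfg.phase_scores[4] == 0.9


class TestScoreEvidence:
    def test_gwas_above_cutoff_rejected(self, config):
        rec = make_record(
            source="ot_genetics_portal",
            datatype="genetic_association",
            resource_score=0.9,
            gwas_pvalue=1e-6,
        )
        assert score_evidence(rec, config) is REJECT

    def test_gwas_below_cutoff_passes_through(self, config):
        rec = make_record(
            source="ot_genetics_portal",
            datatype="genetic_association",
            resource_score=0.9,
            gwas_pvalue=1e-9,
        )
        assert score_evidence(rec, config) == 0.9

    def test_priority_threshold(self, config):
        below = make_record(source="project_score", priority_score=39)
        at = make_record(source="project_score", priority_score=40)
        assert score_evidence(below, config) is REJECT
        assert score_evidence(at, config) == pytest.approx(0.40)

    def test_phase_four_scores_one(self, config):
        rec = make_record(source="chembl", datatype="known_drug", clinical_phase=4)
        assert score_evidence(rec, config) == 1.0

    def test_default_passthrough_clips(self, config):
        assert score_evidence(make_record(resource_score=0.3), config) == 0.3

    def test_unscorable_record_errors(self, config):
        rec = make_record(source="mystery_source", something_else=1)
        with pytest.raises(ScoringError, match="mystery_source"):
            score_evidence(rec, config)


class TestHarmonicSum:
    def test_empty_is_zero(self):
        assert harmonic_sum([], 100) == 0.0

    def test_three_ones(self):
        assert harmonic_sum([1, 1, 1], 100) == pytest.approx(1 + 1 / 4 + 1 / 9, abs=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ScoringError):
            harmonic_sum([1.2], 100)
        with pytest.raises(ScoringError):
            harmonic_sum([-0.1], 100)

    def test_cap_truncates(self):
        assert harmonic_sum([1.0] * 10, 2) == pytest.approx(1 + 1 / 4, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(s=st.floats(0, 1, allow_nan=False))
    def test_single_term_is_identity(self, s):
        assert harmonic_sum([s], 100) == s

    @settings(max_examples=200, deadline=None)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), max_size=50),
        extra=st.floats(0, 1, allow_nan=False),
        cap=st.sampled_from([2, 10, 100]),
    )
    def test_appending_never_decreases(self, scores, extra, cap):
        assert harmonic_sum(scores + [extra], cap) >= harmonic_sum(scores, cap)

    @settings(max_examples=100, deadline=None)
    @given(scores=st.lists(st.floats(0, 1, allow_nan=False), max_size=30), seed=st.integers(0, 99))
    def test_permutation_invariance(self, scores, seed):
        shuffled = list(scores)
        np.random.default_rng(seed).shuffle(shuffled)
        assert harmonic_sum(shuffled, 100) == harmonic_sum(scores, 100)

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores = rng.random(int(rng.integers(0, 201))).tolist()
            for cap in (2, 10, 100):
                assert abs(harmonic_sum(scores, cap) - oracle_harmonic_sum(scores, cap)) < 1e-12


class TestNormalizedHarmonicSum:
    def test_half(self, config):
        assert normalized_harmonic_sum([0.5], config) == pytest.approx(0.5 / DENOM_100, abs=1e-12)
        assert normalized_harmonic_sum([0.5], config) == pytest.approx(0.3058, abs=1e-4)

    def test_cap_copies_of_one_is_exactly_one(self, config):
        assert normalized_harmonic_sum([1.0] * config.cap, config) == 1.0

    def test_empty_is_zero(self, config):
        assert normalized_harmonic_sum([], config) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(scores=st.lists(st.floats(0, 1, allow_nan=False), max_size=150))
    def test_bounded_in_unit_interval(self, scores):
        cfg = ScoringConfig()
        assert 0.0 <= normalized_harmonic_sum(scores, cfg) <= 1.0


class TestAssociationLevels:
    def test_datasource_single_evidence(self, config):
        assert datasource_association([0.8], config) == pytest.approx(0.8 / DENOM_100)

    def test_datasource_two_identical(self, config):
        expected = (0.8 + 0.8 / 4) / DENOM_100
        assert datasource_association([0.8, 0.8], config) == pytest.approx(expected, abs=1e-12)
        assert datasource_association([0.8, 0.8], config) == pytest.approx(0.6116, abs=1e-4)

    def test_datasource_superset_dominates(self, config):
        base = datasource_association([0.9], config)
        for x in (0.0, 0.3, 1.0):
            assert datasource_association([0.9, x], config) >= base

    def test_datatype_weighted(self, config):
        scores = {"ot_genetics_portal": 1.0, "eva": 1.0}
        cfg = config.model_copy(update={"source_weights": {"ot_genetics_portal": 1.0, "eva": 0.2}})
        expected = (1.0 + 0.2 / 4) / DENOM_100
        assert datatype_association(scores, cfg) == pytest.approx(expected, abs=1e-12)
        assert datatype_association(scores, cfg) == pytest.approx(0.6422, abs=1e-4)

    def test_datatype_unknown_source_errors(self, config):
        with pytest.raises(ScoringError, match="datatype"):
            datatype_association({"never_heard_of_it": 0.5}, config)

    def test_overall_single_source_weight_one(self, config):
        assert overall_association({"reactome": 1.0}, config) == pytest.approx(
            1.0 / DENOM_100, abs=1e-12
        )

    def test_overall_zero_source_is_noop(self, config):
        with_zero = overall_association({"reactome": 0.7, "eva": 0.0}, config)
        without = overall_association({"reactome": 0.7}, config)
        assert with_zero == pytest.approx(without, abs=1e-15)

    def test_all_zero_sources(self, config):
        assert datatype_association({"reactome": 0.0, "eva": 0.0}, config) == 0.0


class TestBuildAssociations:
    def test_empty_stream(self, config):
        assert build_associations([], config).empty

    def test_chain_propagation_copies_score(self, chain_graph, config):
        rec = make_record(disease=CHAIN["C"], resource_score=0.6)
        df = build_associations(expand_evidence(chain_graph, [rec]), config)
        indirect = df[~df["direct"]]
        assert set(indirect["disease_id"]) == set(CHAIN.values())
        assert indirect["overall_score"].nunique() == 1
        direct = df[df["direct"]]
        assert list(direct["disease_id"]) == [CHAIN["C"]]

    def test_many_weak_outrank_one_strong(self, chain_graph, config):
        # raw harmonic sums: 0.9 * sum_{1..50} 1/i^2 = 1.46262... > 1.0
        assert oracle_harmonic_sum([0.9] * 50, 100) == pytest.approx(1.4626194, abs=1e-6)
        weak = [
            make_record(target="ENSG00000000001", disease=CHAIN["C"], resource_score=0.9)
            for _ in range(50)
        ]
        strong = [make_record(target="ENSG00000000002", disease=CHAIN["C"], resource_score=1.0)]
        df = build_associations(expand_evidence(chain_graph, weak + strong), config)
        top = df[df["direct"]].iloc[0]
        assert top["target_id"] == "ENSG00000000001"

    def test_rejected_evidence_contributes_nothing(self, chain_graph, config):
        rec = make_record(
            source="ot_genetics_portal",
            datatype="genetic_association",
            disease=CHAIN["C"],
            resource_score=0.9,
            gwas_pvalue=1e-5,
        )
        counter = {}
        df = build_associations(expand_evidence(chain_graph, [rec]), config, counter)
        assert df.empty
        assert counter["n_rejected_by_scorer"] == 1

    def test_scores_bounded_and_sorted(self, chain_graph, config):
        rng = np.random.default_rng(5)
        recs = [
            make_record(
                target=f"ENSG{rng.integers(5):011d}",
                disease=CHAIN[rng.choice(["B", "C"])],
                resource_score=float(np.round(rng.random(), 4)),
            )
            for _ in range(60)
        ]
        df = build_associations(expand_evidence(chain_graph, recs), config)
        assert ((df["overall_score"] >= 0) & (df["overall_score"] <= 1)).all()
        for col in ("datasource_scores", "datatype_scores"):
            for blob in df[col]:
                assert all(0 <= v <= 1 for v in json.loads(blob).values())
        assert (df["overall_score"].diff().dropna() <= 1e-15).all()

    def test_deterministic_output(self, chain_graph, config):
        recs = [make_record(disease=CHAIN["C"], resource_score=s) for s in (0.3, 0.5)]
        a = build_associations(expand_evidence(chain_graph, recs), config)
        b = build_associations(expand_evidence(chain_graph, recs), config)
        assert a.to_csv() == b.to_csv()


def test_overall_equals_manual_composition(config):
    """Overall score is the weighted reduction of datasource scores directly."""
    ds = {"ot_genetics_portal": 0.5, "europepmc": 0.4}
    weighted = sorted(
        [config.weight_for(s) * v for s, v in ds.items()], reverse=True
    )
    manual = sum(v / (i + 1) ** 2 for i, v in enumerate(weighted)) / DENOM_100
    assert overall_association(ds, config) == pytest.approx(manual, abs=1e-15)
    assert math.isclose(config.weight_for("europepmc"), 0.2)
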