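"""Consensus intersection and the technical filter rules."""

import dataclasses

import numpy as np
import pytest

from somascreen.callsets import CandidateCall, CallsetError, VariantKey
from somascreen.filters import (
    DEFAULT_OVERRULED_FILTERS,
    ConsensusCandidate,
    FilterThresholds,
    build_recurrence_index,
    intersect_callsets,
    mutect_filter_policy,
    technical_filter,
)


def make_pair_calls(
    key,
    patient="P1",
    target="T",
    reference="B",
    depth_t=400,
    alt_t=8,
    depth_r=400,
    alt_r=0,
    plus=None,
    minus=None,
    filters=frozenset(),
):
    if plus is None:
        plus = alt_t - alt_t // 2
        minus = alt_t // 2
    common = dict(
        key=key, patient_id=patient, target_cell=target, reference_cell=reference
    )
    mutect = CandidateCall(
        **common, caller="mutect2", depth_target=depth_t, alt_reads_target=alt_t,
        depth_reference=0, alt_reads_reference=0, mutect_filters=frozenset(filters),
    )
    varscan = CandidateCall(
        **common, caller="varscan2", depth_target=depth_t, alt_reads_target=alt_t,
        depth_reference=depth_r, alt_reads_reference=alt_r,
        alt_plus_strand=plus, alt_minus_strand=minus, somatic_p=1e-6,
    )
    return mutect, varscan


def make_candidate(key=None, **kwargs):
    key = key or VariantKey("1", 1000, "C", "T")
    mutect, varscan = make_pair_calls(key, **kwargs)
    return ConsensusCandidate(
        key=key,
        patient_id=mutect.patient_id,
        target_cell=mutect.target_cell,
        reference_cell=mutect.reference_cell,
        mutect=mutect,
        varscan=varscan,
    )


class TestIntersection:
    def test_empty_input_gives_empty_consensus(self):
        _, varscan = make_pair_calls(VariantKey("1", 10, "C", "T"))
        merged, tally = intersect_callsets([], [varscan])
        assert merged == [] and tally == {
            "both": 0, "mutect2_only": 0, "varscan2_only": 1,
        }

    def test_shared_keys_only_brute_force(self, rng):
        keys = [VariantKey("1", int(p), "C", "T")
                for p in rng.choice(10**6, size=1500, replace=False)]
        mutect = [make_pair_calls(k)[0] for k in keys[:1000]]
        varscan = [make_pair_calls(k)[1] for k in keys[990:]]
        merged, tally = intersect_callsets(mutect, varscan)
        # brute-force pairwise scan oracle
        expected = {m.key for m in mutect for v in varscan if v.key == m.key}
        assert {c.key for c in merged} == expected
        assert tally["both"] == len(expected) == 10

    def test_merged_candidate_carries_both_evidence_records(self):
        key = VariantKey("3", 48508943, "C", "G")
        mutect, varscan = make_pair_calls(key)
        merged, _ = intersect_callsets([mutect], [varscan])
        (cand,) = merged
        assert cand.mutect is mutect and cand.varscan is varscan

    def test_symmetric_key_sets(self, rng):
        keys = [VariantKey("2", int(p), "G", "A")
                for p in rng.choice(10**6, size=200, replace=False)]
        mutect = [make_pair_calls(k)[0] for k in keys[:150]]
        varscan = [make_pair_calls(k)[1] for k in keys[100:]]
        ab, _ = intersect_callsets(mutect, varscan)
        # role-reversed inputs: same shared key set
        mutect2 = [make_pair_calls(k)[0] for k in keys[100:]]
        varscan2 = [make_pair_calls(k)[1] for k in keys[:150]]
        ba, _ = intersect_callsets(mutect2, varscan2)
        assert {c.key for c in ab} == {c.key for c in ba}

    def test_duplicate_key_in_one_caller_rejected(self):
        key = VariantKey("1", 10, "C", "T")
        mutect, varscan = make_pair_calls(key)
        with pytest.raises(CallsetError, match="1:10"):
            intersect_callsets([mutect, mutect], [varscan])

    def test_output_sorted_by_position(self):
        keys = [VariantKey("1", p, "C", "T") for p in (500, 100, 300)]
        mutect = [make_pair_calls(k)[0] for k in keys]
        varscan = [make_pair_calls(k)[1] for k in keys]
        merged, _ = intersect_callsets(mutect, varscan)
        assert [c.key.pos for c in merged] == [100, 300, 500]


class TestMutectPolicy:
    @pytest.mark.parametrize(
        "filters,expected",
        [
            (frozenset(), True),
            (frozenset({"clustered_events"}), True),
            (frozenset({"homologous_mapping_event"}), True),
            (frozenset({"clustered_events", "homologous_mapping_event"}), True),
            (frozenset({"clustered_events", "t_lod_fstar"}), False),
            (frozenset({"t_lod_fstar"}), False),
        ],
    )
    def test_subset_semantics(self, filters, expected):
        mutect, _ = make_pair_calls(VariantKey("1", 10, "C", "T"), filters=filters)
        assert mutect_filter_policy(mutect, DEFAULT_OVERRULED_FILTERS) is expected

    def test_matching_is_case_and_separator_insensitive(self):
        mutect, _ = make_pair_calls(
            VariantKey("1", 10, "C", "T"), filters=frozenset({"Clustered-Events"})
        )
        assert mutect_filter_policy(mutect, DEFAULT_OVERRULED_FILTERS)

    def test_varscan_call_rejected(self):
        _, varscan = make_pair_calls(VariantKey("1", 10, "C", "T"))
        with pytest.raises(CallsetError):
            mutect_filter_policy(varscan, DEFAULT_OVERRULED_FILTERS)


class TestRecurrenceIndex:
    def test_counts_distinct_samples_per_cell_type(self):
        key = VariantKey("1", 10, "C", "T")
        cands = [make_candidate(key, patient=f"P{i}") for i in range(3)]
        index = build_recurrence_index(cands)
        assert index.count(key, "T") == 3

    def test_cell_types_counted_separately(self):
        key = VariantKey("1", 10, "C", "T")
        cands = [
            make_candidate(key, patient="P1", target="T", reference="B"),
            make_candidate(key, patient="P2", target="B", reference="T"),
        ]
        index = build_recurrence_index(cands)
        assert index.count(key, "T") == 1 and index.count(key, "B") == 1

    def test_same_sample_counted_once(self):
        key = VariantKey("1", 10, "C", "T")
        cands = [make_candidate(key), make_candidate(key)]
        assert build_recurrence_index(cands).count(key, "T") == 1


class TestTechnicalFilter:
    def empty_index(self):
        return build_recurrence_index([])

    def test_clean_candidate_passes(self):
        cand = make_candidate(depth_t=400, alt_t=8, depth_r=400, alt_r=0)
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert dec.passed and dec.reasons == ()

    def test_coverage_boundary_at_300(self):
        cand = make_candidate(depth_t=299, alt_t=8)
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert dec.reasons == ("low_coverage_target",)
        ok = make_candidate(depth_t=300, alt_t=8, depth_r=300)
        assert technical_filter(ok, build_recurrence_index([ok])).passed

    def test_aaf_boundaries_inclusive_target_exclusive_reference(self):
        # target AAF exactly 0.5% passes; reference exactly 0.5% fails
        cand = make_candidate(depth_t=1000, alt_t=5, depth_r=1000, alt_r=5)
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert dec.reasons == ("high_reference_aaf",)

    def test_single_strand_detection_fails(self):
        cand = make_candidate(alt_t=6, plus=6, minus=0)
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert dec.reasons == ("strand_bias",)

    def test_recurrence_same_and_other_cell_type(self):
        key = VariantKey("1", 10, "C", "T")
        same = [make_candidate(key, patient=f"P{i}") for i in range(3)]
        index = build_recurrence_index(same)
        dec = technical_filter(same[0], index)
        assert "recurrent_same_celltype" in dec.reasons
        # two observations in the *other* cell type also disqualify
        other = [
            make_candidate(key, patient="P1", target="T", reference="B"),
            make_candidate(key, patient="P2", target="B", reference="T"),
            make_candidate(key, patient="P3", target="B", reference="T"),
        ]
        dec = technical_filter(other[0], build_recurrence_index(other))
        assert "recurrent_other_celltype" in dec.reasons

    def test_non_overruled_mutect_filter_reported_by_name(self):
        cand = make_candidate(filters=frozenset({"t_lod_fstar", "clustered_events"}))
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert dec.reasons == ("mutect_filter_failed:t_lod_fstar",)

    def test_all_rules_evaluated_without_short_circuit(self):
        cand = make_candidate(
            depth_t=100, alt_t=6, depth_r=100, alt_r=10, plus=6, minus=0,
            filters=frozenset({"t_lod_fstar"}),
        )
        dec = technical_filter(cand, build_recurrence_index([cand]))
        assert set(dec.reasons) == {
            "low_coverage_target",
            "low_coverage_reference",
            "high_reference_aaf",
            "strand_bias",
            "mutect_filter_failed:t_lod_fstar",
        }

    def test_monotone_in_coverage_and_aaf_thresholds(self, rng):
        cands = _random_candidates(rng, 300)
        index = build_recurrence_index(cands)
        base = FilterThresholds()
        stricter = [
            FilterThresholds(min_coverage=400),
            FilterThresholds(min_target_aaf=0.01),
            FilterThresholds(overruled_mutect_filters=frozenset()),
        ]
        passed_base = {
            id(c) for c in cands if technical_filter(c, index, base).passed
        }
        for th in stricter:
            passed = {id(c) for c in cands if technical_filter(c, index, th).passed}
            assert passed <= passed_base


def _random_candidates(rng, n):
    cands = []
    filter_pool = ["clustered_events", "homologous_mapping_event", "t_lod_fstar",
                   "str_contraction", "germline_risk"]
    shared = [VariantKey("9", int(p), "G", "A")
              for p in rng.choice(10**6, 10, replace=False)]
    for i in range(n):
        if rng.random() < 0.2:
            key = shared[int(rng.integers(len(shared)))]
        else:
            key = VariantKey("1", int(rng.integers(1, 10**7)), "C", "T")
        depth_t = int(rng.integers(100, 800))
        alt_t = int(rng.integers(1, max(2, depth_t // 20)))
        plus = int(rng.integers(0, alt_t + 1))
        depth_r = int(rng.integers(100, 800))
        alt_r = int(rng.integers(0, max(1, depth_r // 50) + 1))
        nf = int(rng.integers(0, 3))
        filters = frozenset(
            str(f) for f in rng.choice(filter_pool, size=nf, replace=False)
        )
        cands.append(
            make_candidate(
                key,
                patient=f"P{int(rng.integers(1, 8))}",
                target="T" if rng.random() < 0.7 else "B",
                depth_t=depth_t, alt_t=alt_t, depth_r=depth_r, alt_r=alt_r,
                plus=plus, minus=alt_t - plus, filters=filters,
            )
        )
    return cands


def brute_force_reference_decision(cand, all_cands, th=FilterThresholds()):
    """Direct re-evaluation of each textual rule, independent of the engine."""
    reasons = set()
    vs = cand.varscan
    if vs.depth_target < th.min_coverage:
        reasons.add("low_coverage_target")
    if vs.depth_reference < th.min_coverage:
        reasons.add("low_coverage_reference")
    if vs.alt_reads_target / vs.depth_target < th.min_target_aaf:
        reasons.add("low_target_aaf")
    if vs.alt_reads_reference / vs.depth_reference >= th.max_reference_aaf:
        reasons.add("high_reference_aaf")
    same_samples = {
        c.patient_id for c in all_cands
        if c.key == cand.key and c.target_cell == cand.target_cell
    }
    if len(same_samples) > th.max_same_celltype_recurrence:
        reasons.add("recurrent_same_celltype")
    other_cells = {c.target_cell for c in all_cands if c.key == cand.key} - {
        cand.target_cell
    }
    for ct in other_cells:
        n = len({
            c.patient_id for c in all_cands
            if c.key == cand.key and c.target_cell == ct
        })
        if n > th.max_other_celltype_recurrence:
            reasons.add("recurrent_other_celltype")
    if not (vs.alt_plus_strand >= 1 and vs.alt_minus_strand >= 1):
        reasons.add("strand_bias")
    for f in cand.mutect.mutect_filters:
        if f.lower() not in {"clustered_events", "homologous_mapping_event"}:
            reasons.add(f"mutect_filter_failed:{f.lower()}")
    if not cand.key.is_snv:
        reasons.add("non_snv")
    return reasons


def test_engine_matches_brute_force_reference(rng):
    cands = _random_candidates(rng, 500)
    index = build_recurrence_index(cands)
    for cand in cands:
        dec = technical_filter(cand, index)
        assert set(dec.reasons) == brute_force_reference_decision(cand, cands)


def test_reason_completeness_single_rule_flip(rng):
    """Disabling exactly the failed rule flips single-reason candidates."""
    cands = _random_candidates(rng, 200)
    index = build_recurrence_index(cands)
    relaxed = {
        "low_coverage_target": FilterThresholds(min_coverage=1),
        "low_target_aaf": FilterThresholds(min_target_aaf=0.0),
        "strand_bias": FilterThresholds(min_reads_per_strand=0),
    }
    for cand in cands:
        dec = technical_filter(cand, index)
        if len(dec.reasons) == 1 and dec.reasons[0] in relaxed:
            re_dec = technical_filter(cand, index, relaxed[dec.reasons[0]])
            if dec.reasons[0] == "low_coverage_target":
                # relaxing min_coverage also lifts the reference-side rule
                assert "low_coverage_target" not in re_dec.reasons
            else:
                assert re_dec.passed


def test_thresholds_validate_ranges():
    with pytest.raises(CallsetError):
        FilterThresholds(min_coverage=0)
    with pytest.raises(CallsetError):
        FilterThresholds(min_target_aaf=1.5)
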