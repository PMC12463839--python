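"""Ungapped aligner, best-hit collation, and isolate summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_align, revcomp
from conftest import reference_records
from rhizoscreen import matching
from rhizoscreen.matching import (
    AlignmentHit,
    SequenceRecord,
    build_reference_index,
    collate_matches,
    summarize_isolates,
    ungapped_local_align,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def make_hit(asv="asv1", subject="s1", isolate="i1", region="merged",
             strand="+", length=253, matches=250, score=None,
             qs=0, ss=0):
    return AlignmentHit(
        asv_id=asv, subject_id=subject, isolate_id=isolate, region=region,
        strand=strand, query_start=qs, subject_start=ss,
        alignment_length=length, matches=matches,
        score=score if score is not None else 2 * matches
        - 3 * (length - matches))


class TestAligner:
    def test_self_alignment_is_perfect(self):
        seq = "ACGTACGTTGCA"
        hit = ungapped_local_align(seq, seq)
        assert (hit.alignment_length, hit.matches) == (len(seq), len(seq))
        assert hit.percent_identity == 100.0
        assert hit.strand == "+" and hit.subject_start == 0

    def test_exact_substring_found_inside_long_subject(self, rng):
        subject = "".join(rng.choice(list("ACGT"), size=1200))
        query = subject[400:653]
        hit = ungapped_local_align(query, subject)
        assert hit.alignment_length == 253
        assert hit.percent_identity == 100.0
        assert hit.subject_start == 400

    def test_agrees_with_bruteforce_enumeration(self, rng):
        for _ in range(60):
            nq, ns = rng.integers(20, 61, size=2)
            query = "".join(rng.choice(list("ACGT"), size=nq))
            subject = "".join(rng.choice(list("ACGT"), size=ns))
            expect = brute_force_align(query, subject)
            hit = ungapped_local_align(query, subject)
            got = (hit.score, hit.alignment_length, hit.matches, hit.strand,
                   hit.query_start, hit.subject_start)
            assert got == expect

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(query=dna, subject=dna)
    def test_reverse_complement_symmetry(self, query, subject):
        fwd = ungapped_local_align(query, subject)
        rev = ungapped_local_align(revcomp(query), subject)
        if fwd is None:
            assert rev is None
        else:
            assert rev.score == fwd.score
            assert rev.alignment_length == fwd.alignment_length
            assert rev.matches == fwd.matches

    def test_ambiguity_codes_never_match(self):
        hit = ungapped_local_align("ANNA" + "CGCG", "ANNACGCG")
        # N-N columns score as mismatch, so the best segment avoids them
        assert hit.matches == hit.alignment_length
        assert "N" not in "ANNACGCG"[hit.subject_start:
                                     hit.subject_start + hit.alignment_length]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ungapped_local_align("", "ACGT")
        with pytest.raises(ValueError):
            ungapped_local_align("ACGT", "ACXT")
        with pytest.raises(ValueError):
            ungapped_local_align("ACGT", "ACGT", reward=-1)


class TestReferenceIndex:
    def test_counts_per_region(self, small_sequence_family):
        index = build_reference_index(
            reference_records(small_sequence_family))
        assert sorted(index.regions) == sorted(matching.REGIONS)
        assert all(len(index.subjects(r)) == 8 for r in matching.REGIONS)
        assert len(index.isolates) == 8

    def test_partial_region_coverage_tolerated(self):
        recs = [SequenceRecord("a|merged", "ACGT", "merged", "a"),
                SequenceRecord("b|merged", "ACGT", "merged", "b"),
                SequenceRecord("a|27F", "ACGT", "27F", "a")]
        index = build_reference_index(recs)
        assert len(index.subjects("merged")) == 2
        assert len(index.subjects("27F")) == 1

    def test_duplicate_and_untagged_rejected(self):
        dup = [SequenceRecord("a|merged", "ACGT", "merged", "a")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_reference_index(dup)
        with pytest.raises(ValueError, match="region"):
            build_reference_index([SequenceRecord("a", "ACGT", None, "a")])


class TestCollation:
    def test_length_rule_boundary(self):
        lengths = {"asv1": 253}
        keep = make_hit(length=251, matches=251)    # |251-253| = 2
        drop = make_hit(length=250, matches=250)    # |250-253| = 3
        table = collate_matches([keep, drop], lengths)
        assert list(table.hits["alignment_length"]) == [251]

    def test_merged_preferred_over_27f_despite_lower_identity(self):
        lengths = {"asv1": 253}
        merged = make_hit(subject="i1|merged", region="merged",
                          length=253, matches=251)   # 99.209
        f27 = make_hit(subject="i1|27F", region="27F",
                       length=253, matches=253)      # 100.0
        table = collate_matches([merged, f27], lengths)
        preferred = table.hits[table.hits["preferred"]]
        assert list(preferred["region"]) == ["merged"]
        assert table.winning_region["asv1"] == "merged"

    def test_full_preference_hierarchy(self):
        lengths = {"asv1": 253}
        hits = [make_hit(subject=f"i1|{r}", region=r)
                for r in ("515R", "515F", "27F")]
        table = collate_matches(hits, lengths)
        assert table.winning_region["asv1"] == "27F"
        table2 = collate_matches(
            [make_hit(subject="i1|515R", region="515R"),
             make_hit(subject="i1|515F", region="515F")], lengths)
        assert table2.winning_region["asv1"] == "515F"

    def test_empty_and_unknown(self):
        assert len(collate_matches([], {"asv1": 253}).hits) == 0
        with pytest.raises(KeyError):
            collate_matches([make_hit(asv="ghost")], {"asv1": 253})

    def test_collation_is_idempotent(self, small_sequence_family):
        sim = small_sequence_family
        index = build_reference_index(reference_records(sim))
        hits = matching.match_asvs(sim.asvs, index)
        lengths = {a: len(s) for a, s in sim.asvs.items()}
        once = collate_matches(hits, lengths)
        twice = collate_matches(once.hits, lengths)
        assert once.hits.equals(twice.hits)
        assert once.winning_region == twice.winning_region

    def test_one_per_asv_mode_keeps_single_winner(self):
        lengths = {"asv1": 253}
        hits = [make_hit(subject="i1|merged", isolate="i1", region="merged"),
                make_hit(subject="i2|27F", isolate="i2", region="27F")]
        table = collate_matches(hits, lengths, one_per_asv=True)
        assert len(table.hits) == 1
        assert table.hits.iloc[0]["region"] == "merged"


class TestSummaries:
    def test_identity_floor_excludes_pair_below(self):
        lengths = {"asv1": 100, "asv2": 100}
        good = make_hit(asv="asv1", subject="i1|merged", isolate="i1",
                        length=100, matches=96)   # 96%
        bad = make_hit(asv="asv2", subject="i2|merged", isolate="i2",
                       length=100, matches=94)    # 94%
        table = collate_matches([good, bad], lengths)
        summaries, report = summarize_isolates(table, min_identity=95.0)
        assert [s.isolate_id for s in summaries] == ["i1"]
        assert report["n_matched_asvs"] == 1
        assert report["fraction_matched"] == 0.5

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(floor=st.floats(min_value=90.0, max_value=100.0))
    def test_raising_floor_never_adds_isolates(self, floor,
                                               small_sequence_family):
        sim = small_sequence_family
        index = build_reference_index(reference_records(sim))
        hits = matching.match_asvs(sim.asvs, index)
        table = collate_matches(hits, {a: len(s)
                                       for a, s in sim.asvs.items()})
        low, _ = summarize_isolates(table, min_identity=90.0)
        high, _ = summarize_isolates(table, min_identity=floor)
        assert {s.isolate_id for s in high} <= {s.isolate_id for s in low}

    def test_invalid_floor(self, small_sequence_family):
        sim = small_sequence_family
        index = build_reference_index(reference_records(sim))
        table = collate_matches(matching.match_asvs(sim.asvs, index),
                                {a: len(s) for a, s in sim.asvs.items()})
        with pytest.raises(ValueError):
            summarize_isolates(table, min_identity=0.0)


def test_truth_recovery_small_family(small_sequence_family):
    """Every planted pair is recovered with its exact Hamming identity."""
    sim = small_sequence_family
    index = build_reference_index(reference_records(sim))
    hits = matching.match_asvs(sim.asvs, index)
    table = collate_matches(hits, {a: len(s) for a, s in sim.asvs.items()})
    pref = table.hits[table.hits["preferred"]].set_index(
        ["asv_id", "isolate_id"])
    planted = sim.truth[sim.truth["source_isolate"] != ""]
    for row in planted.itertuples():
        hit = pref.loc[(row.asv_id, row.source_isolate)]
        assert hit["percent_identity"] == pytest.approx(
            round(row.expected_percent_identity, 3), abs=5e-4)
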