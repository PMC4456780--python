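import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primermap.design import (DesignParameters, ParameterError,
                              count_occurrences, design_primers,
                              enumerate_candidates, passes_filters)
from primermap.seq_io import SequenceRecord, reverse_complement
from primermap.synthetic import GeneratorSpec, generate_records, planted_dataset

from .oracles import oracle_count, oracle_design, oracle_enumerate, oracle_passes


def record_of_length(n, seed=3):
    recs, _ = generate_records(GeneratorSpec(n_records=1,
                                             length_range=(n, n), seed=seed))
    return recs[0]


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs,fragment", [
        ({"len_min": 25, "len_max": 20}, "len_min"),
        ({"gc_min": 70.0, "gc_max": 60.0}, "gc_min"),
        ({"tm_min": 70.0, "tm_max": 65.0}, "tm_min"),
        ({"five_prime_window": 10}, "windows"),
        ({"len_max": 0, "len_min": 0}, "positive"),
    ])
    def test_invariant_violations_rejected(self, kwargs, fragment):
        with pytest.raises(ParameterError, match=fragment):
            DesignParameters(**kwargs)


class TestEnumerateCandidates:
    def test_forward_fixed_length_count(self):
        """Window 30, fixed length 20 -> 30 - 20 + 1 = 11 starts."""
        params = DesignParameters(five_prime_window=30, three_prime_window=30,
                                  len_min=20, len_max=20)
        cands = enumerate_candidates(record_of_length(100), params, "forward")
        assert len(cands) == 11
        assert [c.start for c in cands] == list(range(1, 12))

    def test_reverse_length_range_count(self):
        """Window 25, lengths 18..22 -> sum of (25-len+1) = 30."""
        params = DesignParameters(five_prime_window=25, three_prime_window=25,
                                  len_min=18, len_max=22)
        cands = enumerate_candidates(record_of_length(100), params, "reverse")
        assert len(cands) == 30
        # all spans lie inside the final 25 bases
        assert all(76 <= c.start and c.end <= 100 for c in cands)

    def test_reverse_seq_is_revcomp_of_slice(self):
        params = DesignParameters(five_prime_window=40, three_prime_window=40,
                                  len_min=18, len_max=20)
        rec = record_of_length(120)
        for c in enumerate_candidates(rec, params, "reverse"):
            assert c.seq == reverse_complement(rec.seq[c.start - 1:c.end])

    def test_window_clamped_to_record_length(self):
        rec = record_of_length(60)
        params = DesignParameters(five_prime_window=500, three_prime_window=500,
                                  len_min=18, len_max=20)
        for direction in ("forward", "reverse"):
            cands = enumerate_candidates(rec, params, direction)
            assert all(1 <= c.start and c.end <= 60 for c in cands)
            assert len(cands) == len(oracle_enumerate(rec, params, direction))

    def test_window_narrower_than_len_min_warns_empty(self, caplog):
        rec = record_of_length(400)
        params = DesignParameters(five_prime_window=19, three_prime_window=150,
                                  len_min=19, len_max=24)
        short = SequenceRecord(id="tiny", seq=rec.seq[:10])
        with caplog.at_level("WARNING"):
            assert enumerate_candidates(short, params, "forward") == []
        assert "tiny" in caplog.text

    @pytest.mark.parametrize("direction", ["forward", "reverse"])
    def test_matches_brute_force_enumeration(self, direction):
        rec = record_of_length(400, seed=17)
        params = DesignParameters()
        got = [(c.start, c.end, c.seq)
               for c in enumerate_candidates(rec, params, direction)]
        assert got == oracle_enumerate(rec, params, direction)


class TestPassesFilters:
    def test_gc_clamp_failure_recorded(self):
        params = DesignParameters()
        cands = enumerate_candidates(record_of_length(300), params, "forward")
        ending_at = next(c for c in cands if c.seq[-1] in "AT")
        audited = passes_filters(ending_at, params)
        assert "gc_clamp" in audited.rejection_reasons

    def test_within_bounds_passes(self):
        params = DesignParameters(gc_min=40.0, gc_max=60.0, tm_min=0.0,
                                  tm_max=100.0, gc_clamp=False)
        cand = next(c for c in enumerate_candidates(
            record_of_length(300), params, "forward") if c.gc == 50.0)
        assert passes_filters(cand, params).accepted

    def test_audit_is_pure(self):
        params = DesignParameters()
        cand = enumerate_candidates(record_of_length(300), params, "forward")[0]
        before = dataclasses.replace(cand)
        passes_filters(cand, params)
        assert cand == before

    def test_accepted_subset_matches_independent_predicate(self):
        """1000+ random candidates vs a second implementation of the
        four rules."""
        params = DesignParameters(gc_min=42.0, gc_max=58.0,
                                  tm_min=50.0, tm_max=62.0)
        cands = []
        for seed in (1, 2, 3):
            rec = record_of_length(300, seed=seed)
            for d in ("forward", "reverse"):
                cands.extend(enumerate_candidates(rec, params, d))
        assert len(cands) >= 1000
        for cand in cands:
            audited = passes_filters(cand, params)
            assert audited.accepted == (not oracle_passes(cand.seq, params))


class TestCountOccurrences:
    def test_palindromic_oligo_double_counts(self):
        rec = SequenceRecord(id="r", seq="ACGTACGT")
        assert count_occurrences("ACGT", [rec]) == 4

    def test_reverse_complement_hit(self):
        rec = SequenceRecord(id="r", seq="GTTTT")
        assert count_occurrences("AAAAC", [rec]) == 1

    def test_overlapping_hits_counted(self):
        rec = SequenceRecord(id="r", seq="AAAAAA")
        # "AAA" forward at 1..4 (4 hits) + "TTT" rc hits (0)
        assert count_occurrences("AAA", [rec]) == 4

    def test_matches_sliding_window_oracle(self):
        recs, _ = generate_records(GeneratorSpec(n_records=10,
                                                 length_range=(100, 300),
                                                 seed=23))
        probe = recs[0].seq[10:30]
        assert count_occurrences(probe, recs) == \
            oracle_count(probe, [r.seq for r in recs])


class TestDesignPrimers:
    def test_duplicate_records_kill_whole_file_specificity(self):
        rec = record_of_length(300, seed=5)
        twin = SequenceRecord(id="copy", seq=rec.seq)
        params = DesignParameters(specificity_whole_file=True)
        sets = design_primers([rec, twin], params)
        assert all(len(s) == 0 for s in sets)

    def test_record_scope_recovers_single_record_result(self):
        rec = record_of_length(300, seed=5)
        twin = SequenceRecord(id="copy", seq=rec.seq)
        scoped = DesignParameters(specificity_whole_file=False)
        dup_sets = design_primers([rec, twin], scoped)
        solo_sets = design_primers([rec], scoped)
        key = lambda s: [(p.start, p.end, p.direction, p.seq) for p in s.primers]
        assert key(dup_sets[0]) == key(solo_sets[0])

    def test_end_to_end_equals_brute_force_pipeline(self):
        records, _ = planted_dataset(seed=11)
        params = DesignParameters()
        sets = design_primers(records, params)
        expected = oracle_design(records, params)
        for pset, exp in zip(sets, expected):
            got = [(p.start, p.end, p.direction, p.seq) for p in pset.primers]
            assert got == exp

    def test_whole_file_accepted_subset_of_record_scope(self, seeded_records):
        whole = design_primers(seeded_records,
                               DesignParameters(specificity_whole_file=True))
        scoped = design_primers(seeded_records,
                                DesignParameters(specificity_whole_file=False))
        for w, s in zip(whole, scoped):
            w_keys = {(p.start, p.end, p.direction) for p in w.primers}
            s_keys = {(p.start, p.end, p.direction) for p in s.primers}
            assert w_keys <= s_keys

    def test_invariant_under_record_permutation(self, seeded_records):
        params = DesignParameters()
        forward_order = design_primers(seeded_records, params)
        backward_order = design_primers(seeded_records[::-1], params)
        by_id_fwd = {s.target_id: s for s in forward_order}
        by_id_bwd = {s.target_id: s for s in backward_order}
        assert set(by_id_fwd) == set(by_id_bwd)
        for tid in by_id_fwd:
            a = [(p.start, p.end, p.direction, p.seq, p.name)
                 for p in by_id_fwd[tid].primers]
            b = [(p.start, p.end, p.direction, p.seq, p.name)
                 for p in by_id_bwd[tid].primers]
            assert a == b

    def test_names_unique_within_set(self, seeded_records):
        for pset in design_primers(seeded_records, DesignParameters()):
            names = [p.name for p in pset.primers]
            assert len(names) == len(set(names))
            assert all(n for n in names)

    def test_accepted_primers_reproduce_target_slice(self, seeded_records):
        by_id = {r.id: r for r in seeded_records}
        for pset in design_primers(seeded_records, DesignParameters()):
            rec = by_id[pset.target_id]
            for p in pset.primers:
                slice_ = rec.seq[p.start - 1:p.end]
                if p.direction == "forward":
                    assert p.seq == slice_
                else:
                    assert p.seq == reverse_complement(slice_)

    @given(st.sampled_from(["gc_min", "gc_max", "tm_min", "tm_max", "gc_clamp"]),
           st.integers(min_value=0, max_value=30))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_tightening_any_bound_never_adds_primers(self, knob, seed):
        """Filter monotonicity: a stricter parameter set accepts a
        subset of the looser set's primers."""
        rec = record_of_length(250, seed=seed)
        base = DesignParameters(five_prime_window=80, three_prime_window=80,
                                gc_clamp=False, gc_min=35.0, gc_max=65.0,
                                tm_min=45.0, tm_max=70.0)
        tighter = {
            "gc_min": {"gc_min": 45.0}, "gc_max": {"gc_max": 55.0},
            "tm_min": {"tm_min": 52.0}, "tm_max": {"tm_max": 62.0},
            "gc_clamp": {"gc_clamp": True},
        }[knob]
        loose = design_primers([rec], base)[0]
        strict = design_primers([rec], dataclasses.replace(base, **tighter))[0]
        assert len(strict) <= len(loose)
        strict_keys = {(p.start, p.end, p.direction) for p in strict.primers}
        loose_keys = {(p.start, p.end, p.direction) for p in loose.primers}
        assert strict_keys <= loose_keys

    def test_no_primers_is_not_an_error(self, caplog):
        rec = record_of_length(100)
        params = DesignParameters(tm_min=90.0, tm_max=95.0)
        with caplog.at_level("WARNING"):
            sets = design_primers([rec], params)
        assert sets[0].primers == []
        assert "no primers" in caplog.text

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            design_primers([], DesignParameters())
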