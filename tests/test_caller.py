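"""Alignment, allele classification, UMI consensus and observed summaries."""

import numpy as np
import pytest

from conftest import (enumerate_alignment_score, random_dna,
                      recursive_alignment_score)
from endjoin.caller import (Alignment, COMPLEX, DELETION, INSERTION,
                            OUT_OF_WINDOW, REFERENCE_DISCOVERY_SCORING,
                            WILDTYPE, call_reads, classify_allele,
                            consensus_umis, global_align,
                            observed_distribution, right_align)
from endjoin.catalog import (DeletionClass, InsertionClass, TargetContext,
                             apply_event, collapse_redundant,
                             enumerate_deletion_classes,
                             enumerate_insertion_classes)
from endjoin.simulator import emit_reads, simulate_dataset

BASE = "ATGCTAGTCGACTGGTCACGATGTCCTAGAGTCATCGGTCGATCGTACGATCGATGCATG"


class TestGlobalAlign:
    def test_perfect_match_scores_5_per_base(self):
        a = global_align("ACGT", "ACGT")
        assert a.score == 20
        assert not a.has_gaps()

    def test_two_bp_gap_costs_open_plus_extend(self):
        a = global_align("ACGT", "ACGTAC")
        assert a.score == pytest.approx(4 * 5 - 13 - 0.5)
        assert a.query_aligned == "ACGT--"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_matches_recursive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(33)
        for _ in range(60):
            q = random_dna(rng, int(rng.integers(1, 7)))
            r = random_dna(rng, int(rng.integers(1, 7)))
            got = global_align(q, r).score
            want = recursive_alignment_score(q, r, 5, -4, -13, -0.5)
            assert got == pytest.approx(want)

    def test_recursive_oracle_matches_full_enumeration(self):
        rng = np.random.default_rng(34)
        for _ in range(25):
            q = random_dna(rng, int(rng.integers(1, 6)))
            r = random_dna(rng, int(rng.integers(1, 6)))
            assert recursive_alignment_score(q, r, 5, -4, -13, -0.5) == \
                pytest.approx(enumerate_alignment_score(q, r, 5, -4, -13, -0.5))

    def test_n_mismatch_preset_scores_n_as_neutral(self):
        a = global_align("ACNT", "ACGT", REFERENCE_DISCOVERY_SCORING)
        assert a.score == 15  # 3 matches + one N pairing at 0


class TestRightAlign:
    def test_gap_shifts_to_the_last_repeat_base(self):
        a = global_align("ATTG", "ATTTG")
        assert a.query_aligned == "ATT-G"

    def test_idempotent(self):
        a = global_align("ATTG", "ATTTG")
        again = right_align(a)
        assert (again.query_aligned, again.ref_aligned) == \
            (a.query_aligned, a.ref_aligned)

    def test_gapless_alignment_unchanged(self):
        a = Alignment("ACGT", "ACTT", 11.0)
        b = right_align(a)
        assert (b.query_aligned, b.ref_aligned) == ("ACGT", "ACTT")

    def test_score_is_preserved(self):
        raw = Alignment("A-TTG", "ATTTG", 0.0)
        shifted = right_align(raw)
        assert shifted.query_aligned == "ATT-G"
        assert shifted.ref_aligned == "ATTTG"


class TestClassifyAllele:
    def test_exact_match_is_wildtype(self):
        t = TargetContext(BASE)
        assert classify_allele(t, BASE).category == WILDTYPE

    def test_substitution_only_is_flagged_wildtype(self):
        t = TargetContext(BASE)
        allele = BASE[:10] + ("A" if BASE[10] != "A" else "C") + BASE[11:]
        call = classify_allele(t, allele)
        assert call.category == WILDTYPE
        assert call.substituted

    def test_deletion_far_downstream_is_out_of_window(self):
        t = TargetContext(BASE)
        allele = BASE[:45] + BASE[46:]
        assert classify_allele(t, allele).category == OUT_OF_WINDOW

    def test_two_separated_indels_are_complex(self):
        t = TargetContext(BASE)
        allele = BASE[:5] + BASE[6:29] + BASE[30:]  # deletions at 5 and 29
        assert classify_allele(t, allele).category == COMPLEX

    def test_round_trip_returns_collapse_canonical(self, random_targets):
        classes = enumerate_deletion_classes()
        for t in random_targets(2, seed=41):
            canon = collapse_redundant(t, classes)
            for dc in classes[::7]:
                call = classify_allele(t, apply_event(t, dc))
                assert call.category == DELETION
                assert call.event == canon[dc]
            for ic in enumerate_insertion_classes():
                allele = apply_event(t, ic,
                                     long_seq="ACGTA" if ic.is_long else None)
                call = classify_allele(t, allele)
                assert call.category == INSERTION
                assert call.event == ic


class TestConsensusUMIs:
    UMI = "ACGTACGTACGTACG"

    def test_group_of_ten_identical_reads_kept(self):
        groups, stats = consensus_umis([(self.UMI, BASE)] * 10)
        assert len(groups) == 1
        assert groups[0].representative == BASE
        assert stats["kept_groups"] == 1

    def test_nine_reads_dropped(self):
        groups, stats = consensus_umis([(self.UMI, BASE)] * 9)
        assert groups == []
        assert stats["dropped_small_groups"] == 1

    def test_low_identity_reads_filtered_but_group_kept(self):
        # 2 of 12 reads at 80% identity to the majority sequence
        rogue = "".join("A" if i % 5 == 0 and c != "A" else c
                        for i, c in enumerate(BASE))
        n_diff = sum(a != b for a, b in zip(rogue, BASE))
        assert 1 - n_diff / 60 < 0.9
        groups, stats = consensus_umis([(self.UMI, BASE)] * 10 +
                                       [(self.UMI, rogue)] * 2)
        assert len(groups) == 1
        assert stats["low_identity_reads"] == 2
        assert len(groups[0].reads) == 10

    def test_ties_break_lexicographically(self):
        a, b = sorted([BASE, BASE[:-1] + "A"])
        groups, _ = consensus_umis([(self.UMI, a)] * 6 + [(self.UMI, b)] * 6)
        assert groups[0].representative == a

    def test_malformed_umi_counted_and_dropped(self):
        groups, stats = consensus_umis([("SHORT", BASE)] * 10)
        assert groups == []
        assert stats["malformed_umi_reads"] == 10


class TestObservedDistribution:
    def test_frequencies_over_indel_calls_only(self, random_targets):
        (t,) = random_targets(1, seed=51)
        dc = enumerate_deletion_classes()[0]
        canon = collapse_redundant(t, enumerate_deletion_classes())[dc]
        calls = ([classify_allele(t, apply_event(t, dc))] * 80 +
                 [classify_allele(t, apply_event(t, InsertionClass("A")))] * 20 +
                 [classify_allele(t, t.sequence)] * 50)
        dist, summary = observed_distribution(calls)
        assert dist.probs[canon.event_id(30)] == pytest.approx(0.8)
        assert dist.probs["I:A"] == pytest.approx(0.2)
        assert summary["fraction_wildtype"] == pytest.approx(50 / 150)

    def test_no_usable_calls_flagged(self, random_targets):
        (t,) = random_targets(1, seed=52)
        dist, summary = observed_distribution([classify_allele(t, t.sequence)])
        assert dist is None
        assert np.isnan(summary["entropy_bits"])


class TestPipelineRoundTrip:
    def test_error_free_reads_recover_sampled_counts_exactly(self):
        ds = simulate_dataset(3, 30, seed=61)
        reads = emit_reads(ds, reads_per_umi=10, error_rate=0.0, seed=61)
        targets = {r.target.target_id: r.target for r in ds.records}
        calls = call_reads(reads, targets)
        for rec in ds.records:
            got = {}
            for c in calls:
                if c.target_id == rec.target.target_id:
                    got[c.event_id(30)] = got.get(c.event_id(30), 0) + 1
            want = {e: n for e, n in rec.counts.items() if n > 0}
            assert got == want
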