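"""Folding DP correctness and the stem-loop / duplex acceptance criteria."""

import dataclasses

import numpy as np
import pytest

from smallrna_crstress import novel_hairpin as nh
from smallrna_crstress.annotate_known import Locus, reverse_complement

from _oracles import brute_force_mfe, chain_energy


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFold:
    def test_no_complementarity_no_pairs(self):
        r = nh.fold("AAAAAAAAAA")
        assert r.structure == "." * 10 and r.mfe == 0.0

    def test_simple_stem(self):
        r = nh.fold("GGGGAAAACCCC")
        assert r.structure == "((((....))))"
        # 3 WC/WC stacks + hairpin closing penalty
        assert r.mfe == pytest.approx(3 * -2.0 + 3.0)
        assert r.mfe == pytest.approx(brute_force_mfe("GGGGAAAACCCC"))

    def test_alphabet_and_length_validation(self):
        with pytest.raises(ValueError, match="length"):
            nh.fold("ACGT")
        with pytest.raises(ValueError, match="invalid characters"):
            nh.fold("ACGTNACGTNACGT")

    def test_dp_equals_enumeration_on_random_sequences(self):
        """DP energy == exhaustive enumeration over the structure class."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            seq = _random_seq(rng, int(rng.integers(12, 25)))
            assert nh.fold(seq).mfe == pytest.approx(brute_force_mfe(seq)), seq

    def test_reported_structure_scores_its_energy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = _random_seq(rng, 40)
            r = nh.fold(seq)
            chain = sorted(r.pairs())
            if chain:
                assert nh.score_structure(seq, chain) == pytest.approx(r.mfe)
                assert chain_energy(seq, chain) == pytest.approx(r.mfe)

    def test_structure_well_formed(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = _random_seq(rng, 60)
            r = nh.fold(seq)
            assert len(r.structure) == len(seq)
            pairs = r.pairs()
            for i, j in pairs:
                assert nh.pair_type(seq[i], seq[j]) > 0
            if pairs:
                k, l = max(pairs)
                assert l - k - 1 >= nh.DEFAULT_MODEL.min_loop

    def test_deterministic(self):
        seq = "GCGCGAUAUAUAUCGCGCAUAU"
        assert nh.fold(seq).structure == nh.fold(seq).structure


class TestExciseCandidates:
    REF = {"c1": "".join(np.array(list("ACGT"))[np.random.default_rng(3).integers(0, 4, 2000)])}

    def test_both_orientations_produced(self):
        tag = self.REF["c1"][500:521]
        wins = nh.excise_candidates(Locus("c1", 500, 521, "+"), self.REF)
        assert all(w.sequence[w.mature_offset : w.mature_offset + 21] == tag for w in wins)
        offs = {w.mature_offset for w in wins}
        assert min(offs) <= 15 and max(offs) > 100  # 5p-anchored and 3p-anchored

    def test_contig_edge_truncates_without_failure(self):
        wins = nh.excise_candidates(Locus("c1", 5, 26, "+"), self.REF)
        assert wins and all(w.start >= 0 for w in wins)

    def test_minus_strand_contains_tag(self):
        tag_rc = reverse_complement(self.REF["c1"][500:521])
        wins = nh.excise_candidates(Locus("c1", 500, 521, "-"), self.REF)
        assert all(w.sequence[w.mature_offset : w.mature_offset + 21] == tag_rc for w in wins)


def _perfect_hairpin(mature, loop="CAACAAGA"):
    return mature + loop + reverse_complement(mature)


class TestEvaluateHairpin:
    MATURE = "TGACAGAAGAGAGTGAGCACA"

    def _window(self, seq, offset):
        return nh.Window("c1", 0, len(seq), "+", offset, seq)

    def test_perfect_inverted_repeat_accepted(self):
        crit = dataclasses.replace(nh.DEFAULT_CRITERIA, precursor_min=40)
        pre = _perfect_hairpin(self.MATURE)
        cand = nh.evaluate_hairpin(self._window(pre, 0), self.MATURE, criteria=crit)
        assert cand.accepted, cand.reason
        assert cand.arm == "5p"
        assert cand.duplex_mismatches == 0
        assert cand.asymmetric_bulge == 0

    def test_mature_in_loop_rejected(self):
        # place the tag across the terminal loop of a long hairpin
        stem = "GCTAGCTAGCGATCGATCGAGCTA"
        pre = stem + self.MATURE + reverse_complement(stem)
        cand = nh.evaluate_hairpin(self._window(pre, len(stem) - 3), self.MATURE)
        assert not cand.accepted
        assert cand.reason in ("mature-in-loop", "mfe")

    def test_mfe_threshold_rejects_weak_stem(self):
        crit = dataclasses.replace(nh.DEFAULT_CRITERIA, precursor_min=40, mfe_max=-60.0)
        pre = _perfect_hairpin(self.MATURE)
        cand = nh.evaluate_hairpin(self._window(pre, 0), self.MATURE, criteria=crit)
        assert not cand.accepted and cand.reason == "mfe"

    def test_acceptance_monotone_in_mfe_threshold(self):
        """Relaxing mfe_max never un-accepts a candidate."""
        pre = _perfect_hairpin(self.MATURE)
        crit_tight = dataclasses.replace(nh.DEFAULT_CRITERIA, precursor_min=40, mfe_max=-30.0)
        crit_loose = dataclasses.replace(crit_tight, mfe_max=-18.0)
        a = nh.evaluate_hairpin(self._window(pre, 0), self.MATURE, criteria=crit_tight)
        b = nh.evaluate_hairpin(self._window(pre, 0), self.MATURE, criteria=crit_loose)
        assert (not a.accepted) or b.accepted

    def test_star_sequence_is_duplex_partner(self):
        crit = dataclasses.replace(nh.DEFAULT_CRITERIA, precursor_min=40)
        flank = "GATT"
        pre = flank + self.MATURE + "CAACAAGA" + reverse_complement(self.MATURE) + reverse_complement(flank)
        cand = nh.evaluate_hairpin(self._window(pre, len(flank)), self.MATURE, criteria=crit)
        assert cand.accepted
        # the inferred star overlaps the planted complementary arm
        arm_start = len(flank) + len(self.MATURE) + 8
        assert abs(cand.star_offset - arm_start) <= 2


class TestCallNovel:
    def test_planted_hairpins_recovered_and_merged(self, small_dataset):
        ds = small_dataset
        from smallrna_crstress.sequence_io import clean_reads, collapse, merge_tables
        from smallrna_crstress.annotate_known import map_reference

        table = None
        for label, lib in ds.libraries.items():
            cleaned, _ = clean_reads(lib, ds.spec.adapter3)
            t = collapse(cleaned, label)
            table = t if table is None else merge_tables(table, t)
        planted = ds.truth.loci_by_kind("novel")
        present = [p for p in planted if p.sequence in table]
        mapped, _ = map_reference([p.sequence for p in present], ds.reference)
        calls = nh.call_novel(mapped, ds.reference, table)
        assert len(calls) >= 0.9 * len(present)
        # every call sits on a planted hairpin locus
        for c in calls:
            w = c.candidate.window
            assert any(
                p.ref_id == w.ref_id and w.start < p.end and p.start < w.end
                for p in planted
            )

    def test_empty_input_empty_result(self):
        assert nh.call_novel({}, {"c1": "ACGT" * 100}) == []
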