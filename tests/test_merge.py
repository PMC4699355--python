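import numpy as np
import pytest

from circlekit.align import Hit
from circlekit.contig import Contig
from circlekit.local_assembly import LocalUnit
from circlekit.merge import (MergeParams, apply_merge, merge_to_fixpoint,
                             propose_merges)
from circlekit.read_filter import FilterParams
from circlekit.seqio import revcomp
from circlekit.simulate import (Fragmented, RepliconSpec, SimConfig,
                                score_against_truth, simulate)

from conftest import random_seq


def _unit(uid, n):
    return LocalUnit(uid, "A" * n, False, 127)


def _hit(contig_id, uid, rs, re, qs, qe, strand="+"):
    return Hit(contig_id, uid, rs, re, qs, qe, strand, 100.0,
               max(re - rs, qe - qs))


A = Contig("A", "A" * 40_000)
B = Contig("B", "A" * 40_000)


class TestProposeMerges:
    def base_hits(self):
        # 12 kb unit: bases [0,5000) match A's end (ending 500 bp from A's
        # end), bases [7000,12000) match B's start (200 bp in)
        return [_hit("A", "u", 34_500, 39_500, 0, 5000),
                _hit("B", "u", 200, 5200, 7000, 12_000)]

    def test_clean_bridge_accepted(self):
        d = propose_merges([_unit("u", 12_000)], [A, B], self.base_hits())
        assert len(d) == 1 and d[0].accepted
        assert {d[0].left_contig_id, d[0].right_contig_id} == {"A", "B"}

    def test_short_end_match_rejected(self):
        hits = [self.base_hits()[0],
                _hit("B", "u", 200, 3700, 8500, 12_000)]
        d = propose_merges([_unit("u", 12_000)], [A, B], hits)
        assert not d[0].accepted and d[0].reason == "min_match_len"

    def test_both_matches_same_contig_rejected(self):
        hits = [_hit("A", "u", 30_000, 35_000, 0, 5000),
                _hit("A", "u", 200, 5200, 7000, 12_000)]
        d = propose_merges([_unit("u", 12_000)], [A, B], hits)
        assert not d[0].accepted and d[0].reason == "same_contig"

    def test_match_far_from_contig_end_rejected(self):
        hits = [_hit("A", "u", 18_000, 23_000, 0, 5000),  # 17 kb from ends
                self.base_hits()[1]]
        d = propose_merges([_unit("u", 12_000)], [A, B], hits)
        assert not d[0].accepted
        assert d[0].reason in ("contig_end_dist", "orientation")

    def test_longer_match_elsewhere_rejected(self):
        hits = self.base_hits() + [_hit("B", "u", 10_000, 15_500, 3000,
                                        8500)]
        d = propose_merges([_unit("u", 12_000)], [A, B], hits)
        assert not d[0].accepted and d[0].reason == "longer_match_elsewhere"

    def test_match_not_at_unit_end_means_no_candidate(self):
        hits = [_hit("A", "u", 34_500, 39_500, 2000, 7000),
                self.base_hits()[1]]
        d = propose_merges([_unit("u", 12_000)], [A, B], hits,
                           MergeParams(max_unit_end_dist=1000))
        assert not d[0].accepted


class TestApplyMerge:
    def _fixture(self, rng, gap=2000, overlap=0, flip_b=False):
        """Two contigs from one molecule, bridged by a unit covering
        A's tail, the gap and B's head."""
        mol = random_seq(rng, 30_000)
        a_seq = mol[:14_000]
        b_seq = mol[14_000 + gap - overlap:]
        unit_seq = mol[9000:19_000 + gap]
        contigs = [Contig("A", a_seq),
                   Contig("B", revcomp(b_seq) if flip_b else b_seq)]
        unit = LocalUnit("u", unit_seq, False, 127)
        # hit coordinates: unit[0:5000) == A[9000:14000);
        # unit tail == B head (5000 + gap - overlap onwards)
        s_hit = _hit("A", "u", 9000, 14_000, 0, 5000)
        tail = len(unit_seq) - (5000 + gap)
        if flip_b:
            e_hit = Hit("B", "u", len(b_seq) - tail, len(b_seq),
                        5000 + gap, len(unit_seq), "-", 100.0, tail)
        else:
            e_hit = _hit("B", "u", overlap, tail + overlap,
                         5000 + gap, len(unit_seq))
        return mol, contigs, unit, [s_hit, e_hit]

    def test_gap_bridged_exactly(self, rng):
        mol, contigs, unit, hits = self._fixture(rng, gap=2000)
        d = propose_merges([unit], contigs, hits)[0]
        assert d.accepted
        merged = apply_merge(d, contigs, unit)
        assert merged.seq == mol

    def test_overlap_deduplicated(self, rng):
        mol, contigs, unit, hits = self._fixture(rng, gap=0, overlap=1000)
        d = propose_merges([unit], contigs, hits)[0]
        assert d.accepted
        merged = apply_merge(d, contigs, unit)
        assert merged.seq == mol  # shared bases appear once

    def test_reverse_complemented_partner(self, rng):
        mol, contigs, unit, hits = self._fixture(rng, gap=2000, flip_b=True)
        d = propose_merges([unit], contigs, hits)[0]
        assert d.accepted
        merged = apply_merge(d, contigs, unit)
        assert merged.seq in (mol, revcomp(mol))


def scaled_params():
    return (FilterParams(length_cutoff=5000, end_window=2500),
            MergeParams(min_match_len=1000, max_unit_end_dist=1000,
                        max_contig_end_dist=2000))


class TestFixpoint:
    def test_three_fragments_merge_to_one(self):
        ts = simulate(SimConfig(seed=11, replicons=[
            RepliconSpec(30_000, Fragmented(3, 500))]))
        fp, mp = scaled_params()
        contigs, units, log = merge_to_fixpoint(
            ts.contig_objects(), ts.reads, filter_params=fp, merge_params=mp)
        assert len(contigs) == 1
        assert sum(r["merges"] for r in log) == 2
        assert log[-1]["merges"] == 0  # fixpoint reached

    def test_no_cross_replicon_merge(self):
        ts = simulate(SimConfig(seed=12, replicons=[
            RepliconSpec(16_000, Fragmented(2, 400)),
            RepliconSpec(12_000, Fragmented(2, 400))]))
        fp, mp = scaled_params()
        contigs, units, log = merge_to_fixpoint(
            ts.contig_objects(), ts.reads, filter_params=fp, merge_params=mp)
        assert len(contigs) == 2
        for c in contigs:
            parents = {p.split(":")[1].split("+")[0].split(".")[0]
                       for p in c.provenance if p.startswith("merged_from")}
            assert len(parents) <= 1  # never mixes rep0 and rep1 pieces

    def test_single_contig_is_immediate_fixpoint(self, rng):
        c = Contig("only", random_seq(rng, 20_000))
        reads = [c]  # a single "read" suffices; no merge is possible
        contigs, units, log = merge_to_fixpoint(
            [c], [type("R", (), {"id": "r", "seq": c.seq[:2000]})()],
            filter_params=FilterParams())
        assert [x.seq for x in contigs] == [c.seq]
        assert log[-1]["merges"] == 0

    def test_contig_order_invariance(self):
        ts = simulate(SimConfig(seed=13, replicons=[
            RepliconSpec(24_000, Fragmented(3, 400))]))
        fp, mp = scaled_params()
        out1, _, _ = merge_to_fixpoint(ts.contig_objects(), ts.reads,
                                       filter_params=fp, merge_params=mp)
        shuffled = ts.contig_objects()[::-1]
        out2, _, _ = merge_to_fixpoint(shuffled, ts.reads,
                                       filter_params=fp, merge_params=mp)
        canon = lambda cs: sorted(min(c.seq, revcomp(c.seq)) for c in cs)
        assert canon(out1) == canon(out2)

    def test_sequence_content_conserved(self):
        ts = simulate(SimConfig(seed=11, replicons=[
            RepliconSpec(30_000, Fragmented(3, 500))]))
        fp, mp = scaled_params()
        contigs, _, _ = merge_to_fixpoint(ts.contig_objects(), ts.reads,
                                          filter_params=fp, merge_params=mp)
        truth = ts.replicons[0].seq
        doubled = truth + truth
        for c in contigs:
            assert c.seq in doubled or revcomp(c.seq) in doubled
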