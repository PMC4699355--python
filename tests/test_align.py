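import edlib
import numpy as np
import pytest

from circlekit.align import (AlignParams, Hit, align_all, align_translated,
                             filter_hits, read_coords, write_coords)
from circlekit.seqio import SeqRecord, revcomp

from conftest import random_seq


@pytest.fixture
def ref5k(rng):
    return SeqRecord("ref", random_seq(rng, 5000))


class TestAlignAll:
    def test_self_alignment_full_hit(self, ref5k):
        hits = align_all([ref5k], [SeqRecord("q", ref5k.seq)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.ref_start, h.ref_end) == (0, 5000)
        assert (h.qry_start, h.qry_end) == (0, 5000)
        assert h.strand == "+" and h.pct_id == 100.0

    def test_planted_revcomp_interval(self, ref5k):
        qry = SeqRecord("q", revcomp(ref5k.seq[1000:3000]))
        hits = align_all([ref5k], [qry])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        assert (h.ref_start, h.ref_end) == (1000, 3000)
        assert (h.qry_start, h.qry_end) == (0, 2000)
        assert h.pct_id == 100.0

    def test_mutated_query_recovery_vs_edit_distance_oracle(self, rng, ref5k):
        # 3 % substitutions: recovered at the 95 % identity threshold with
        # near-full coverage; a 99 % threshold drops coverage
        seq = np.frombuffer(ref5k.seq.encode(), np.uint8).copy()
        pos = rng.choice(5000, size=150, replace=False)
        for i in pos:
            seq[i] = ord("ACGT"[(b"ACGT".index(seq[i]) + 1) % 4])
        qry = SeqRecord("q", seq.tobytes().decode())
        oracle_id = 100 * (1 - edlib.align(qry.seq, ref5k.seq)["editDistance"] / 5000)
        assert oracle_id >= 95.0

        hits = align_all([ref5k], [qry], AlignParams(min_pct_id=95.0))
        cov = sum(h.ref_end - h.ref_start for h in hits)
        assert cov >= 0.95 * 5000
        assert all(h.pct_id >= 95.0 for h in hits)

        strict = align_all([ref5k], [qry], AlignParams(min_pct_id=99.0))
        assert sum(h.ref_end - h.ref_start for h in strict) < cov

    def test_planted_interval_recovery_matches_oracle(self, rng):
        # every planted high-identity interval of sufficient length is
        # recovered with near-exact coordinates (exact for clean plants)
        ref = SeqRecord("r", random_seq(rng, 2000))
        for start, end in ((0, 400), (700, 1500), (1600, 2000)):
            qry = SeqRecord("q", ref.seq[start:end])
            hits = align_all([ref], [qry], AlignParams(min_hit_len=200))
            spans = [(h.ref_start, h.ref_end) for h in hits]
            assert (start, end) in spans

    def test_strand_symmetry(self, rng):
        ref = SeqRecord("r", random_seq(rng, 3000))
        q = SeqRecord("q", ref.seq[500:2500])
        fwd = align_all([ref], [q])
        rev = align_all([ref], [SeqRecord("q", revcomp(q.seq))])
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f.ref_start, f.ref_end) == (r.ref_start, r.ref_end)
        assert {f.strand, r.strand} == {"+", "-"}
        assert (r.qry_start, r.qry_end) == (len(q.seq) - f.qry_end,
                                            len(q.seq) - f.qry_start)

    def test_empty_inputs_rejected(self, ref5k):
        with pytest.raises(ValueError):
            align_all([], [ref5k])

    def test_breaklen_bridges_small_gap_but_not_large(self, rng):
        # a diverged patch shorter than breaklen is bridged into one hit;
        # a patch far larger than breaklen splits the alignment
        left = random_seq(rng, 2000)
        right = random_seq(rng, 2000)
        patch = random_seq(rng, 300)
        ref = SeqRecord("r", left + patch + right)
        qry = SeqRecord("q", left + random_seq(rng, 300) + right)
        one = align_all([ref], [qry], AlignParams(min_pct_id=80, breaklen=500))
        assert any(h.ref_end - h.ref_start >= 4000 for h in one)
        split = align_all([ref], [qry], AlignParams(min_pct_id=80, breaklen=50))
        assert all(h.ref_end - h.ref_start < 4000 for h in split)


class TestFilterHits:
    def _hit(self, pct):
        return Hit("r", "q", 0, 100, 0, 100, "+", pct, 100)

    def test_threshold_95_default_convention(self):
        hits = [self._hit(96.0), self._hit(94.0)]
        assert filter_hits(hits, 95.0) == [hits[0]]

    def test_boundary_and_identity(self):
        hits = [self._hit(95.0), self._hit(100.0)]
        assert filter_hits(hits, 95.0) == hits       # >= keeps the boundary
        assert filter_hits(hits, 0.0) == hits
        assert filter_hits([self._hit(100.0)], 100.0) == [self._hit(100.0)]

    def test_idempotent(self):
        hits = [self._hit(p) for p in (90.0, 95.0, 99.5)]
        once = filter_hits(hits, 95.0)
        assert filter_hits(once, 95.0) == once


class TestCoords:
    def test_forward_and_reverse_encoding(self, tmp_path):
        hits = [Hit("r", "q", 0, 100, 0, 100, "+", 100.0, 100),
                Hit("r", "q", 5, 105, 0, 100, "-", 98.5, 100)]
        p = tmp_path / "h.coords"
        write_coords(hits, str(p))
        rows = [l.split("\t") for l in p.read_text().splitlines()]
        assert rows[0][:4] == ["1", "100", "1", "100"]
        assert rows[1][:4] == ["6", "105", "100", "1"]   # qry_start > qry_end
        assert read_coords(str(p)) == hits

    def test_malformed_row_names_row_number(self, tmp_path):
        p = tmp_path / "bad.coords"
        p.write_text("1\t100\t1\t100\t100\t100\t99.00\t0\t0\t1\ta\tb\nnot\ta\trow\n")
        with pytest.raises(ValueError, match="row 2"):
            read_coords(str(p))


class TestTranslatedSearch:
    def _gene(self, rng, n_codons=100):
        stops = {"TAA", "TAG", "TGA"}
        codons = ["ATG"]
        while len(codons) < n_codons:
            c = random_seq(rng, 3)
            if c not in stops:
                codons.append(c)
        return "".join(codons) + "TAA"

    def test_planted_gene_forward(self, rng):
        gene = self._gene(rng)
        contig = SeqRecord(
            "c", random_seq(rng, 300) + gene + random_seq(rng, 400))
        hits = align_translated(contig, [SeqRecord("g", gene)], 80.0)
        assert any(h.ref_start == 300 and h.strand == "+"
                   and h.pct_id == 100.0 for h in hits)

    def test_planted_gene_reverse(self, rng):
        gene = self._gene(rng)
        contig = SeqRecord(
            "c", random_seq(rng, 300) + revcomp(gene) + random_seq(rng, 400))
        hits = align_translated(contig, [SeqRecord("g", gene)], 80.0)
        # the coding part minus the stop codon, which on '-' hits sits at
        # the low end of the forward-strand interval
        assert any(h.strand == "-" and h.ref_start == 303
                   and h.ref_end == 300 + len(gene) for h in hits)

    def test_synonymous_changes_keep_protein_identity(self, rng):
        # swap leucine codons CTT->CTG (same amino acid): nucleotide
        # identity drops but amino-acid identity stays 100
        codons = ["ATG"] + ["CTT"] * 60 + ["GAT"] * 40
        gene = "".join(codons) + "TAA"
        mutated = gene.replace("CTT", "CTG")
        contig = SeqRecord("c", random_seq(rng, 99) + mutated
                           + random_seq(rng, 99))
        hits = align_translated(contig, [SeqRecord("g", gene)], 80.0)
        assert any(h.pct_id == 100.0 and h.strand == "+" for h in hits)
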