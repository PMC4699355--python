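"""Local alignment hits between sequence sets, plus coords-table I/O.

A single seed–chain–extend engine stands in for the three external aligners
a production circularization workflow would call (read mapper, genome
matcher, translated gene search).  k-mer anchors are collected with numpy,
chained along near-constant diagonals (anchors whose diagonal offsets
differ by more than ``diagdiff`` are never merged into one cluster), and
gaps of up to ``breaklen`` bases on either sequence are bridged into one
hit, emulating the extension behaviour that helps alignments cross poorly
aligned regions.  Percent identity of each final hit is measured with a
global edit-distance alignment of the matched intervals (edlib).

Hits are emitted in the column order of ``show-coords -dTlro`` style
tables; reverse-strand hits are encoded there by a query start greater
than the query end, as MUMmer does.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq as _BioSeq

from .seqio import SeqRecord, revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_MAX_KMER_OCC = 64  # seeds more repetitive than this are not anchored


@dataclass(frozen=True)
class Hit:
    """One local alignment between a query and a reference interval.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; ``strand == '-'`` means the reverse complement of the query
    interval aligns to the reference interval.  ``aln_len`` is the larger
    of the two interval lengths.
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    pct_id: float
    aln_len: int

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start


@dataclass
class AlignParams:
    """Engine parameters.

    ``min_pct_id`` and ``breaklen`` carry the conventional defaults of the
    genome-matching step (delta-filter -i 95, nucmer -b 500); the nanopore
    preset relaxes them to 85 / 1000.
    """

    min_pct_id: float = 95.0
    breaklen: int = 500
    seed_k: int = 15
    min_hit_len: int = 100
    diagdiff: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.min_pct_id <= 100:
            raise ValueError("min_pct_id must be in (0, 100]")
        if self.breaklen < 0:
            raise ValueError("breaklen must be >= 0")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; k-mers containing N are coded as -1."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ weights
    invalid = (win == 4).any(axis=1)
    vals[invalid] = -1
    return vals


class _RefIndex:
    def __init__(self, refs: Sequence[SeqRecord], k: int):
        self.k = k
        self.refs = list(refs)
        kmers, rids, pos = [], [], []
        for ri, ref in enumerate(self.refs):
            v = _kmer_codes(ref.seq, k)
            keep = v >= 0
            kmers.append(v[keep])
            pos.append(np.nonzero(keep)[0])
            rids.append(np.full(keep.sum(), ri, dtype=np.int64))
        allk = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.int64)
        order = np.argsort(allk, kind="stable")
        self.kmers = allk[order]
        self.pos = (np.concatenate(pos) if pos else np.empty(0, np.int64))[order]
        self.rids = (np.concatenate(rids) if rids else np.empty(0, np.int64))[order]

    def anchors(self, qseq: str):
        """(ref_index, ref_pos, qry_pos) anchor arrays for one query."""
        qv = _kmer_codes(qseq, self.k)
        valid = qv >= 0
        qpos_all = np.nonzero(valid)[0]
        qv = qv[valid]
        if qv.size == 0 or self.kmers.size == 0:
            e = np.empty(0, np.int64)
            return e, e, e
        lo = np.searchsorted(self.kmers, qv, side="left")
        hi = np.searchsorted(self.kmers, qv, side="right")
        counts = hi - lo
        counts[counts > _MAX_KMER_OCC] = 0
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e, e
        qrep = np.repeat(qpos_all, counts)
        starts = np.repeat(np.cumsum(counts) - counts, counts)
        idx = np.repeat(lo, counts) + (np.arange(total) - starts)
        return self.rids[idx], self.pos[idx], qrep


def _cluster(rpos: np.ndarray, qpos: np.ndarray, k: int,
             diagdiff: int, breaklen: int):
    """Group anchors into chains; returns per-cluster interval bounds.

    Anchors are ordered by (diagonal, query position); a new chain starts
    whenever the diagonal jumps by more than ``diagdiff`` or the query
    position jumps forward by more than ``breaklen``.
    """
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    d, q, r = diag[order], qpos[order], rpos[order]
    if d.size == 0:
        return []
    dq = np.diff(q)
    dd = np.diff(d)
    brk = (np.abs(dd) > diagdiff) | (dq > breaklen + k)
    cid = np.concatenate(([0], np.cumsum(brk)))
    out = []
    for c in range(cid[-1] + 1):
        m = cid == c
        out.append((int(r[m].min()), int(r[m].max()) + k,
                    int(q[m].min()), int(q[m].max()) + k))
    return out


def _identity(a: str, b: str) -> float:
    """Percent identity from a global edit-distance alignment (unrounded)."""
    if a == b:
        return 100.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    cols = max(len(a), len(b))
    return 100.0 * (1.0 - d / cols)


def align_all(refs: Sequence[SeqRecord], qrys: Sequence[SeqRecord],
              params: AlignParams | None = None) -> list[Hit]:
    """Maximal chained local alignments between two sequence sets.

    Both strands of every query are searched against every reference.
    Every returned hit satisfies ``pct_id >= params.min_pct_id`` and
    ``aln_len >= params.min_hit_len``.
    """
    if params is None:
        params = AlignParams()
    if not refs or not qrys:
        raise ValueError("align_all requires non-empty inputs")
    k = params.seed_k
    index = _RefIndex(refs, k)
    hits: list[Hit] = []
    for qry in qrys:
        qlen = len(qry.seq)
        for strand, qseq in (("+", qry.seq), ("-", revcomp(qry.seq))):
            rids, rpos, qpos = index.anchors(qseq)
            for ri in np.unique(rids):
                m = rids == ri
                ref = index.refs[int(ri)]
                for rs, re, qs, qe in _cluster(
                        rpos[m], qpos[m], k, params.diagdiff, params.breaklen):
                    if strand == "-":
                        fqs, fqe = qlen - qe, qlen - qs
                        qseg = revcomp(qry.seq[fqs:fqe])
                    else:
                        fqs, fqe = qs, qe
                        qseg = qry.seq[fqs:fqe]
                    aln_len = max(re - rs, fqe - fqs)
                    if aln_len < params.min_hit_len:
                        continue
                    pct = _identity(ref.seq[rs:re], qseg)
                    if pct < params.min_pct_id:
                        continue
                    hits.append(Hit(ref.id, qry.id, rs, re, fqs, fqe,
                                    strand, pct, aln_len))
    # deterministic order: by ref, then ref interval, then query
    hits.sort(key=lambda h: (h.ref_id, h.ref_start, h.ref_end,
                             h.qry_id, h.qry_start, h.strand))
    return hits


def filter_hits(hits: Iterable[Hit], min_pct_id: float) -> list[Hit]:
    """Retain hits with identity at least ``min_pct_id``, order preserved."""
    return [h for h in hits if h.pct_id >= min_pct_id]


def is_self_identity(h: Hit) -> bool:
    """True for the trivial full self-match of a sequence against itself."""
    return (h.ref_id == h.qry_id and h.strand == "+"
            and h.ref_start == h.qry_start and h.ref_end == h.qry_end)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


COORDS_COLUMNS = ("ref_start", "ref_end", "qry_start", "qry_end",
                  "ref_len_aln", "qry_len_aln", "pct_id",
                  "ref_len", "qry_len", "strand", "ref_id", "qry_id")


def write_coords(hits: Iterable[Hit], path: str,
                 ref_lens: dict[str, int] | None = None,
                 qry_lens: dict[str, int] | None = None) -> None:
    """Write a tab-delimited coords table (1-based inclusive coordinates).

    Reverse-strand hits are encoded with qry_start > qry_end.  Sequence
    lengths are written when provided, otherwise 0.
    """
    ref_lens = ref_lens or {}
    qry_lens = qry_lens or {}
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                q1, q2 = h.qry_start + 1, h.qry_end
            else:
                q1, q2 = h.qry_end, h.qry_start + 1
            row = (h.ref_start + 1, h.ref_end, q1, q2,
                   h.ref_len, h.qry_len, f"{_round2(h.pct_id):.2f}",
                   ref_lens.get(h.ref_id, 0), qry_lens.get(h.qry_id, 0),
                   1 if h.strand == "+" else -1, h.ref_id, h.qry_id)
            fh.write("\t".join(str(c) for c in row) + "\n")


def read_coords(path: str) -> list[Hit]:
    """Inverse of :func:`write_coords`."""
    hits = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                r1, r2, q1, q2 = (int(f[0]), int(f[1]), int(f[2]), int(f[3]))
                pct = float(f[6])
                ref_id, qry_id = f[10], f[11]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row {n}: {exc}") from exc
            if q1 <= q2:
                strand, qs, qe = "+", q1 - 1, q2
            else:
                strand, qs, qe = "-", q2 - 1, q1
            rs, re = r1 - 1, r2
            hits.append(Hit(ref_id, qry_id, rs, re, qs, qe, strand, pct,
                            max(re - rs, qe - qs)))
    return hits


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(_BioSeq(seq[:n]).translate())


def align_translated(contig: SeqRecord, genes: Sequence[SeqRecord],
                     min_pct_id: float = 80.0) -> list[Hit]:
    """Six-frame translated search of gene sequences against a contig.

    Genes are nucleotide sequences; each is translated and searched (as an
    infix, i.e. over its full protein length) against the six frame
    translations of the contig.  Hits are reported in contig nucleotide
    coordinates with frame-consistent strand; percent identity is measured
    on amino acids.  Only full-gene-length placements are reported.
    """
    n = len(contig.seq)
    frames = []
    for f in range(3):
        frames.append(("+", f, _translate(contig.seq[f:])))
    rc = revcomp(contig.seq)
    for f in range(3):
        frames.append(("-", f, _translate(rc[f:])))
    hits: list[Hit] = []
    for gene in genes:
        if len(gene.seq) < 3:
            raise ValueError(f"gene {gene.id!r} shorter than one codon")
        prot = _translate(gene.seq).rstrip("*")
        if not prot:
            continue
        for strand, f, fprot in frames:
            if len(fprot) < len(prot):
                continue
            res = edlib.align(prot, fprot, mode="HW", task="locations")
            d = res["editDistance"]
            pct = 100.0 * (1.0 - d / len(prot))
            if pct < min_pct_id:
                continue
            seen = set()
            for (s_aa, e_aa) in res["locations"]:
                if s_aa is None:
                    s_aa = 0
                if (s_aa, e_aa) in seen:
                    continue
                seen.add((s_aa, e_aa))
                nt_s = f + 3 * s_aa
                nt_e = f + 3 * (e_aa + 1)
                if strand == "-":
                    nt_s, nt_e = n - nt_e, n - nt_s
                hits.append(Hit(contig.id, gene.id, nt_s, nt_e,
                                0, len(gene.seq), strand, pct, nt_e - nt_s))
    hits.sort(key=lambda h: (h.ref_start, h.qry_id, h.strand))
    return hits
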