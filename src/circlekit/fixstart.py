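"""Rotate circular contigs to begin at an anchor gene.

Bacterial chromosomes are conventionally reported starting at *dnaA*,
which sits near the origin of replication in most species.  Each circular
contig is searched, in translated (protein) space, against a user-supplied
nucleotide gene database; the first match covering the entire length of
any gene at >= 80 % amino-acid identity wins, and the contig is rotated
(reverse complemented first if the gene lies on the reverse strand) so
that it starts with that gene on its forward strand.  The search runs on
the doubled contig so a gene straddling the current origin is still found.

If no full-length anchor match exists, the start of a predicted open
reading frame nearest the middle of the contig is used instead.  ORFs are
called with a minimal finder (ATG/GTG/TTG to stop, both strands, >= 300 nt,
standard code) and predictions touching either contig end are excluded —
an artificial linearization point must not attract the new origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import align_translated
from .contig import Contig
from .seqio import SeqRecord, revcomp, rotate

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
MIN_ORF_LEN = 300


@dataclass
class GeneMatch:
    gene_id: str
    contig_id: str
    contig_start: int     # 0-based nucleotide position of the gene's first base
    strand: str
    pct_id: float         # amino-acid identity
    spans_full_gene: bool
    gene_len: int


def find_anchor(contig: Contig, genes: Sequence[SeqRecord],
                min_pct_id: float = 80.0) -> GeneMatch | None:
    """First full-gene-length translated match on the circular contig.

    Tie order is (contig position, gene file order).
    """
    if not contig.circular:
        raise ValueError("anchor search applies to circular contigs only")
    n = len(contig)
    doubled = SeqRecord(contig.id, contig.seq + contig.seq)
    gene_order = {g.id: i for i, g in enumerate(genes)}
    best = None
    for h in align_translated(doubled, genes, min_pct_id):
        if h.ref_start >= n:
            continue  # duplicate placement in the second copy
        key = (h.ref_start, gene_order[h.qry_id])
        if best is None or key < best[0]:
            best = (key, GeneMatch(h.qry_id, contig.id, h.ref_start % n,
                                   h.strand, h.pct_id, True,
                                   h.ref_end - h.ref_start))
    return best[1] if best else None


def rotate_to_anchor(contig: Contig, match: GeneMatch) -> Contig:
    """Start the contig at the anchor gene's first base, forward strand."""
    if not contig.circular:
        raise ValueError("only circular contigs are rotated")
    n = len(contig)
    seq = contig.seq
    flipped = False
    if match.strand == "-":
        seq = revcomp(seq)
        flipped = True
        offset = (n - (match.contig_start + match.gene_len)) % n
    else:
        offset = match.contig_start % n
    seq = rotate(seq, offset)
    ev = f"rotated:anchor:{match.gene_id}:offset={offset}:flipped={flipped}"
    return Contig(contig.id, seq, circular=True,
                  provenance=contig.provenance + (ev,))


def find_orfs(seq: str, min_len: int = MIN_ORF_LEN) -> list[tuple[int, int, str]]:
    """(start, end, strand) of ORFs start-codon→stop, both strands,
    reported in forward-strand coordinates (end exclusive, stop included)."""
    n = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            open_at = None
            while i + 3 <= n:
                codon = s[i:i + 3]
                if open_at is None and codon in START_CODONS:
                    open_at = i
                elif open_at is not None and codon in STOP_CODONS:
                    if i + 3 - open_at >= min_len:
                        if strand == "+":
                            out.append((open_at, i + 3, "+"))
                        else:
                            out.append((n - (i + 3), n - open_at, "-"))
                    open_at = None
                i += 3
    out.sort()
    return out


def fallback_middle_gene(contig: Contig) -> tuple[int, str] | None:
    """Offset and strand of the predicted ORF start nearest the contig
    middle; ORFs abutting either end are excluded.  None if no ORF."""
    n = len(contig)
    mid = n / 2
    cands = []
    for s, e, strand in find_orfs(contig.seq):
        if s <= 0 or e >= n:
            continue  # prediction touching a contig end
        start = s if strand == "+" else e  # gene's first base
        pos = s if strand == "+" else e - 1
        cands.append((abs(pos - mid), 0 if strand == "+" else 1,
                      pos, start, strand))
    if not cands:
        return None
    cands.sort()
    _, _, _, start, strand = cands[0]
    return start, strand


def fix_starts(contigs: Sequence[Contig], genes: Sequence[SeqRecord],
               min_pct_id: float = 80.0
               ) -> tuple[list[Contig], list[dict]]:
    """Rotate every circular contig; linear contigs pass through.

    Returns the contigs plus one report row per contig with the method
    used (anchor, middle_orf or none), the offset and the strand flip.
    """
    out, report = [], []
    for c in contigs:
        if not c.circular:
            out.append(c)
            report.append({"contig": c.id, "method": "not_circular",
                           "offset": 0, "strand_flipped": False})
            continue
        m = find_anchor(c, genes, min_pct_id) if genes else None
        if m is not None:
            rc = rotate_to_anchor(c, m)
            out.append(rc)
            report.append({"contig": c.id, "method": "anchor",
                           "gene": m.gene_id,
                           "offset": m.contig_start,
                           "strand_flipped": m.strand == "-"})
            continue
        fb = fallback_middle_gene(c)
        if fb is None:
            out.append(c)
            report.append({"contig": c.id, "method": "none",
                           "offset": 0, "strand_flipped": False})
            continue
        start, strand = fb
        seq = c.seq
        flipped = strand == "-"
        if flipped:
            seq = revcomp(seq)
            start = len(c) - start
        seq = rotate(seq, start % len(c))
        out.append(Contig(c.id, seq, circular=True,
                          provenance=c.provenance
                          + (f"rotated:middle_orf:offset={start}",)))
        report.append({"contig": c.id, "method": "middle_orf",
                       "offset": start, "strand_flipped": flipped})
    return out, report
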