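"""The two optimized overlap-only circularization methods used for
comparison with the read-evidence pipeline.

Both operate purely on sequence self-similarity — no read evidence — and
are defined by their decision logic, which is reproduced here over the
package's own alignment engine.

``iterative_end_trim`` repeatedly self-aligns a contig and, whenever a
disjoint overlap pairs the contig's start with its end, removes the
duplicated prefix, iterating to a fixpoint.  Run iteratively it fully
collapses tandem multi-copy contigs, but it will also happily "circularize"
a linear contig whose ends merely share a repeat.

``split_merge_circularize`` models the split-in-half-and-remerge protocol:
each contig is broken at its midpoint and the two halves are merged back
through their overlaps.  If the halves reunite into a single sequence the
contig is deemed circular, with the end-start duplication collapsed once.
On tandem multi-copy contigs only the outermost duplication is recognized,
so more than one copy of the true sequence survives — the documented
failure mode of this approach.  Every contig is treated independently, and
any internal failure simply retains the original contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignParams, align_all, is_self_identity
from .contig import Contig
from .seqio import SeqRecord

DEFAULT_MIN_OVERLAP_LEN = 2000  # declared default; avoids short-repeat trims
_END_SLACK = 100  # an overlap must reach this close to the sequence ends


def _end_overlap(seq_a: str, seq_b: str, min_len: int, min_pct_id: float,
                 ) -> int | None:
    """Length of a suffix(seq_a)/prefix(seq_b) overlap, if one exists."""
    params = AlignParams(min_pct_id=min_pct_id, min_hit_len=min_len)
    a = SeqRecord("a", seq_a)
    b = SeqRecord("b", seq_b)
    if len(seq_a) <= params.seed_k or len(seq_b) <= params.seed_k:
        return None
    best = None
    for h in align_all([a], [b], params):
        if h.strand != "+":
            continue
        if len(seq_a) - h.ref_end > _END_SLACK or h.qry_start > _END_SLACK:
            continue
        if best is None or h.aln_len > best:
            best = h.aln_len
    return best


def _start_end_dup(seq: str, min_len: int, min_pct_id: float) -> int | None:
    """End position (on the prefix copy) of a disjoint start/end repeat."""
    params = AlignParams(min_pct_id=min_pct_id, min_hit_len=min_len)
    rec = SeqRecord("c", seq)
    if len(seq) <= params.seed_k:
        return None
    best = None
    for h in align_all([rec], [rec], params):
        if h.strand != "+" or is_self_identity(h):
            continue
        first = (h.ref_start, h.ref_end)
        second = (h.qry_start, h.qry_end)
        if first > second:
            first, second = second, first
        if first[1] > second[0]:
            continue  # the two copies overlap each other: not an end repeat
        if first[0] > _END_SLACK or len(seq) - second[1] > _END_SLACK:
            continue
        if best is None or first[1] > best:
            best = first[1]
    return best


def iterative_end_trim(contig: Contig,
                       min_overlap_len: int = DEFAULT_MIN_OVERLAP_LEN,
                       min_pct_id: float = 95.0
                       ) -> tuple[Contig, bool, int]:
    """Trim duplicated start sequence until no start/end overlap remains.

    Returns (contig, circular, n_trims); circular is True iff at least one
    trim occurred.
    """
    seq = contig.seq
    n_trims = 0
    while True:
        cut = _start_end_dup(seq, min_overlap_len, min_pct_id)
        if cut is None or cut <= 0 or cut >= len(seq):
            break
        seq = seq[cut:]
        n_trims += 1
    if n_trims == 0:
        return contig, False, 0
    out = Contig(contig.id, seq, circular=True,
                 provenance=contig.provenance
                 + (f"end_trimmed:x{n_trims}",))
    return out, True, n_trims


def split_merge_circularize(contigs: Sequence[Contig],
                            min_overlap_len: int = DEFAULT_MIN_OVERLAP_LEN,
                            min_pct_id: float = 95.0,
                            premerge: bool = False) -> list[Contig]:
    """Split each contig in half and remerge the halves through their
    overlaps; a reunited single sequence is flagged circular, otherwise
    the original contig is retained.

    ``premerge`` optionally first joins input contigs that share an
    end overlap, pairwise, before the per-contig split step.
    """
    work = list(contigs)
    if premerge:
        work = _premerge_overlapping(work, min_overlap_len, min_pct_id)
    out = []
    for c in work:
        out.append(_split_merge_one(c, min_overlap_len, min_pct_id))
    return out


def _split_merge_one(contig: Contig, min_overlap_len: int,
                     min_pct_id: float) -> Contig:
    n = len(contig)
    half = n // 2
    if half <= min_overlap_len:
        return contig
    h1, h2 = contig.seq[:half], contig.seq[half:]
    # the halves always share the original split point; a circular contig
    # additionally overlaps h2's end with h1's start.  Rebuild through
    # that circular junction: one merged sequence means circularity.
    ov = _end_overlap(h2, h1, min_overlap_len, min_pct_id)
    if ov is None or ov >= min(len(h1), len(h2)):
        return contig  # failure or no junction: original retained
    merged = h2 + h1[ov:]
    return Contig(contig.id, merged, circular=True,
                  provenance=contig.provenance + ("split_merge",))


def _premerge_overlapping(contigs: list[Contig], min_overlap_len: int,
                          min_pct_id: float) -> list[Contig]:
    work = list(contigs)
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(len(work)):
                if i == j:
                    continue
                ov = _end_overlap(work[i].seq, work[j].seq,
                                  min_overlap_len, min_pct_id)
                if ov is not None and ov < min(len(work[i]), len(work[j])):
                    merged = Contig(
                        f"{work[i].id}.{work[j].id}",
                        work[i].seq + work[j].seq[ov:],
                        provenance=(f"premerged:{work[i].id}+{work[j].id}",))
                    work = [c for k, c in enumerate(work) if k not in (i, j)]
                    work.append(merged)
                    changed = True
                    break
            if changed:
                break
    return work
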