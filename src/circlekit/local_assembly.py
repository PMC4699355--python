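"""Greedy overlap assembly of filtered reads, with circularity detection.

Corrected long reads are high identity, so a desk-scale local assembler
can work with exact overlaps: reads are joined whenever the suffix of the
growing unitig exactly matches a read prefix (either orientation) by at
least the current overlap length ``k``.  The overlap length starts at the
top of a descending ladder (127 down to 71 by default) and is lowered only
if no unitig at least as long as the longest read is produced, mirroring
how a reassembly k-mer is reduced when coverage is too low.

Extension is conservative, with unitig semantics: if two candidate reads
disagree about the sequence beyond the current end, extension stops.  A
unitig whose extension walks back into a read it has already used has gone
around a circle; it is emitted with ``circular=True`` and the duplicated
closure bases removed, so a circular unit stores exactly one period.  A
single read spanning a small circle more than once is collapsed to its
minimal period the same way.

Externally assembled FASTA can be slotted in instead; circularity is then
encoded as a ``circular=true`` token in the description line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import SeqRecord, revcomp

DEFAULT_K_LADDER = (127, 121, 111, 101, 95, 91, 85, 81, 75, 71)


@dataclass
class LocalUnit:
    id: str
    seq: str
    circular: bool
    k_used: int

    def __len__(self) -> int:
        return len(self.seq)

    def to_seqrecord(self) -> SeqRecord:
        desc = "circular=true" if self.circular else "circular=false"
        return SeqRecord(self.id, self.seq, desc=desc)


@dataclass
class AssembleParams:
    k_ladder: tuple[int, ...] = DEFAULT_K_LADDER
    min_overlap_id: float = 95.0

    def __post_init__(self) -> None:
        lad = tuple(self.k_ladder)
        if any(b >= a for a, b in zip(lad, lad[1:])):
            raise ValueError("k_ladder must be strictly decreasing")
        if any(k < 21 for k in lad):
            raise ValueError("k_ladder values must be >= 21")
        self.k_ladder = lad


def _prefix_suffix_overlap(s: str) -> int:
    """Length of the longest proper prefix of ``s`` that is also a suffix
    (KMP failure function of the last position)."""
    n = len(s)
    pi = [0] * n
    j = 0
    for i in range(1, n):
        c = s[i]
        while j and s[j] != c:
            j = pi[j - 1]
        if s[j] == c:
            j += 1
        pi[i] = j
    return pi[-1] if n else 0


def _closure_depth_check(period: str, read_seqs: list[str],
                         window: int = 500, max_ratio: float = 2.2
                         ) -> tuple[bool, int | None]:
    """Read-depth guard on a candidate circular closure.

    A genuine circle is covered uniformly by its reads.  A false closure
    through a long repeat shared by both ends of a linear molecule carries
    the reads of *both* repeat copies on one collapsed region, doubling its
    depth.  The closure is accepted only when no window of the period is
    covered ``max_ratio`` times deeper than the median window.  Reads that
    do not place exactly on the period (errors, other replicons) are
    ignored; with too few placed reads the guard abstains and accepts.
    """
    p = len(period)
    doubled = period + period
    cov = np.zeros(p, dtype=np.int64)
    placed = 0
    for s in read_seqs:
        pos = doubled.find(s)
        if pos < 0:
            pos = doubled.find(revcomp(s))
        if pos < 0:
            continue
        placed += 1
        cov += len(s) // p
        rem = len(s) % p
        start = pos % p
        end = start + rem
        if end <= p:
            cov[start:end] += 1
        else:
            cov[start:] += 1
            cov[:end - p] += 1
    if placed < 4:
        return True, None  # not enough exactly placed reads to judge
    w = min(window, p)
    kern = np.ones(w) / w
    ext = np.concatenate([cov, cov[:w - 1]])
    means = np.convolve(ext, kern, mode="valid")[:p]
    med = np.median(means)
    if med <= 0 or float(means.max()) < max_ratio * med:
        return True, None
    split = (int(np.argmax(means)) + w // 2) % p
    return False, split


class _Candidate:
    __slots__ = ("idx", "orient", "overlap", "ext")

    def __init__(self, idx, orient, overlap, ext):
        self.idx = idx
        self.orient = orient
        self.overlap = overlap
        self.ext = ext


def _extend_right(contig: str, members: set[int], seqs: list[str],
                  rcs: list[str], used: list[bool],
                  pref_idx: dict[str, list[tuple[int, int]]],
                  k: int, max_len: int) -> tuple[str, bool]:
    """Greedy rightward extension; returns (contig, closed_circle)."""
    while True:
        cands: list[_Candidate] = []
        lo = max(0, len(contig) - max_len)
        hi = len(contig) - k
        closure = False
        for p in range(lo, hi + 1):
            for idx, orient in pref_idx.get(contig[p:p + k], ()):
                s = seqs[idx] if orient == 0 else rcs[idx]
                ov = len(contig) - p
                if ov >= len(s):
                    continue
                if contig[p:] != s[:ov]:
                    continue
                if idx in members:
                    closure = True
                    continue
                if used[idx]:
                    return contig, False  # boundary with another unitig
                cands.append(_Candidate(idx, orient, ov, s[ov:]))
        if closure:
            return contig, True
        if not cands:
            return contig, False
        # consistency: every extension must be a prefix of the longest one
        cands.sort(key=lambda c: (-len(c.ext), c.idx))
        longest = cands[0].ext
        for c in cands[1:]:
            if not longest.startswith(c.ext):
                return contig, False  # ambiguous branching: stop unitig
        for c in cands:
            used[c.idx] = True
            members.add(c.idx)
        contig = contig + longest


def _assemble_at_k(seqs: list[str], rcs: list[str], ids: list[str],
                   k: int) -> list[LocalUnit]:
    n = len(seqs)
    max_len = max(len(s) for s in seqs)
    pref_idx: dict[str, list[tuple[int, int]]] = {}
    for i in range(n):
        if len(seqs[i]) >= k:
            pref_idx.setdefault(seqs[i][:k], []).append((i, 0))
            pref_idx.setdefault(rcs[i][:k], []).append((i, 1))
    used = [False] * n
    order = sorted(range(n), key=lambda i: (-len(seqs[i]), seqs[i]))
    units: list[LocalUnit] = []
    for seed in order:
        if used[seed] or len(seqs[seed]) < k:
            continue
        used[seed] = True
        members = {seed}
        contig, closed = _extend_right(seqs[seed], members, seqs, rcs, used,
                                       pref_idx, k, max_len)
        if not closed:
            contig = revcomp(contig)
            contig, closed = _extend_right(contig, members, seqs, rcs, used,
                                           pref_idx, k, max_len)
            contig = revcomp(contig)
        ov = _prefix_suffix_overlap(contig)
        circular = False
        split_at = None
        if ov >= k:
            period = len(contig) - ov
            # without an observed closure, only a read spanning the circle
            # more than once justifies a period collapse; a chance repeat
            # shared by both unitig ends does not
            if closed or period <= max_len:
                ok, split_at = _closure_depth_check(contig[:period], seqs)
                if ok:
                    circular = True
                    contig = contig[:period]
                else:
                    # repeat-induced closure: break the unitig at the
                    # deepest-covered point instead of closing the circle
                    contig = contig[:period]
        if split_at is not None and k <= split_at <= len(contig) - k:
            pieces = [contig[:split_at], contig[split_at:]]
        else:
            pieces = [contig]
        for piece in pieces:
            units.append(LocalUnit(f"unit.{len(units)}", piece, circular, k))
        # absorb unused reads contained in this unitig
        search = contig + contig[: max_len] if circular else contig
        for i in range(n):
            if not used[i] and (seqs[i] in search or rcs[i] in search):
                used[i] = True
    return units


def assemble(reads: Sequence, params: AssembleParams | None = None
             ) -> list[LocalUnit]:
    """Assemble reads into local units, lowering the overlap length down
    the ladder until a unitig at least as long as the longest read appears.
    Returns an empty list (never raises) if nothing assembles."""
    if params is None:
        params = AssembleParams()
    if not reads:
        raise ValueError("assemble requires at least one read")
    # dedupe identical sequences (and pure reverse complements)
    seen: dict[str, int] = {}
    seqs: list[str] = []
    ids: list[str] = []
    for r in sorted(reads, key=lambda r: (-len(r.seq), r.seq, r.id)):
        rc = revcomp(r.seq)
        if r.seq in seen or rc in seen:
            continue
        seen[r.seq] = len(seqs)
        seqs.append(r.seq)
        ids.append(r.id)
    rcs = [revcomp(s) for s in seqs]
    max_read = max(len(s) for s in seqs)
    units: list[LocalUnit] = []
    for k in params.k_ladder:
        units = _assemble_at_k(seqs, rcs, ids, k)
        # an assembly "succeeded" when reads genuinely contiguate: some
        # unitig spans more than two read lengths, or a circle closed
        # (closures may collapse below read length)
        if any(len(u) > 2 * max_read or u.circular for u in units):
            return units
    return units


def units_from_fasta(records: Sequence[SeqRecord]) -> list[LocalUnit]:
    """Interpret externally assembled contigs; ``circular=true`` in the
    description marks circular units."""
    return [LocalUnit(r.id, r.seq, "circular=true" in r.desc, 0)
            for r in records]
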