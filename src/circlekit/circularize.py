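"""Turn contigs that represent circles into single-copy linear form.

Two paths are tried in order, per contig:

**Replacement** — if the contig's matches to one circular local unit cover
at least 95 % of the contig (interval union, so overlaps are not double
counted), all covering matches are to that same unit, and at least one
single match spans at least 95 % of the unit, the contig is replaced by
the unit's sequence.  This collapses tandem multi-copy contigs, whose
every period matches the unit end to end.

**End join** — otherwise, the longest match near the contig start and the
longest near the contig end are identified with the same end-distance
criteria as merging.  If both land on the same unit with consistent
orientations and positions, the contig is trimmed at the two junctions
and closed through the unit's bridging sequence, each junction base
occurring exactly once.  The bridge restores sequence missing from the
contig; a duplicated low-quality end is cut where the end-side match
reaches the start-side match's first unit base.

For a *circular* unit, the unit's own ends are an artifact of its
linearization origin, so the within-1000-bp-of-unit-end criterion is not
applied to it, and a single match chosen for both contig ends is treated
as a self-closure through the unit (wrap-around bridge) rather than
triggering the second-longest substitution used for linear units.

A successfully closed output is finally checked for a residual start/end
self-overlap; if one at least ``min_match_len`` long remains, the
candidate join is rejected and the contig passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import edlib

from .align import AlignParams, Hit, align_all
from .contig import Contig
from .local_assembly import LocalUnit
from .merge import MergeParams, _mirror
from .seqio import SeqRecord, revcomp


@dataclass
class CircularizeParams:
    min_contig_cov: float = 0.95
    min_unit_frac: float = 0.95
    merge: MergeParams = None  # end-match criteria are shared with merging

    def __post_init__(self) -> None:
        if self.merge is None:
            self.merge = MergeParams()
        for name in ("min_contig_cov", "min_unit_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class CircularizeAction:
    contig_id: str
    action: str                 # replaced | end_joined | unchanged
    unit_id: str | None = None
    junctions: tuple[int, int] | None = None


def _union_len(intervals) -> int:
    total, end = 0, -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def circularize_by_replacement(contig: Contig, units: Sequence[LocalUnit],
                               hits: Sequence[Hit],
                               params: CircularizeParams | None = None
                               ) -> Contig | None:
    """Replace the contig by a circular unit it is a (possibly repeated)
    copy of.  ``hits`` map units (query) onto the contig (reference)."""
    if params is None:
        params = CircularizeParams()
    circ_units = {u.id: u for u in units if u.circular}
    cands = []
    for uid, u in circ_units.items():
        uh = [h for h in hits
              if h.qry_id == uid and h.ref_id == contig.id]
        if not uh:
            continue
        cov = _union_len((h.ref_start, h.ref_end) for h in uh)
        if cov < params.min_contig_cov * len(contig):
            continue
        best = max(h.aln_len for h in uh)
        if best < params.min_unit_frac * len(u):
            continue
        cands.append((cov, uid))
    if not cands:
        return None
    # coverage must come from a single circular unit; if several qualify
    # independently take the best covered one
    cands.sort(key=lambda t: (-t[0], t[1]))
    u = circ_units[cands[0][1]]
    return Contig(contig.id, u.seq, circular=True,
                  provenance=contig.provenance + (f"replaced_by:{u.id}",))


def _self_end_overlap(seq: str, min_len: int, params: AlignParams) -> bool:
    """True if the sequence still carries a start/end duplication of at
    least ``min_len`` bases (same strand prefix/suffix repeat)."""
    if len(seq) < 2 * min_len:
        return False
    probe = AlignParams(min_pct_id=params.min_pct_id,
                        breaklen=params.breaklen,
                        seed_k=params.seed_k, min_hit_len=min_len)
    rec = SeqRecord("x", seq)
    for h in align_all([rec], [rec], probe):
        if h.strand != "+" or (h.ref_start, h.ref_end) == (h.qry_start, h.qry_end):
            continue
        a = (h.ref_start, h.ref_end)
        b = (h.qry_start, h.qry_end)
        first, second = (a, b) if a < b else (b, a)
        if first[0] <= probe.breaklen and len(seq) - second[1] <= probe.breaklen:
            return True
    return False


def circularize_by_end_join(contig: Contig, units: Sequence[LocalUnit],
                            hits: Sequence[Hit],
                            params: CircularizeParams | None = None,
                            align_params: AlignParams | None = None
                            ) -> Contig | None:
    if params is None:
        params = CircularizeParams()
    mp = params.merge
    if align_params is None:
        align_params = AlignParams(min_pct_id=mp.min_pct_id,
                                   breaklen=mp.breaklen)
    unit_by_id = {u.id: u for u in units}
    ch = [h for h in hits if h.ref_id == contig.id
          and h.qry_id in unit_by_id]
    n = len(contig)

    def longest(cands, skip=None):
        return max((h for h in cands if h is not skip),
                   key=lambda h: (h.aln_len, h.qry_id, -h.ref_start),
                   default=None)

    start_c = [h for h in ch if h.ref_start <= mp.max_contig_end_dist]
    end_c = [h for h in ch if n - h.ref_end <= mp.max_contig_end_dist]
    s0 = longest(start_c)
    e0 = longest(end_c)
    if s0 is None or e0 is None:
        return None
    # candidate (start, end) pairs, tried in order: the primary pair; on a
    # shared match, the second longest substituted on either side; and, for
    # a circular unit only, the shared match closing through itself
    pairs: list[tuple[Hit, Hit]] = []
    if s0 is not e0:
        pairs.append((s0, e0))
    else:
        e1 = longest(end_c, skip=e0)
        s1 = longest(start_c, skip=s0)
        if e1 is not None:
            pairs.append((s0, e1))
        if s1 is not None:
            pairs.append((s1, e0))
        if unit_by_id[s0.qry_id].circular:
            pairs.append((s0, e0))
    for s_hit, e_hit in pairs:
        if s_hit.qry_id != e_hit.qry_id:
            continue
        out = _attempt_join(contig, unit_by_id[s_hit.qry_id], s_hit, e_hit,
                            mp, align_params)
        if out is not None:
            return out
    return None


def _attempt_join(contig: Contig, unit: LocalUnit, s_hit: Hit, e_hit: Hit,
                  mp: MergeParams, align_params: AlignParams
                  ) -> Contig | None:
    same = s_hit is e_hit
    L = len(unit)
    useq = unit.seq
    # orient the unit so the start-side match is forward
    if s_hit.strand == "-":
        if same:
            s_hit = e_hit = _mirror(s_hit, L)
        else:
            s_hit, e_hit = _mirror(s_hit, L), _mirror(e_hit, L)
        useq = revcomp(useq)
    if s_hit.strand != "+" or e_hit.strand != "+":
        return None
    if not unit.circular:
        if not same and (
                e_hit.qry_start > mp.max_unit_end_dist
                or L - s_hit.qry_end > mp.max_unit_end_dist):
            return None
    cs1, us1 = s_hit.ref_start, s_hit.qry_start
    ce1, ce2 = e_hit.ref_start, e_hit.ref_end
    ue1, ue2 = e_hit.qry_start, e_hit.qry_end

    if not same:
        # both contig ends matching the *same* unit bases is the signature
        # of a repeat shared by the ends, not of a junction: reject pairs
        # where one unit interval contains the other
        s_iv = (s_hit.qry_start, s_hit.qry_end)
        e_iv = (ue1, ue2)
        if ((s_iv[0] >= e_iv[0] and s_iv[1] <= e_iv[1])
                or (e_iv[0] >= s_iv[0] and e_iv[1] <= s_iv[1])):
            return None

    if not same and ue1 <= us1 < ue2:
        # the end-side match runs past the start-side match's first unit
        # base: cut the contig there, no bridge needed
        cut = ce1 + (us1 - ue1)
        if cut <= cs1:
            return None
        seq = contig.seq[cs1:cut]
        junctions = (cs1, cut)
    else:
        if same and (s_hit.qry_end - s_hit.qry_start) < 2 * L / 3:
            # a contig matching the circular unit over a shared single hit
            # may self-close only when it carries most of the circle; a
            # fragment of a replicon is not circularizable
            return None
        if unit.circular:
            gap = (us1 - ue2) % L
            bridge = (useq[ue2:] + useq)[:gap]
        else:
            if us1 < ue2:
                return None
            bridge = useq[ue2:us1]
        seq = contig.seq[cs1:ce2] + bridge
        junctions = (cs1, ce2)
    if len(seq) < 1:
        return None
    # sequence conservation: the trimmed contig ends must be redundant
    # with the resulting circle (duplicated junction sequence); an end
    # join never discards unique sequence
    for piece in (contig.seq[:junctions[0]], contig.seq[junctions[1]:]):
        if len(piece) >= 200 and not _contained_in_circle(piece, seq):
            return None
    if _self_end_overlap(seq, mp.min_match_len, align_params):
        return None
    return Contig(contig.id, seq, circular=True,
                  provenance=contig.provenance
                  + (f"end_joined_via:{unit.id}",))


def _contained_in_circle(piece: str, circle: str,
                         max_divergence: float = 0.1) -> bool:
    """True if ``piece`` aligns near-fully somewhere on the circle."""
    if len(piece) > 2 * len(circle):
        return False
    target = circle + circle
    best = min(
        edlib.align(p, target, mode="HW", task="distance")["editDistance"]
        for p in (piece, revcomp(piece)))
    return best <= max_divergence * len(piece)


def circularize_contigs(contigs: Sequence[Contig],
                        units: Sequence[LocalUnit], hits: Sequence[Hit],
                        params: CircularizeParams | None = None
                        ) -> tuple[list[Contig], list[CircularizeAction]]:
    """Run both circularization paths over every non-circular contig.
    Contigs are modified only when a path fires; otherwise they pass
    through byte identical."""
    if params is None:
        params = CircularizeParams()
    out, actions = [], []
    for c in contigs:
        if c.circular:
            out.append(c)
            actions.append(CircularizeAction(c.id, "unchanged"))
            continue
        rep = circularize_by_replacement(c, units, hits, params)
        if rep is not None:
            out.append(rep)
            actions.append(CircularizeAction(
                c.id, "replaced", rep.provenance[-1].split(":", 1)[1]))
            continue
        ej = circularize_by_end_join(c, units, hits, params)
        if ej is not None:
            out.append(ej)
            actions.append(CircularizeAction(
                c.id, "end_joined", ej.provenance[-1].split(":", 1)[1]))
            continue
        out.append(c)
        actions.append(CircularizeAction(c.id, "unchanged"))
    return out, actions
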