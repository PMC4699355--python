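"""Join original contigs using locally reassembled units, to a fixpoint.

A local unit whose two ends each match a different contig end can bridge
those contigs.  Acceptance of a merge requires, with the stated defaults:
both end-matches at least 4000 bp long, starting/ending within 1000 bp of
the unit's ends, landing within 15,000 bp of a contig end (contig ends are
given more tolerance because they are often low quality), no strictly
longer match to the unit anywhere else, and orientations/positions that
admit a consistent join.  After each applied merge the reads are
re-filtered against the new assembly and the filter → assemble → merge
cycle repeats until an iteration applies no merge.

The "no longer match" rule is read strictly: no hit to the unit, to any
contig, may be strictly longer than the smaller of the two chosen
end-matches.  When several accepted merges touch the same contig in one
iteration, the one with the largest combined match length is applied and
the others wait for the next iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import AlignParams, Hit, align_all
from .contig import Contig
from .local_assembly import AssembleParams, LocalUnit, assemble
from .read_filter import FilterParams, filter_reads
from .seqio import revcomp


@dataclass
class MergeParams:
    min_match_len: int = 4000
    max_unit_end_dist: int = 1000
    max_contig_end_dist: int = 15_000
    min_pct_id: float = 95.0
    breaklen: int = 500
    max_iterations: int = 10

    def __post_init__(self) -> None:
        for name in ("min_match_len", "max_unit_end_dist",
                     "max_contig_end_dist", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class _JoinPlan:
    x_flip: bool
    x_cut: int       # prefix of (possibly flipped) left contig to keep
    y_flip: bool
    y_from: int      # first kept base of (possibly flipped) right contig
    u_flip: bool
    b2: int          # unit position where the left match ends
    c1: int          # unit position where the right match starts


@dataclass
class MergeDecision:
    unit_id: str
    left_contig_id: str | None
    right_contig_id: str | None
    left_hit: Hit | None
    right_hit: Hit | None
    accepted: bool
    reason: str
    plan: _JoinPlan | None = None

    @property
    def combined_len(self) -> int:
        if self.left_hit is None or self.right_hit is None:
            return 0
        return self.left_hit.aln_len + self.right_hit.aln_len


def _mirror(h: Hit, unit_len: int) -> Hit:
    return Hit(h.ref_id, h.qry_id, h.ref_start, h.ref_end,
               unit_len - h.qry_end, unit_len - h.qry_start,
               "-" if h.strand == "+" else "+", h.pct_id, h.aln_len)


def _orient(s_hit: Hit, e_hit: Hit, contig_len: dict[str, int],
            max_cdist: int, u_flip: bool) -> _JoinPlan | None:
    """Geometry for a unit (oriented forward) walking off the end of the
    left contig, through the bridge, into the start of the right contig."""
    lx = contig_len[s_hit.ref_id]
    if s_hit.strand == "+":
        if lx - s_hit.ref_end > max_cdist:
            return None
        x_flip, x_cut = False, s_hit.ref_end
    else:
        if s_hit.ref_start > max_cdist:
            return None
        x_flip, x_cut = True, lx - s_hit.ref_start
    ly = contig_len[e_hit.ref_id]
    if e_hit.strand == "+":
        if e_hit.ref_start > max_cdist:
            return None
        y_flip, y_from = False, e_hit.ref_start
    else:
        if ly - e_hit.ref_end > max_cdist:
            return None
        y_flip, y_from = True, ly - e_hit.ref_end
    return _JoinPlan(x_flip, x_cut, y_flip, y_from, u_flip,
                     s_hit.qry_end, e_hit.qry_start)


def propose_merges(units: Sequence[LocalUnit], contigs: Sequence[Contig],
                   hits: Sequence[Hit],
                   params: MergeParams | None = None) -> list[MergeDecision]:
    """Decide, per unit, whether it can merge two contigs.  ``hits`` map
    units (query) onto contigs (reference)."""
    if params is None:
        params = MergeParams()
    contig_len = {c.id: len(c.seq) for c in contigs}
    by_unit: dict[str, list[Hit]] = {}
    for h in hits:
        by_unit.setdefault(h.qry_id, []).append(h)
    decisions = []
    for u in sorted(units, key=lambda u: u.id):
        hu = by_unit.get(u.id, [])
        L = len(u.seq)

        def longest(cands):
            return max(cands, key=lambda h: (h.aln_len, h.ref_id,
                                             -h.ref_start), default=None)

        s_hit = longest([h for h in hu
                         if h.qry_start <= params.max_unit_end_dist])
        e_hit = longest([h for h in hu
                         if L - h.qry_end <= params.max_unit_end_dist])

        def reject(reason):
            decisions.append(MergeDecision(
                u.id,
                s_hit.ref_id if s_hit else None,
                e_hit.ref_id if e_hit else None,
                s_hit, e_hit, False, reason))

        if s_hit is None or e_hit is None:
            reject("missing_end_match")
            continue
        if s_hit.ref_id == e_hit.ref_id:
            reject("same_contig")
            continue
        if min(s_hit.aln_len, e_hit.aln_len) < params.min_match_len:
            reject("min_match_len")
            continue
        shorter = min(s_hit.aln_len, e_hit.aln_len)
        if any(h.aln_len > shorter for h in hu
               if h is not s_hit and h is not e_hit):
            reject("longer_match_elsewhere")
            continue
        ok_dist = all(
            min(h.ref_start, contig_len[h.ref_id] - h.ref_end)
            <= params.max_contig_end_dist for h in (s_hit, e_hit))
        if not ok_dist:
            reject("contig_end_dist")
            continue
        plan = _orient(s_hit, e_hit, contig_len,
                       params.max_contig_end_dist, u_flip=False)
        if plan is None:
            plan = _orient(_mirror(e_hit, L), _mirror(s_hit, L),
                           contig_len, params.max_contig_end_dist,
                           u_flip=True)
        if plan is None:
            reject("orientation")
            continue
        left = s_hit if not plan.u_flip else e_hit
        right = e_hit if not plan.u_flip else s_hit
        decisions.append(MergeDecision(u.id, left.ref_id, right.ref_id,
                                       left, right, True, "ok", plan))
    return decisions


def apply_merge(decision: MergeDecision, contigs: Sequence[Contig],
                unit: LocalUnit) -> Contig:
    """Build the merged contig for an accepted decision."""
    if not decision.accepted or decision.plan is None:
        raise ValueError("apply_merge requires an accepted decision")
    plan = decision.plan
    by_id = {c.id: c for c in contigs}
    x = by_id[decision.left_contig_id]
    y = by_id[decision.right_contig_id]
    xs = revcomp(x.seq) if plan.x_flip else x.seq
    ys = revcomp(y.seq) if plan.y_flip else y.seq
    us = revcomp(unit.seq) if plan.u_flip else unit.seq
    if plan.c1 >= plan.b2:
        bridge, y_start = us[plan.b2:plan.c1], plan.y_from
    else:
        bridge, y_start = "", plan.y_from + (plan.b2 - plan.c1)
    seq = xs[:plan.x_cut] + bridge + ys[y_start:]
    if not seq:
        raise ValueError("merge produced an empty sequence")
    return Contig(
        id=f"{x.id}.{y.id}", seq=seq, circular=False,
        provenance=x.provenance + y.provenance
        + (f"merged_from:{x.id}+{y.id}:via:{decision.unit_id}",))


def _map_reads(contigs, reads, params: AlignParams):
    read_params = AlignParams(min_pct_id=80.0, breaklen=params.breaklen,
                              seed_k=params.seed_k, min_hit_len=100)
    return align_all(contigs, reads, read_params)


def merge_to_fixpoint(contigs: Sequence[Contig], reads,
                      filter_params: FilterParams | None = None,
                      assemble_params: AssembleParams | None = None,
                      align_params: AlignParams | None = None,
                      merge_params: MergeParams | None = None):
    """Iterate filter → assemble → align → merge until no merge applies.

    Returns ``(contigs, units, log)`` where ``units`` are the last
    iteration's local units (circularization consumes them) and ``log`` is
    one record per iteration.
    """
    filter_params = filter_params or FilterParams()
    assemble_params = assemble_params or AssembleParams()
    merge_params = merge_params or MergeParams()
    if align_params is None:
        align_params = AlignParams(min_pct_id=merge_params.min_pct_id,
                                   breaklen=merge_params.breaklen)
    contigs = list(contigs)
    log = []
    units: list[LocalUnit] = []
    for it in range(1, merge_params.max_iterations + 1):
        if any(len(c) >= filter_params.length_cutoff for c in contigs):
            read_hits = _map_reads(contigs, reads, align_params)
        else:
            read_hits = []
        freads = filter_reads(reads, contigs, read_hits, filter_params)
        if not freads:
            log.append({"iteration": it, "merges": 0,
                        "contigs": len(contigs)})
            break
        units = assemble(freads, assemble_params)
        if not units:
            log.append({"iteration": it, "merges": 0,
                        "contigs": len(contigs)})
            break
        unit_hits = align_all(contigs, units, align_params)
        decisions = propose_merges(units, contigs, unit_hits, merge_params)
        accepted = sorted([d for d in decisions if d.accepted],
                          key=lambda d: (-d.combined_len, d.unit_id))
        unit_by_id = {u.id: u for u in units}
        consumed: set[str] = set()
        applied = 0
        for d in accepted:
            if d.left_contig_id in consumed or d.right_contig_id in consumed:
                continue  # requeued for the next iteration
            merged = apply_merge(d, contigs, unit_by_id[d.unit_id])
            contigs = [c for c in contigs
                       if c.id not in (d.left_contig_id, d.right_contig_id)]
            contigs.append(merged)
            consumed.update((d.left_contig_id, d.right_contig_id, merged.id))
            applied += 1
        log.append({"iteration": it, "merges": applied,
                    "contigs": len(contigs)})
        if applied == 0:
            break
    return contigs, units, log
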