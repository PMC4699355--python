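"""Drop short contigs and remove redundant contained contigs.

A non-circular contig A is contained in contig B when a single alignment
between them has at least 95 % identity and covers at least 95 % of A's
length (one hit must meet the length bar on its own; interval unions are
not summed).  The containment relation is closed transitively, mutual
containment classes are collapsed to their longest member (ties broken by
id), and every remaining contig contained in a survivor is removed.
Circular contigs are exempt from containment removal but not from the
minimum-length filter, which runs first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .align import Hit, is_self_identity
from .contig import Contig


@dataclass
class RefineParams:
    min_contig_len: int = 2000
    containment_min_id: float = 95.0
    containment_min_frac: float = 0.95

    def __post_init__(self) -> None:
        if self.min_contig_len <= 0:
            raise ValueError("min_contig_len must be positive")
        if not 0 < self.containment_min_frac <= 1:
            raise ValueError("containment_min_frac must be in (0, 1]")


def drop_short(contigs: Sequence[Contig], min_contig_len: int = 2000
               ) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Remove contigs shorter than ``min_contig_len``; returns the kept
    contigs and a removal log of (contig_id, reason)."""
    kept, log = [], []
    for c in contigs:
        if len(c) < min_contig_len:
            log.append((c.id, "too_short"))
        else:
            kept.append(c)
    return kept, log


def containment_graph(contigs: Sequence[Contig], self_hits: Sequence[Hit],
                      params: RefineParams | None = None) -> nx.DiGraph:
    """Directed relation A→B meaning "A is contained in B", transitively
    closed.  ``self_hits`` come from aligning the assembly to itself; the
    trivial identity hit of a contig to itself is ignored."""
    if params is None:
        params = RefineParams()
    by_id = {c.id: c for c in contigs}
    g = nx.DiGraph()
    g.add_nodes_from(by_id)
    for h in self_hits:
        if h.ref_id == h.qry_id:
            continue
        if is_self_identity(h) or h.pct_id < params.containment_min_id:
            continue
        if h.ref_id not in by_id or h.qry_id not in by_id:
            continue
        for inner, outer in ((h.qry_id, h.ref_id), (h.ref_id, h.qry_id)):
            a = by_id[inner]
            if a.circular:
                continue
            if h.aln_len >= params.containment_min_frac * len(a):
                g.add_edge(inner, outer)
    return nx.transitive_closure(g, reflexive=False)


def resolve_containment(contigs: Sequence[Contig], relation: nx.DiGraph
                        ) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Collapse mutual-containment classes to their longest member, then
    drop every contig contained in a survivor."""
    by_id = {c.id: c for c in contigs}
    log: list[tuple[str, str]] = []
    removed: set[str] = set()
    for comp in nx.strongly_connected_components(relation):
        if len(comp) < 2:
            continue
        keep = min(comp, key=lambda i: (-len(by_id[i]), i))
        for cid in sorted(comp):
            if cid != keep:
                removed.add(cid)
                log.append((cid, f"equivalence_loser_to:{keep}"))
    for cid in sorted(by_id):
        if cid in removed:
            continue
        containers = [v for v in relation.successors(cid)
                      if v not in removed and v != cid]
        if containers:
            removed.add(cid)
            log.append((cid, f"contained_in:{sorted(containers)[0]}"))
    kept = [c for c in contigs if c.id not in removed]
    return kept, log


def refine(contigs: Sequence[Contig], self_hits: Sequence[Hit],
           params: RefineParams | None = None
           ) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Length filter, then containment removal."""
    if params is None:
        params = RefineParams()
    kept, log = drop_short(contigs, params.min_contig_len)
    rel = containment_graph(kept, self_hits, params)
    kept, log2 = resolve_containment(kept, rel)
    return kept, log + log2
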