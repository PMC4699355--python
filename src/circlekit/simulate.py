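"""Ground-truthed synthetic fixtures for every pipeline stage.

The generator emulates the characteristic ways a linear contig can
misrepresent a circular replicon:

* ``dup_ends`` — the contig carries the same sequence at both ends, the
  trailing copy optionally degraded ("low-quality ends");
* ``missing`` — bases at the circle's junction are absent from the contig;
* ``tandem`` — a small circle assembled as two or more concatenated
  full copies;
* ``fragmented`` — the circle split into several linear pieces with
  unassembled gaps between them;
* ``false_overlap`` — a *linear* molecule with an identical repeat planted
  at both ends: the negative control that an overlap between contig ends
  does not imply circularity.

Corrected reads are sampled around the circle (crossing the origin) or
along the linear truth, on either strand, at a configurable coverage and
length distribution.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .contig import Contig
from .seqio import SeqRecord, revcomp, rotate

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# pathology spec factories -------------------------------------------------


@dataclass(frozen=True)
class DupEnds:
    length: int
    error: float = 0.02  # substitutions confined to the duplicated region


@dataclass(frozen=True)
class Missing:
    length: int


@dataclass(frozen=True)
class Tandem:
    copies: int

    def __post_init__(self):
        if self.copies < 2:
            raise ValueError("tandem needs at least 2 copies")


@dataclass(frozen=True)
class Fragmented:
    n: int
    gap: int


@dataclass(frozen=True)
class FalseOverlap:
    """Linear truth with an identical repeat at both ends.

    Assemblies fragment at repeats precisely because the repeat occurs
    elsewhere in the genome, so the fixture also emits a companion linear
    "repeat family" molecule carrying ``family_copies`` further copies of
    the repeat in unique context, and samples reads from it too.
    """

    repeat_len: int
    family_copies: int = 3
    spacer_len: int = 2000


Pathology = DupEnds | Missing | Tandem | Fragmented | FalseOverlap


@dataclass
class RepliconSpec:
    length: int
    pathology: Pathology
    anchor_gene_at: int | None = None  # plant the anchor gene here


@dataclass
class SimConfig:
    seed: int
    replicons: list[RepliconSpec]
    read_length_mean: int = 1500
    read_length_sd: int = 150
    coverage: float = 20.0
    per_base_error: float = 0.0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.per_base_error <= 0.2:
            raise ValueError("per_base_error must be in [0, 0.2]")


@dataclass
class TruthReplicon:
    id: str
    seq: str
    circular: bool
    anchor_gene: SeqRecord | None = None
    anchor_pos: int | None = None


@dataclass
class TruthSet:
    replicons: list[TruthReplicon]
    contigs: list[SeqRecord]
    reads: list[SeqRecord]
    provenance: list[tuple] = field(default_factory=list)

    def contig_objects(self) -> list[Contig]:
        return [Contig(r.id, r.seq) for r in self.contigs]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only degradation at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


_ANCHOR_STOPS = {"TAA", "TAG", "TGA"}


def make_anchor_gene(rng: np.random.Generator, length: int = 1200) -> str:
    """A stop-free open reading frame: ATG, random codons, one stop."""
    ncod = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < ncod + 1:
        c = _random_seq(rng, 3)
        if c not in _ANCHOR_STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _derive_contig(rng, rep_id, truth_seq, pathology):
    """Linear contig(s) representing the truth, per pathology."""
    L = len(truth_seq)
    o = int(rng.integers(0, L))
    lin = rotate(truth_seq, o)
    if isinstance(pathology, DupEnds):
        dup = _mutate(rng, lin[:pathology.length], pathology.error)
        return [SeqRecord(f"{rep_id}.ctg", lin + dup)]
    if isinstance(pathology, Missing):
        return [SeqRecord(f"{rep_id}.ctg", lin[:L - pathology.length])]
    if isinstance(pathology, Tandem):
        return [SeqRecord(f"{rep_id}.ctg", lin * pathology.copies)]
    if isinstance(pathology, Fragmented):
        n, gap = pathology.n, pathology.gap
        pieces = []
        bounds = [i * L // n for i in range(n)] + [L]
        for i in range(n):
            s, e = bounds[i], bounds[i + 1] - gap
            if e <= s:
                raise ValueError("gap too large for fragment size")
            pieces.append(SeqRecord(f"{rep_id}.ctg.{i}", lin[s:e]))
        return pieces
    raise AssertionError(f"unhandled pathology {pathology!r}")


def _sample_reads(rng, rep_id, truth: TruthReplicon, cfg: SimConfig
                  ) -> list[SeqRecord]:
    L = len(truth.seq)
    n_reads = int(np.ceil(L * cfg.coverage / cfg.read_length_mean))
    reads = []
    for i in range(n_reads):
        rl = int(round(rng.normal(cfg.read_length_mean, cfg.read_length_sd)))
        rl = max(300, min(rl, 4 * cfg.read_length_mean))
        if truth.circular:
            start = int(rng.integers(0, L))
            reps = rl // L + 2
            seq = (truth.seq * reps)[start:start + rl]
        else:
            rl = min(rl, L)
            start = int(rng.integers(0, L - rl + 1))
            seq = truth.seq[start:start + rl]
        seq = _mutate(rng, seq, cfg.per_base_error)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SeqRecord(f"{rep_id}.read.{i}", seq))
    return reads


def simulate(config: SimConfig) -> TruthSet:
    """Generate truth replicons, pathological contigs and reads."""
    rng = np.random.default_rng(config.seed)
    replicons, contigs, reads, prov = [], [], [], []
    for ri, spec in enumerate(config.replicons):
        rep_id = f"rep{ri}"
        if isinstance(spec.pathology, FalseOverlap):
            po = spec.pathology
            r = po.repeat_len
            if 2 * r >= spec.length:
                raise ValueError("repeat_len too large")
            rep = _random_seq(rng, r)
            mid = _random_seq(rng, spec.length - 2 * r)
            seq = rep + mid + rep
            truth = TruthReplicon(rep_id, seq, circular=False)
            replicons.append(truth)
            contigs.append(SeqRecord(f"{rep_id}.ctg", seq))
            prov.append((f"{rep_id}.ctg", "false_overlap", r))
            if po.family_copies > 0:
                parts = [_random_seq(rng, po.spacer_len)]
                for _ in range(po.family_copies):
                    parts.append(rep)
                    parts.append(_random_seq(rng, po.spacer_len))
                fam = TruthReplicon(f"{rep_id}.family", "".join(parts),
                                    circular=False)
                replicons.append(fam)
                contigs.append(SeqRecord(f"{rep_id}.family.ctg", fam.seq))
                prov.append((f"{rep_id}.family.ctg", "repeat_family",
                             po.family_copies))
                reads.extend(_sample_reads(rng, fam.id, fam, config))
        else:
            seq = _random_seq(rng, spec.length)
            gene = pos = None
            if spec.anchor_gene_at is not None:
                g = make_anchor_gene(rng)
                pos = spec.anchor_gene_at % spec.length
                if pos + len(g) > spec.length:
                    pos = spec.length - len(g)
                seq = seq[:pos] + g + seq[pos + len(g):]
                gene = SeqRecord("anchor_gene", g)
            truth = TruthReplicon(rep_id, seq, circular=True,
                                  anchor_gene=gene, anchor_pos=pos)
            replicons.append(truth)
            for ctg in _derive_contig(rng, rep_id, seq, spec.pathology):
                contigs.append(ctg)
                prov.append((ctg.id, type(spec.pathology).__name__.lower(),
                             len(ctg.seq)))
        reads.extend(_sample_reads(rng, rep_id, truth, config))
    return TruthSet(replicons, contigs, reads, prov)


# scoring -------------------------------------------------------------------


@dataclass
class RepliconScore:
    replicon_id: str
    contig_id: str | None
    circularized: bool
    length_delta: int
    identity: float
    correctly_circularized: bool
    false_circularized: bool = False


def _best_identity(out_seq: str, truth: TruthReplicon) -> float:
    """Identity of an output contig against the truth, rotation and
    strand invariant for circular truth (search within the doubled
    sequence)."""
    target = truth.seq + truth.seq if truth.circular else truth.seq
    best = 0.0
    for probe in (out_seq, revcomp(out_seq)):
        if probe in target:
            return 100.0
        if len(probe) > len(target):
            probe, t = target, probe  # output longer than doubled truth
        else:
            t = target
        d = edlib.align(probe, t, mode="HW", task="distance")["editDistance"]
        best = max(best, 100.0 * (1.0 - d / len(probe)))
    return best


def score_against_truth(outputs: Sequence[Contig], truth: TruthSet
                        ) -> list[RepliconScore]:
    """Per-replicon report; a replicon is correctly circularized when its
    best-matching output contig is flagged circular, has exactly the truth
    length, and matches at 100 % identity up to rotation and strand."""
    scores = []
    for rep in truth.replicons:
        best = None
        for c in outputs:
            ident = _best_identity(c.seq, rep)
            cand = (ident, -abs(len(c) - len(rep.seq)), c)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            scores.append(RepliconScore(rep.id, None, False,
                                        -len(rep.seq), 0.0, False))
            continue
        ident, _, c = best
        delta = len(c) - len(rep.seq)
        correct = (rep.circular and c.circular and delta == 0
                   and ident == 100.0)
        false_circ = (not rep.circular) and c.circular
        scores.append(RepliconScore(rep.id, c.id, c.circular, delta,
                                    ident, correct, false_circ))
    return scores
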