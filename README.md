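# circlekit

Post-assembly circularization of long-read genome assemblies.

Long-read assemblers (HGAP, PBcR/Canu, SPRAI and kin) produce linear
contigs even for circular DNA molecules — bacterial chromosomes,
plasmids, mitochondria, plastids. The linear representation of a circle
typically carries one of three junction artifacts: the same sequence
duplicated at both (often low-quality) contig ends, sequence at the
junction missing outright, or — for circles shorter than the read length
— several complete tandem copies of the molecule in one contig. Methods
that circularize by looking only for an end-to-end overlap also fall into
a trap: a *linear* fragment flanked by two copies of a genomic repeat
looks exactly like a circle.

circlekit is aimed at people finishing microbial and organelle genomes
from corrected long reads. It resolves circular contigs from *read
evidence*: corrected reads mapping near contig ends are locally
reassembled, and the reassembled units drive four fixed stages —

1. **merge** — units whose two ends match the ends of two different
   contigs (matches ≥ 4000 bp, within 1 kb of the unit's ends and 15 kb
   of the contigs' ends, identity ≥ 95 %) join those contigs; read
   filtering, reassembly and merging iterate to a fixpoint;
2. **circularize** — a contig covered ≥ 95 % by matches to one circular
   unit, one match spanning ≥ 95 % of that unit, is replaced by the unit
   (collapsing tandem multi-copies); otherwise matching the contig's
   start and end to the same unit in a consistent geometry trims the
   junction and closes the circle, restoring any missing sequence from
   the unit;
3. **refine** — contigs under 2000 bp are dropped, and non-circular
   contigs ≥ 95 %-contained in another contig at ≥ 95 % identity
   (transitively closed) are removed;
4. **fixstart** — each circular contig is rotated to begin at an anchor
   gene (dnaA homologs by convention; ≥ 80 % amino-acid identity over the
   full gene, found by six-frame translated search), or failing that at a
   predicted gene start nearest the contig middle.

The two classical overlap-only approaches — iterative end trimming and
split-in-half-and-remerge — are included as `baseline-trim` and
`baseline-splitmerge` for comparison, and a simulator generates
ground-truthed fixtures for every junction pathology, so the whole
pipeline is testable hermetically.

## Worked example

Simulate a 30 kb plasmid assembled into three tandem copies (a 90 kb
contig), with an anchor gene planted, then run the pipeline and score
against the simulated truth:

```
$ circlekit simulate demo --seed 11 --length 30000 --pathology tandem:3 --anchor-gene
$ circlekit all demo/contigs.fasta demo/reads.fasta demo/out
{"contigs_in": 1, "contigs_out": 1, "merges": 0, "circularized_replaced": 1,
 "circularized_end_joined": 0, "removed": 0, "rotated": 1, "circular_out": 1}
$ circlekit score demo/out/final.fasta demo/truth.fasta
{"replicon_id": "rep0", "contig_id": "rep0.ctg", "circularized": true,
 "length_delta": 0, "identity": 100.0, "correctly_circularized": true,
 "false_circularized": false}
```

The summary line says the single input contig came out as a single
contig, circularized by the *replacement* path (`circularized_replaced:
1`): the reads reassembled into one circular unit, and the tandem contig
was collapsed onto it. The score line confirms the output is flagged
circular, has exactly the truth length (`length_delta: 0`) and matches
the simulated plasmid at 100 % identity up to rotation and strand. The
output FASTA marks circularity in the description (`>rep0.ctg
circular=true`), `demo/out/circularize.tsv` records which path fired per
contig, and `demo/out/comparison.crunch` holds the contig-versus-unit
alignments in crunch format for inspection in a comparison viewer such as
ACT.

Every stage is also a subcommand (`merge`, `circularize`, `refine`,
`fixstart`), `--coords-in` feeds externally computed alignment tables to
`circularize`, and `--nanopore` applies the permissive matching preset
(identity 85, extension 1000) for noisier assemblies. Supply a real
anchor-gene FASTA with `--genes`; the tests use synthetic genes.

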