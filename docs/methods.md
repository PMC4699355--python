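# Methods

## The problem

Long-read assemblers emit linear contigs even when the underlying DNA
molecule is circular (bacterial chromosomes and plasmids, organelle
genomes). A linear contig can misrepresent its circle in three
characteristic ways: near-identical low-quality copies of the same
sequence at both ends; sequence at the junction missing entirely; or, for
circles shorter than the read length, several complete tandem copies of
the molecule concatenated into one contig. A fourth situation is the trap
for naive methods: a *linear* fragment flanked by copies of a genomic
repeat looks exactly like a circle to any method that only inspects
end-to-end sequence similarity.

circlekit resolves circular contigs using read evidence rather than
end-overlap alone: corrected long reads near contig ends are locally
reassembled, and the reassembled units drive contig merging,
circularization, redundancy removal and start-position fixing, in that
fixed order.

## Pipeline stages

### Read filtering

Reads are mapped to the assembly. For contigs at least `length_cutoff`
(default 100,000 bp) long, only reads mapping within the first or last
`end_window` (default 50,000 bp) bases are kept; a read crossing a window
boundary is trimmed back to the part aligned inside the window and kept
if at least `min_trimmed_len` (default 250 bp) remains. Reads mapping to
shorter contigs, and unmapped reads, are kept whole. "Maps to" means the
read's primary hit (largest `aln_len x pct_id`); trimming cuts the read at
the base aligned to the window boundary, and unaligned overhangs beyond
the contig end are kept because they may bridge the circle.

Two desk-scale placement rules make this robust for small replicons.
When the two windows tile the whole contig there is nothing to trim
toward, so reads are kept whole. And when a read places equally well at
several positions (tandem or repeated sequence), a placement that avoids
trimming is preferred; if *every* equal-score placement crosses a window
boundary the read is kept whole, because the trim position would be an
artifact of an arbitrary placement choice. Without these rules, window
boundaries that are congruent to the circle origin (as they always are on
a tandem multi-copy contig) systematically cut the read set at one circle
position and no closure can ever be observed.

### Local assembly

Corrected reads are high identity, so the local assembler joins reads on
exact overlaps, with unitig semantics: all candidate extensions of the
growing sequence must agree (each a prefix of the longest); any
disagreement terminates the unitig. The minimum overlap starts at the top
of a descending ladder (127, 121, 111, 101, 95, 91, 85, 81, 75, 71) and
is lowered only when no unitig grows beyond twice the longest read and no
circle closes — the desk-scale analog of lowering a reassembly k-mer when
coverage is too thin. The assembler is deterministic given the input
reads: seeds are processed longest-first with lexicographic tie-breaks.

A walk that re-enters a read it has already used has gone around a
circle. The duplicated wrap is removed with a prefix/suffix overlap
computation, so a circular unit stores exactly one period; a single read
spanning a small circle more than once collapses to its minimal period
the same way. Without an observed closure, a period collapse is accepted
only when the period is short enough that one read could span it —
a chance repeat shared by the two ends of a linear unitig is not
circularity.

**Closure depth guard.** A circular closure additionally requires the
period to be covered uniformly by the reads. This matters because a
linear molecule flanked by copies of a repeat longer than the reads is
*logically indistinguishable* from a circle at the level of read content:
every local junction of the false circle is read-supported. What does
distinguish it is depth — the collapsed repeat region carries the reads
of every repeat copy and is covered a multiple of the background depth.
Reads are placed exactly on the candidate period (unplaceable reads, e.g.
from other replicons, are ignored), windowed mean coverage (500 bp
windows) is computed around the circle, and the closure is rejected when
the maximum window exceeds 2.2 times the median window. The threshold
sits between the two measured populations: across 80 simulated true
circles (4–50 kb, 600–1500 bp reads, 20x) the worst max/median ratio was
1.74, while across 40 simulated repeat-flanked false closures the lowest
was 2.83. On rejection the unitig is broken at the deepest-covered point
(the repeat) rather than circularized. With fewer than four placeable
reads the guard abstains and accepts.

### Contig merging

Each unit's longest match near its start and longest near its end are
identified. A merge of two contigs through the unit is accepted when both
matches are at least `min_match_len` (default 4000 bp) long, lie within
`max_unit_end_dist` (default 1000 bp) of the unit's ends and within
`max_contig_end_dist` (default 15,000 bp) of a contig end — contig ends
get more tolerance because they are often low quality — they touch
*different* contigs, no strictly longer match to the unit exists anywhere
(read strictly: longer than the smaller of the two chosen matches), and
the orientations admit a consistent join (the unit walks off the end of
one contig, through its bridging interval, into the start of the other;
either contig and the unit itself may be reverse-complemented to reach
this normal form, head-to-head configurations are rejected). The merged
sequence uses the unit's bases between the two matched intervals,
trusting the local reassembly over the low-quality contig ends; if the
matched intervals overlap on the unit, the shared bases appear once.

When several accepted merges touch the same contig in one round, the one
with the largest combined match length is applied and the rest wait.
After each round the reads are re-filtered against the new assembly and
the filter → assemble → merge cycle repeats until a round applies no
merge (bounded by `max_iterations`, default 10; the contig count strictly
decreases whenever a merge applies).

### Circularization

Two paths are tried per contig, in order.

*Replacement*: if the contig's matches to one circular unit cover at
least 95 % of the contig (interval union — overlapping hits are not
double-counted), all covering matches are to that same unit, and one
single match spans at least 95 % of the unit, the contig is replaced by
the unit. A tandem multi-copy contig with two or more full copies always
contains the unit's full linearization as a substring, so this path
collapses tandems of any copy number.

*End join*: otherwise the longest match near the contig's start and the
longest near its end are found with the merge-stage distance criteria. If
both land on the same unit with consistent orientations and positions the
contig is cut at the two junctions and closed, any missing junction
sequence supplied from the unit. Geometrically: with the unit oriented so
the start-side match is forward, the end-side match must also be forward;
if the end-side match runs past the start-side match's first unit base
the contig is simply cut where the two meet (this removes a duplicated
end exactly once), otherwise the unit's interval between the two matches
becomes the bridge. For a circular unit the bridge may wrap around the
unit's origin.

When the longest start-side and end-side matches are the same single hit,
the second longest is substituted on either side (both orders are tried).
For a *circular* unit a shared single match can also be a legitimate
self-closure — the unit's own ends are an artifact of its linearization
origin — so, as a last resort, the contig closes through the unit with a
wrap-around bridge, but only when the hit spans at least two thirds of
the unit: a contig must carry most of the circle to be circularizable,
and a mere fragment of a replicon is left alone. For the same reason the
within-1000-bp-of-unit-end criterion is not applied to circular units.

Three guards reject degenerate joins. Hit pairs whose unit intervals are
properly nested are refused: both contig ends matching the *same* unit
bases is the signature of a repeat shared by the ends, not of a junction.
The trimmed contig ends must each be redundant with the resulting circle
(at most 10 % divergence over the trimmed piece, pieces under 200 bp
exempt): a legitimate circularization discards only duplicated junction
sequence, never unique sequence. And the final circle must carry no
residual start/end self-overlap at the merge match length.

### Refinement

Contigs shorter than 2000 bp are dropped first (circular or not — the
circularity exemption below applies only to containment). Then the
assembly is aligned to itself: a non-circular contig A is *contained* in
B when one single alignment has at least 95 % identity and covers at
least 95 % of A (hits are judged alone, never summed). The relation is
closed transitively, mutual-containment classes collapse to their longest
member (ties to the lexicographically smallest id), and every remaining
contig contained in a survivor is removed.

### Start fixing

Each circular contig is searched in translated (protein) space against a
nucleotide gene database supplied by the user — dnaA homologs by
convention, since dnaA sits near the origin of replication in most
bacteria. The search runs over the doubled contig so a gene straddling
the current origin is found; amino-acid identity of at least 80 % over
the full gene length is required; the first match in (contig position,
gene file order) wins. The contig is reverse-complemented if needed and
rotated so the gene's first base is position 0 on the forward strand.
With no anchor match, a minimal ORF caller (ATG/GTG/TTG to stop, both
strands, ≥ 300 nt, standard code) supplies the predicted gene start
nearest the contig middle, predictions touching either contig end being
excluded so the artificial linearization point cannot attract the origin.
The shipped tests use synthetic anchor genes; real analyses should supply
a curated gene FASTA via `--genes`.

## Baselines

Two overlap-only methods are implemented for comparison, over the same
alignment engine, because they are defined by their decision logic:

* `iterative_end_trim` self-aligns a contig and, whenever a disjoint
  same-strand repeat pairs the contig's start with its end (reaching
  within 100 bp of both extremities, at least `min_overlap_len` long —
  default 2000 bp, a declared default of this implementation), removes
  the duplicated prefix; iterated to a fixpoint. It fully collapses
  tandem multi-copies (one copy per round) but, by construction, also
  "circularizes" any linear contig whose ends share a long repeat.
* `split_merge_circularize` cuts each contig at its midpoint and remerges
  the halves through the overlap between the second half's end and the
  first half's start. One reunited sequence means circular; any failure
  retains the original contig. On a tandem triple it recognizes only the
  outermost duplication and outputs two copies of the truth — its
  documented failure mode. Contigs are processed independently so
  separate contigs can never be merged into each other by accident.

## Alignment engine

One seed–chain–extend engine stands in for external read mappers, genome
matchers and translated searchers at desk scale (a `--coords-in` mode
ingests externally produced coords tables instead). k-mer anchors
(default k = 15, repetitive seeds above 64 occurrences skipped) are
collected with numpy on both strands, ordered by (diagonal, query
position), and chained: a new chain starts when the diagonal jumps by
more than `diagdiff` (25) or the along-sequence gap exceeds `breaklen`
(default 500 bp; 1000 in the nanopore preset), which lets hits extend
across short poorly aligned patches. Every chain becomes one hit whose
percent identity is measured by a global edit-distance alignment of the
matched intervals (edlib); hits below `min_pct_id` (default 95 %; 85 in
the nanopore preset) or `min_hit_len` are dropped. Because anchors are
collected at every exact position, hit boundaries are exact wherever the
sequence is clean — the junction cut positions in circularization depend
on this. Ties are broken toward the lower reference coordinate. Identity
is reported unrounded internally and rounded half-up to two decimals only
in coords export; thresholds always compare the unrounded value.

The translated search translates the contig in six frames and aligns each
gene's protein as an infix (edlib HW), so every reported gene hit spans
the full gene; amino-acid identity is the reported identity, and protein
coordinates are mapped back to contig nucleotides with frame-consistent
strand. Only placements at the best edit distance are reported.

## The simulator

Fixtures are generated, never stored: a uniform-random circle (GC bias is
out of scope), a contig derived per pathology, and reads sampled around
the circle (crossing the origin, both strands) at the configured
coverage. Defaults: read length 1500 ± 150 bp (minimum 300), coverage
20x, error-free reads. The degraded duplicated end of the `dup_ends`
pathology carries 2 % substitutions confined to the duplicated region —
enough to exercise the sub-100 % identity code paths while staying
clearly inside the 95 % alignment threshold; an error rate equal to the
threshold would make retention of those hits a coin flip of the noise
draw rather than a property of the method. The `false_overlap` fixture
plants one identical repeat at both ends of a linear molecule and also
emits a companion "repeat family" molecule carrying three further copies
of the repeat in unique context, with reads sampled from it too: real
assemblies fragment at repeats precisely because the repeat occurs
elsewhere in the genome, and those extra copies are what make the
coverage signature of a false closure unambiguous.

Scoring is rotation- and strand-invariant (the output is searched within
the doubled truth, forward and reverse-complemented). A replicon counts
as correctly circularized only when its best-matching output contig is
flagged circular, has exactly the truth length, and matches at 100 %
identity — the strictest possible criterion, appropriate for error-free
fixtures.

## Problem sizes and configuration in tests

The test and acceptance fixtures use circles of 4–50 kb at 20x coverage,
which exercise every decision rule while keeping a full suite run around
a minute. Fixtures probing the merge loop use a proportionally scaled
configuration (length cutoff 5000, end window 2500, merge match length
1000) because their contigs are far below the 100 kb default cutoff that
real chromosome-scale assemblies occupy; this runs the genuine end-window
mechanism — junction-spanning local units, iterated remapping — at small
scale. The `false_overlap` fixtures use 600 bp reads so that no read
spans even the shortest (1 kb) planted repeat, which is the scenario
under test. All other suites run the shipped defaults.

What passing these simulations does *not* show: behaviour under real
corrected-read error profiles (chimeras, homopolymer indels), GC-biased
coverage, diploid or multi-chromosome genomes, or assemblies at megabase
scale. The exact-overlap local assembler in particular assumes corrected,
high-identity reads; noisy raw reads require an external assembler, whose
contigs can be supplied directly (circularity marked `circular=true` in
the FASTA description).

## Known limitations

* The local assembler resolves no repeat beyond unambiguous extension; a
  repeat with several genomic contexts breaks the unitigs around it (by
  design, see the depth guard).
* A replicon fragmented into pieces all shorter than the read-filter
  cutoff is handled as "short contigs" (all reads retained); its
  fragments are merged only if the whole-circle unit geometry admits it,
  and a lone fragment is deliberately never inflated into a full circle.
* Containment removal never inspects read depth, so two near-identical
  plasmids are kept only if they differ by more than the containment
  thresholds.
* The middle-gene fallback rotation is not idempotent (a second run sees
  a different middle); anchor-gene rotation is.
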