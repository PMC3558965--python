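# Methods

## Coordinate and library conventions

All coordinates are 1-based and closed; BED export is the only 0-based
half-open boundary. Circular replicons represent origin-wrapping
intervals canonically as `start > end`, and all interval arithmetic
takes the sequence length explicitly.

The mate-pair library is described by `LibrarySpec`: insert range
(default 1,000–3,500 bp, uniform), read length (default 25 bp) and the
expected relative strand of the two reads. The default, `same`, models
mate-pair (circularised-fragment) chemistry: both reads report on the
strand of the original fragment, so concordant pairs map on equal
strands and an inverted genomic segment manifests as opposite-strand
pairs. `opposite` (conventional paired-end) is supported throughout;
every classifier consults the library rather than hard-coding the
convention.

## Synthetic data generator

`mateinv.simulate` produces every input the pipeline consumes, with
truth metadata, as a pure function of `(config, seed)` (seeded
`numpy.random.Generator`s; no global state).

* **Reference**: an i.i.d. base model at a target GC (default 55.08%),
  default length 300 kb — a scaled-down stand-in for a ~2.4 Mb archaeal
  chromosome — plus an optional small circular extra-chromosomal element
  (default 16,887 bp at 50.58% GC).
* **Repeat families** (default three families: 300 bp × 8, 500 bp × 5,
  1,000 bp × 3 copies): identical random motifs pasted at uniform
  non-overlapping positions. Only their mapping consequence matters —
  25-mers inside any copy are ambiguous and are discarded by the unique
  mapper, as real interspersed repeats would be. Copy placements avoid
  inversion flanks so locus truth stays interpretable.
* **Inversion loci**: non-overlapping segments, each with a population
  frequency and an inverted-repeat flank length `r`. The two flank
  copies are exact reverse complements placed just inside the segment
  boundaries, so the inverted allele is locally *identical* to the
  reference across the repeats; the observable sequence change spans
  `[start + r, end − r]`. The default three-locus population uses the
  published frequencies (0.17, 0.18, 0.35); the first locus carries a
  gene-scale 1.5 kb flank (a duplicated-gene boundary), the others
  300 bp. Segment lengths are kept in the tens of kb — far above the
  maximum insert, as in the real genome — rather than scaled strictly
  proportionally, so no fragment can span a whole segment.
* **Mate pairs**: per pair, the haplotype is drawn independently per
  locus at the locus frequency (no linkage between loci — no
  co-occurrence information exists to calibrate any), fragment start
  uniform on the circle, length uniform on the insert range, strand
  uniform; reads are the fragment's first and last `read_length` bases.
  Substitution errors are i.i.d. per base (default 0); no indel,
  quality or machine-specific error model.
* **Contigs**: the reference circle is cut into `n` arcs (default 20)
  with a guaranteed minimum arc (default twice the maximum insert,
  drawn constructively: minimum arc plus uniform spacings of the slack,
  so the constraint always holds), optionally dropping a fixed gap at
  each cut; each contig is emitted in a random orientation.

What the generator does **not** emulate: sequencing-machine error
structure (colorspace, homopolymer), chimeric pairs, insert-size
distributions other than uniform/truncated ranges, biological linkage
between inversion loci, and real repeat sequences. Passing tests
therefore demonstrate correctness of the inference given the declared
sampling model, not robustness to every artefact of a real library.

## Unique exact mapping

Reads are mapped by exact k-mer lookup (k = read length) against both
strands of every target; circular targets contribute origin-crossing
k-mers so every position is a valid start. A read is kept only when it
has exactly one match anywhere (ambiguous and unmapped reads are
counted, never guessed; reads containing N never map), and a pair only
when both reads are unique. Exact matching is a deliberate choice: at
25 bp with a controlled error rate, it is the cleanest realisation of
"uniquely mapping", and it makes the mapper's behaviour provable against
a brute-force scan (tested). A mismatch-tolerant mode was considered
and rejected as out of scope.

## Scaffolding

Each doubly-unique inter-contig pair identifies one *end* of each
contig: the fragment leaves the first-read contig through the end its
mapped direction points at and enters the second-read contig likewise.
End-level counts are the primary record (the three-orientation
From::To table — same / converging / diverging — is a view of them,
since `same` alone cannot distinguish A-before-B from B-before-A).

Closure is greedy: links sorted by support (ties broken
lexicographically for determinism), accepted unless an end is already
taken or a premature sub-cycle would form; a link closing the cycle
over *all* contigs yields the circular scaffold. Within each contig
pair, minority orientation cells are ignored when the dominant cell
exceeds them at least 4:1 (configurable): pairs spanning an
inversion-polymorphic junction produce exactly such minority cells, and
they are inversion evidence, not scaffold evidence.

`min_support` defaults to 5 pairs per link, a guard against stray
chimeric or erroneous pairs in real libraries. For the error-free
recovery experiment in the test suite (20 contigs, 300 kb, 10×
physical coverage) the threshold is set to 2: junction support there is
Poisson with mean ≈ 10, so requiring 5 would reject genuinely supported
junctions in a large fraction of runs (P(support < 5) ≈ 2.6% per
junction, ~20 junctions per run), while with exact matching and zero
error rate every observed inter-contig pair is genuine evidence. This
is an analysis-parameter choice derived from the Poisson argument, not
from tuning against outcomes.

Gap lengths are estimated per junction by inverting the moment
condition `E[d_a + d_b | gap]` under the library's insert distribution
(bisection), where `d_a`, `d_b` are read-to-contig-end distances of
spanning pairs. Fragments observed spanning a junction are a
size-biased sample — `E[L | spans] = E[L²]/E[L] ≈ 2,481` for the
uniform 1,000–3,500 bp insert, not 2,250 — so the naive
`mean_insert − mean(d_a + d_b)` estimator would be biased low by
~230 bp; the moment inversion removes that bias (verified against
simulated truth gaps). Junctions without spanning pairs are reported
unknown and exported as 100 bp `U` gaps in AGP v2.1.

## Inversion calling

Intra-chromosome doubly-unique pairs are classified exhaustively into
concordant, inverted (strand convention violated) or other-discordant
(distance only). Inverted pairs bracketing the segment's *start* are
separated from those bracketing its *end* by the mapped strand of the
fragment's 5' read — for a same-strand library the fragment runs
left-to-right in reference coordinates at its 5' read exactly when it
straddles the start breakpoint (derived analytically from the four
fragment-strand × breakpoint cases; verified by simulation).

Within each side, footprints are clustered by single linkage, linking
two pairs when both footprint coordinates lie within one maximum insert
(pairs witnessing one breakpoint of one segment can never be farther
apart); clusters below `min_support` (default 10) are dropped. On
circular chromosomes, coordinates are first rotated into the widest
inverted-pair-free arc so no cluster straddles the origin;
origin-wrapping loci are reported as canonical wrapping intervals.
Start-side and end-side clusters are paired greedily by combined
support under mutual-consistency constraints (start-side footprints
precede end-side footprints at both breakpoints, within twice the
maximum insert — an allowance that accommodates gene-scale unmappable
flanking repeats); clusters viable in more than one pairing are flagged
ambiguous, unpaired clusters reported as orphans.

Reported coordinates are the innermost uniquely-mappable positions.
Uncertainty windows use deterministic evidence bounds: every read
anchors at least one genuinely matching base on its own side of a
sequence-change junction but may overhang it by up to `read_length − 1`
bases (chance matches, or exact mirrors across an inverted-repeat
flank), so each window bound concedes that allowance. On error-free
data the windows provably bracket the observable junctions
`[start + r, end − r]`; with flanks longer than a read they widen to
roughly the repeat length, and a flank longer than the maximum insert
leaves no bracketing evidence at all — the locus is invisible to the
library (tested as such).

The population frequency is the inverted fraction of spanning pairs
summed over both breakpoints, `f̂ = n_inv / (n_inv + n_conc)`, with a
Wilson 95% interval (chosen over Wald for small-count stability;
statsmodels implementation, cross-checked against the closed form in
the tests). Concordant pairs are counted as spanning only when their
two *reads* bracket the same breakpoint region the inverted evidence
itself attains — using one acceptance region for both classes keeps
the estimator unbiased even when repeats carve unmappable zones around
a breakpoint. Segments are much longer than any insert, so the two
breakpoints contribute independent fragments and the binomial interval
is valid for the pooled count. This read-pair fraction estimates the
cell fraction under uniform fragment sampling across haplotypes; the
two notions coincide in this sampling model but need not on real
libraries with coverage biases.

## Genome summary arithmetic

Percentages round half away from zero at two decimals (the convention
of genome-report tables; `Decimal`-based, since float rounding is
banker's). "Coding region" is the union of protein-coding and RNA gene
intervals with overlaps merged and origin-wrapping genes split at the
origin — the standard convention; summing raw gene lengths would
double-count overlaps. The per-base union is cross-checked against a
brute-force marking oracle in the tests. One published-style report row
(RNA genes at 4.74% of 2,980 total genes, where 145/2,980 = 4.87%) does
not recompute from its own ratio; the report always emits the
self-consistent value rather than replicating the discrepancy.

## Simulation scales used by the test suite

Chosen as the smallest scales at which each quantity is identifiable:

* Frequency recovery: 300 kb, three loci (0.17/0.18/0.35), 900,000
  pairs — with the 1.5 kb flank only fragments ≥ repeat + 2 reads can
  bracket a breakpoint, so this depth yields ≥ 2,000 uniquely-mapping
  spanning pairs per breakpoint (binomial SE ≈ 0.006, against a ±0.02
  acceptance band). No interspersed repeats or ECE: both only remove
  pairs, and a repeat landing adjacent to a breakpoint would degrade
  the spanning-pair precondition stochastically.
* Scaffold recovery: 50 seeded runs, 20 contigs, 300 kb, 10× physical
  coverage, error-free, `min_support=2` (Poisson argument above).
* Breakpoint localisation: single locus at 0.35, 200× physical
  coverage, flanks of 12 bp and 1,500 bp.
* Estimator calibration: 200 binomial replicates of 500 spanning pairs
  at f = 0.17; the exact Wilson coverage at this design point is 0.951,
  centred in the 0.92–0.98 acceptance band.

## Known limitations

* Exact matching only; a single sequencing error hides a read.
* Insertions, deletions, duplications and translocations are out of
  scope; only inversions are modelled and called.
* Frequencies are read-pair fractions; no attempt is made to model
  coverage bias between haplotypes.
* The scaffolder resolves no repeats beyond unique-pair filtering and
  performs no sequence overlap or gap finishing.
* Breakpoints inside flanking repeats are reported as windows, never
  point-resolved — with 25 bp reads the data cannot do better.
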