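# Methods

## Community sampling

Reads are sampled with replacement. For a genome of length *L* at target
fold-coverage *c* with read length *r*, the number of reads is
round(*c·L/r*) with banker's rounding (round-half-even) — a documented,
deterministic convention for the half cases. The replicon is chosen with
probability proportional to its length and the start position uniformly
on [0, len − r]; genomes are treated as linear (no wrap-around reads),
the conservative choice for replicons whose topology is unknown. Each
read is reverse-complemented with probability 0.5. Reads containing N
are kept by default (`max_n_fraction` enables a filter). Coordinates are
0-based half-open internally and 1-based inclusive in every TSV the
package writes.

Alternative identical placements are found with an exact k-mer-anchored
index (anchor length min(read length, 16), every candidate verified by
full string comparison), never a heuristic: a read's placement set is
the set of positions, on either strand of any replicon in the sampled
set, whose sequence equals the read exactly. Strand convention: a
placement's strand says on which genomic strand the *read sequence as
emitted* lies, so the origin of a reverse-complemented read carries
strand `-`. A site matching on both strands (a palindromic read) is
reported once, with strand `+`.

## 454 flow model

Nucleotides are flowed in the repeating order TACG (the de facto 454
convention; configurable, as is the TCAG key). A flow matching the next
homopolymer of length *n* draws its signal from Normal(*n*, 0.15·√*n*),
truncated at zero (negligible mass at the default coefficient); a
non-matching flow draws from a lognormal whose **natural-scale** mean is
0.23 and sd 0.15. The natural-scale reading was chosen because signal
intensities, not their logarithms, are what the instrument reports; the
underlying normal parameters are μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²).
Base calling rounds each signal to the nearest integer with ties at .5
rounding up; a negative-flow draw reaching 0.5 therefore produces a
one-base insertion, and positive-signal rounding errors produce
homopolymer length errors — the platform's characteristic error modes.
Carry-forward/incomplete-extension effects are deliberately out of
scope: only homopolymer-length determination errors are modelled.

SFF output is binary SFF v1 (flowgram format code 1, signals quantised
to 1/100 as uint16, no index block). Because the format fixes the
number of flows per read in the common header, shorter flowgrams are
zero-padded to the common flow count at write time; round-trips are
exact at the quantisation for equal-length flowgrams.

## Illumina model

The per-position substitution probability is a degree-4 polynomial in
the relative position x = i/(r−1), clipped to [0, 1]. The default
coefficients (0.002, 0.002, 0, 0, 0.032), lowest order first, were
chosen once to satisfy the two constraints that characterise the
platform's positional error profile — a read-average substitution rate
in [0.5 %, 1 %] (the default integrates to ≈ 0.94 %) and a 3′-terminal
rate above 3 % (the default gives 3.6 % at x = 1) — and are fully
overridable. Substitutions mutate to a uniformly chosen *different*
base. Insertions and deletions occur independently at 10⁻⁶ per base
(0.0001 %), split evenly between the two types, with inserted bases
uniform. Error-free bases receive a fixed high FASTQ quality and
erroneous bases a fixed low one; quality modelling beyond that is out of
scope.

Two vectorised helpers exist for large-scale statistics: the indel
process as chunked per-base Bernoulli draws, and per-position
substitution counts as one binomial draw per position (the exact
distribution of the per-read Bernoulli process summed over reads). The
scalar per-read path and these helpers implement the same process and
are cross-checked in the tests.

## Assembly evaluation

ACE files are parsed (via Biopython's ACE reader) into contigs with
unpadded consensus sequences; read offsets are shifted by the number of
consensus pads preceding them and clamped to the consensus for reads
hanging off its ends. A contig is **chimeric** iff the intersection over
its reads of the per-read compatible-genome sets is empty — this
operationalises "no single organism of origin", and means a read shared
identically between genomes never forces chimericity. The naive
origin-label definition is available behind
`use_alternative_placements=False` for comparison. The assigned genome
is the one compatible with the most reads; ties are broken by the
run-level seeded RNG.

"% of reads in chimeras" restricts to contigs longer than the read
length in both numerator and denominator; because the denominator is
ambiguous between assembled and sampled reads, both variants are
computed (reads in retained contigs, and optionally all sampled reads).
N50 is the smallest length among the longest contigs jointly covering
≥ 50 % of the total assembly length (assembly-, not genome-relative).
The LCA of a chimera's reads is found by lineage-path intersection;
nodes with "no rank" resolve to the nearest named ancestor rank,
matching NCBI practice. Divergence per base is (mismatches + inserted +
deleted bases) / aligned contig length, from either a PSL row or a
built-in affine-gap local alignment (Biopython PairwiseAligner,
match +1 / mismatch −2 / gap open −4 / extend −1, both strands tried) —
the latter intended for toy scale only. The chimera-sharing matrix entry
(i, j) is 100 × (reads of i or j inside chimeric contigs containing
both) / (reads sampled from i and j); the diagonal is defined as 0.

## Functional concordance

The e-value cutoff "10e−3" is read as 10⁻³ (the common typesetting of
1e-3) and is configurable. Best-hit order is e-value ascending, then bit
score descending, then subject id lexical — fully deterministic.
Overlapping contig hits are merged transitively; each merged interval
carries the category and coordinates of its best hit. The minimum
overlap for both real and contig-level annotation is 40 bp. Ties between
equally overlapping genes resolve to the leftmost gene start. Overlap is
computed strand-agnostically (a COG category has no strand at this
granularity). The deviation statistic is the sum of **absolute**
proportion differences over categories (a signed sum would telescope to
≈ 0); distributions are proportion-normalised over annotated reads.
Verdict classes cross-classify read level × contig level as
correct/incorrect/none, with unassembled reads a separate contig-level
class; the classes partition the read set.

## Genome similarity

MUMs are found with a generalized suffix array over genome a, genome b
and b's reverse complement, plus an LCP array: an adjacent suffix pair
from the two genomes whose LCP is a local maximum (both flanking LCPs
strictly shorter) identifies a substring occurring exactly once in each
genome (counting both strands of b); left-maximality is checked on the
preceding characters, right-maximality is implied by the LCP. Brute
force enumeration is reserved for the test oracle. The suffix sort is
comparison-based, appropriate for the toy-to-moderate genome sizes this
package targets. Coverage is the union of MUM intervals over the genome
length; the two coverages of a pair combine by arithmetic mean (min/max
available) into d = 1 − coverage, and clustering is average linkage
(complete/single available) with the tree written as Newick, branch
lengths ultrametric (merge height halved).

## Fixtures and what passing tests show

Toy genomes are i.i.d.-uniform DNA with identical blocks copied between
chosen pairs — structural realism (shared tracts, genes, a ranked
taxonomy) without evolutionary realism (no substitution models, no
rearrangements, uniform base composition). Mock assemblies stitch reads'
origin fragments by concatenation, so consensus sequences are error-free
and chimera structure is exactly the planted plan. Mock hit tables
reproduce the true category with a configurable fidelity and e-values
that always pass the default cutoff, with bit score tied to overlap so
best-hit selection follows maximal overlap. Consequently, passing the
closed-loop tests shows the *metrics* are computed correctly on inputs
with known truth; it does not show that real assemblers produce such
inputs, nor that real homology searches achieve any particular fidelity.

## Problem sizes and numerical choices

The statistical recovery checks use 10⁵ sampled reads (strand model),
10⁵ draws per homopolymer length n = 1..8 (flow sd regression, through
the origin), 10⁶ negative-flow draws, 10⁸ bases for the indel rate and
10⁶ reads of 110 bp for the positional substitution profile — sizes at
which each estimator's sampling error is far below the tolerance being
checked while the whole suite runs in seconds. Oracle-equivalence checks
use 100 randomized fixtures (25 seeds × 4 operations) of ≤ 1.2 kb so the
brute-force oracles remain exhaustive. All stochastic code takes a
numpy Generator or an integer seed; identical seeds give bit-identical
outputs.

## Known limitations

No mate pairs, no amplification or GC bias, no quality-value modelling,
no CAFIE 454 errors, no PCR chimeras. ACE is the only assembly dialect
parsed (no AMOS/afg). The built-in aligner and MUM finder are for toy
scale; real studies would use dedicated aligners and feed the tabular
results in. The mock-assembly generator does not model consensus errors,
so divergence on fixtures is zero by construction unless errors are
injected into the reads.
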