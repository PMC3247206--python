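# Methods

This note documents the models and procedures implemented in
`coraltrx`, the defaults they ship with, and what the synthetic-data
generator does and does not emulate.

## Read QC

Reads are screened for the SMART "CAP" cDNA-synthesis primer
(`AAGCAGTGGTATCAACGCAGAGT`) at either end, in forward or
reverse-complement orientation, allowing up to 2 substitutions (no
indels); the primer and everything outboard of it are clipped, with
qualities kept in lockstep, and both ends are rescreened until clean.
Whole-read filters then apply in a fixed order — N count, average
quality, length — so each rejection is attributed to exactly one rule
and the report's tallies always sum to `n_in − n_out`.

Choices that were genuinely open:

* **Filter order.** The primer is clipped *before* the length window is
  judged, because a read's usable length is what remains after
  clipping.
* **"Average quality"** is the arithmetic mean of phred scores, not the
  mean error probability.
* **Boundary semantics** follow the strict inequalities of the
  thresholds: a 280 bp read, or one at exactly Q20, is kept.
* The mismatch tolerance of historical primer screeners is
  undocumented; 2 substitutions over a 23-mer is tight enough that a
  chance match in a random read is negligible (< 10⁻⁹ per position).

## Completeness, redundancy and gene count

Reference deduplication is greedy longest-first: sequences are visited
in decreasing length order and dropped when they share a local-alignment
identity above the threshold (default 90%) with an already-kept
sequence.  Identity comes from the supplied all-vs-all hit table; a
global-identity variant would need the sequences themselves, which the
hit-table interface deliberately avoids.

"Best unique hit for each query and subject" is a greedy descending-
bitscore assignment (ties: ascending e-value, then subject id, then
query id), not an optimal bipartite matching — this matches what the
phrase means in practice in annotation pipelines and is deterministic.

The redundancy factor counts *distinct* assembled sequences hitting
each single-copy ortholog above both cutoffs (defaults bitscore ≥ 130,
e-value ≤ 2×10⁻³⁸, the scale appropriate for high-quality protein
hits); orthologs with no hit are excluded from the mean and reported
separately.  The gene-count estimate floors the quotient
`n_contigs / redundancy`, since a fraction of a gene is not a gene.
The modal length ratio uses 2%-wide histogram bins — narrow enough to
resolve a mode near 100%, wide enough that a few hundred pairs fill the
bins.

Annotation selection walks hits in rank order and takes the first one
clearing bitscore > 45 and e-value < 10⁻⁵ whose description contains no
avoid-keyword ("uncharacterized protein", "predicted protein";
case-insensitive substrings, user-extensible).  If every passing hit is
uninformative the best one is kept, flagged `informative=False`.  Note
the two bitscore conventions: the completeness map uses ≥ 45, the
annotation selector > 45, mirroring how such cutoffs are quoted in the
two contexts.

## SNP calling and Ts/Tv screens

A column of a padded alignment is a SNP when its non-gap, non-N depth
is ≥ `min_depth` (default 4) and the second-most-common base reaches
both `min_minor` reads (default 2) and `min_minor_frac` of depth
(default 0.2).  The defaults are the conservative two-read-support rule
of 454-era EST SNP pipelines; all three are exposed.  Columns with a
third passing allele are emitted once, as the top-2 pair, flagged
multiallelic.  Gaps and Ns never count toward depth, and indel
polymorphisms are not called.

Transitions are within-purine or within-pyrimidine changes; the
unordered spectrum uses the 6 classes A/G, C/T (transitions) and A/C,
A/T, C/G, G/T.  Summaries report density as ⌊assayed bp / n SNPs⌋
("1 SNP per N bp"), the rounded Ts/Tv percentage split, and the global
ratio at one decimal.  Per-contig ratios are undefined (and excluded
from screens) when a contig has no transversions; the tail screen
flags defined ratios < 1 (candidate positive selection) and > 5
(candidate purifying selection) and reports the empirical percentile of
both thresholds so the user can see where the fixed cutoffs sit in
their own distribution.

## Microsatellites

The scanner detects perfect period-m runs (2 ≤ m ≤ 6) as maximal
stretches with `seq[j] == seq[j−m]`, rejects motifs that are powers of
a shorter period (so mononucleotide runs and "ATAT"-style dimers of
dimers never masquerade as longer motifs), and merges same-class runs
separated by at most one motif length when both components carry a
substantial share of the copy threshold, the interruption contains no
N, and the merged purity stays ≥ 90%.  Overlaps are resolved
longest-first, then by purity, then leftmost.  Defaults require 6
copies for dinucleotides, 5 for tri- and 4 for tetra- through
hexanucleotides — chosen once as the level at which planted class
spectra are recovered exactly while random sequence stays quiet; they
are declared, not inferred from any external tool's settings.  This is
a pure-repeat scanner with a purity allowance, not a reimplementation
of Tandem Repeats Finder's probabilistic alignment model.

Canonical classes pool all rotations of a motif and of its reverse
complement and take the lexicographic minimum, giving A-first labels
(AAC, not GTT).  Enumeration over all 4³ trinucleotides yields exactly
10 classes; the AAN super-class (AAC + AAG + AAT) supports the
cross-species comparisons typical of repeat surveys.

## Paralog clustering

Ortholog seeds are mutual best cross-species hits on a symmetric score
table (asymmetric search scores averaged; pairs ≤ 40 bits dropped;
ties broken by lexicographic partner id).  In-paralogs join a seed when
their within-species score to it is at least the seed pair's
cross-species score — the defining InParanoid criterion — with
confidence `(score(x,a) − score(a,b)) / (score(a,a) − score(a,b))`
clamped to [0, 1] when the self-score is available.  A sequence
eligible for several groups is assigned to the one with the highest
confidence (ties: higher seed score, then earlier seed id), so groups
partition the clustered ids.  The full InParanoid bootstrap and
group-merging machinery is intentionally out of scope; the
implementation is InParanoid-*style*, not a clone.

## Statistics

Fisher's exact test uses the point-probability two-sided rule (sum of
hypergeometric tables no more probable than the observed one); a table
with a zero margin is undefined and returns p = 1 with a warning.
Multiple testing uses Benjamini–Hochberg.  The enrichment driver runs
one test per GO term present in the background, with subset membership
as the contrast; no GO-graph propagation is performed, terms are tested
as annotated.

The likelihood-ratio test computes 2ΔlnL = 2(lnL_alt − lnL_null)
against the χ² upper tail at the supplied degrees of freedom.  Display
rounding is two decimals, the precision at which such p-values are
printed.  A negative statistic — which cannot arise from properly
nested, fully optimized fits — yields p = 1 with a warning rather than
an exception, since imported log-likelihoods are often truncated.

## Synthetic data: what it emulates, and what it does not

Transcript and read lengths are lognormal with the configured mean/sd
(defaults 1030 ± 623 bp and 398 ± 118 bp, the scale of assembled
contigs and 454 Titanium reads) — lognormal because it is positive and
matches mean and sd exactly, so sampling-distribution tests hold
without truncation bias.  Reads carry Gaussian per-read quality means
(default 30 ± 5) with per-base jitter (sd 3), per-base N probability
0.002, and SMART-primer contamination on 15% of reads.

Fragmentation draws `1 + Poisson(redundancy − 1)` fragments per
transcript, so the mean equals the requested redundancy with
`redundancy = 1` exactly lossless.  Planted SNPs put the minor allele
into enough reads to clear the caller's default thresholds, which is
what makes the 100%-recall property meaningful: it verifies the
caller's column logic, not its behaviour under marginal coverage.
Transition planting is Bernoulli with probability odds/(1 + odds).
Gene families get geometric sizes (capped at 4 per species) so
single-member groups dominate, as in real ortholog-group size
distributions; the emitted bitscore table uses fixed tiers (self 400,
member-to-seed 300, seed pair 200, other cross pairs 150) so that at
zero noise MBH seeds and in-paralog membership follow by construction.

Deliberately **not** emulated: 454 homopolymer indel errors, chimeric
reads, expression-level variation (the motivating libraries were
normalized), assembler consensus errors, and reads that span SNP sites
partially (read stacks are full-length).  Singleton-like sequences are
represented as depth-1 fragments rather than by modelling assembler
join decisions.  Passing tests on this generator therefore demonstrate
the correctness of the downstream procedures' logic under clean planted
truth — not robustness to the full error structure of real 454 data.

All generator coordinates are 0-based half-open; hit tables are 1-based
inclusive (outfmt-6 convention).  All features are planted on the
forward strand; reverse-complement handling is exercised where it
matters scientifically, in motif canonicalization.  Every operation is
byte-deterministic under a fixed seed.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
so each statistical bound is meaningful: 5000 transcripts for
length-distribution checks, 1000 for redundancy recovery (±10%), ~600
transcripts × 2% density ≈ 12,000 planted sites for the
transition-fraction bound (3 binomial sd), full enumeration up to
margin 15 for the Fisher oracle.  The headline arithmetic identities
(gene counts, density, ratios, LRT p) are scale-free and exact.

## Known limitations

* `dedup_reference` needs hit-table identities; without an all-vs-all
  search it refuses rather than guessing.
* The SNP caller reports at most one call per column; allele pairs
  beyond the top two are only flagged, not emitted.
* The repeat scanner's purity model (merge across ≤ 1-motif
  interruptions) will split heavily degenerate repeats that
  alignment-based detectors would join.
* `enrich_terms` treats GO terms as flat labels; parent terms are not
  credited with descendant annotations.
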