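# Methods

This note records the models, numerical choices and open design decisions
behind `mfremotif`, in the spirit of a statistical package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cleavage geometry

MspJI-family restriction enzymes (MFREs) are modeled as cutting a fixed
`cut_distance` (default 16) bases 3′ of a 5-methylcytosine, on the strand
carrying the methyl mark, subject to a per-enzyme sequence context around
the m5C (MspJI: `CNNR` with the m5C first; FspEI: `CC` with the m5C
second; LpnPI: `CCDG` with the m5C second). The 4-base 5′ overhangs are
treated as already end-repaired: a fragment is fully described by its
duplex start/end, and all coordinates are 0-based half-open internally
(reports use 1-based inclusive positions).

For a motif with top-strand m5C at index *i* and the bottom-strand m5C
paired with the base at index *j*, the signed offset is *x* = *i* − *j*
and the doubly-cut excision product has length *l* = *x* + 33. *x* = 0
would require the two methylated cytosines to be base-paired with each
other, so *l* = 33 cannot occur; this single fact drives several
downstream invariants (a 33-base read can never pass base filtering, and
the discovery loop skips length 33 outright).

A `generic` enzyme model (context `C`, i.e. no flanking requirement) is
provided alongside the three commercial enzymes. Simulations default to
it so that pipeline geometry can be exercised without the site-constraint
effects of a particular enzyme; tests of constraint behaviour use the real
models explicitly.

### Fragment taxonomy

Theoretical digests classify fragments by the excision intervals of fully
methylated sites: `motif-cleaved` (exactly one site's interval),
`interstitial` (no site, no spanned missed cut), `overlap-short` /
`overlap-long` (two sites with overlapping excision intervals — under
~30 bp apart — split by whether the inter-site cuts were realized),
`concatenated` (spans an expected but unrealized cut), `other`
(≥ 3 clustered sites or mixed provenance). Classification never breaks
tiling: fragments always partition each record exactly.

## Read filtering

* **Reference filter.** Exact matching of whole reads against both strands
  via a k-mer index (k = 20, the shortest supported read). All matching
  loci are recorded; reads matching only the reverse strand are stored as
  their reverse complement ("oriented to the top strand"); a read matching
  both strands stores the lexicographically smaller form with per-locus
  strand flags, which makes collapsing deterministic for palindromic
  fragments. Duplicates are collapsed after orientation, on the canonical
  form, and copy counts are conserved. Reads containing N are discarded
  (exact matching is the error filter; no quality-aware processing).
* **Size filter.** Search range 26–40 bp (the possible correctly-cut
  lengths for motifs up to 8 bp); background range 41–80 bp. Both are
  configurable.
* **Base filter.** C as the 17th base from the 3′ end and G as the 17th
  from the 5′ end — the invariant m5C positions of a correctly cut read.
  The analytic pass rate for i.i.d. reads is P(C)·P(G) (1/16 ≈ 6.2% at
  50% G+C), which the diagnostics use as a sanity anchor.
* **Diagnostics.** Per length: total reads, unique reads, mean redundancy
  (total/unique), base-filter pass fraction over unique reads. Background
  levels are unweighted means of the per-length metrics over the
  background range (not pooled reads, which would overweight abundant
  lengths). Candidate lengths are those where any metric exceeds
  `threshold_multiplier` (default 2.0) times its background mean.
* **Copy-number filter.** Within a candidate bin, unique reads with copy
  number at or below the background mean redundancy are dropped.

Multi-mapping reads are counted once in per-length statistics but credit
all of their loci in site-representation reports (repeat pileup otherwise
makes repeated sites look unrepresented); a `multi_mapping` flag preserves
auditability.

## Consensus calling

Reads of one length are stacked into an ungapped alignment; each column's
base distribution is compared by Kullback–Leibler divergence,
KL(observed ‖ expected), with the expected distribution of each of the 15
IUPAC symbols formed by restricting the genome's base frequencies to the
symbol's allowed bases and renormalizing. Both distributions are floored
at ε and renormalized before the divergence is taken. The
smallest-divergence symbol wins; ties resolve toward the more specific,
alphabetically first symbol. Leading and trailing N runs are trimmed;
interior N's are kept.

**Choice of ε = 10⁻³.** The direction KL(obs ‖ exp) penalizes observed
mass on bases a symbol forbids by roughly *f*·ln(*f*/4ε), where *f* is
the contaminating (non-motif) read fraction. The floor therefore sets the
contamination level at which a motif column loses to the unrestricted N
model. With ε = 10⁻³ the weakest common motif column (a two-base symbol
such as W) beats N for *f* up to ≈ 0.2 and loses above it, which brackets
the regime in which this class of experiment is expected to work; a much
smaller floor (10⁻⁶) pushes the crossover down to *f* ≈ 0.1–0.15 and
makes even pure columns fail at moderate contamination, while a much
larger one erodes the advantage of specific symbols on clean data. The
same ε applies to the observed side so empty cells are well-defined.

**Complexity score.** Per symbol: A/C/G/T = 8, two-base symbols = 4,
three-base symbols = 2, N = 0. One C, one G (the base-filter freebies)
and all N's are removed before summing; strings scoring ≥ 10 are candidate
motifs (CCGG → 16 passes; CRYG → 8 and CNNG → 0 do not). The **per-base
specificity** used to rank candidates is the complexity score divided by
the number of non-N symbols; this normalization keeps long, weakly
specified consensus strings from outranking short strong ones, and ties
break on raw score, then shorter string, then lexicographic order.

**Methylated positions** follow from the source read length alone: in a
presumed correctly-cut read of length L the top-strand m5C is at read
index L−17 and the bottom-strand m5C's paired G at index 16, translated
into motif coordinates via the consensus placement. Placements that put
either position outside the motif are rejected as inconsistent.

## Iterative discovery

Background levels are established once; then repeatedly: find candidate
lengths, copy-number- and base-filter each bin, call the consensus, keep
candidates scoring ≥ 10, accept the highest per-base specificity, infer
its methylated positions, and delete every read containing an instance of
the accepted motif with an exactly cleaved end (distance exactly 16 on at
least one side — (16,16), (x,16) and (16,x) reads). Iterate until no
candidates remain.

Two guards beyond the basic loop:

* a consensus is only called on bins with at least `min_candidate_reads`
  (default 20) unique reads after filtering — below a few tens of
  examples the caller's own minimum-read experiment shows deductions are
  unreliable, and tiny bins otherwise produce spuriously over-specified
  strings;
* a candidate whose string contains an already-accepted motif (either
  orientation) is discarded. Reads slipped by +1 bp on *both* ends have
  no exactly cleaved end, survive subtraction, and for motifs with a C
  just 3′ of the top m5C and a G just 5′ of the bottom-strand G would
  re-report the accepted motif from length *l*+2 with shifted methylated
  positions. The containment check removes exactly these echoes; truly
  distinct motifs are unaffected unless one literally contains the other,
  which among known short palindromic m5C motifs is rare.

Consensus calling uses unique reads unweighted by copy number (a single
hot locus must not dominate the alignment); copy-number weighting is
available as an option.

## Deconvolution

For a degenerate apparent motif, every non-degenerate instance is counted
at the motif's expected offset in reads of the source length (reads derive
from either strand, so a non-palindromic source contributes both the
instance and its reverse complement — that asymmetry is the signal).
Instances with read support below `min_fraction` (default 0.1) of the
best-supported instance are deemed absent. Then:

* all instances present at similar frequency (max/min ≤ 4) → true
  degeneracy;
* survivors = {s, reverse-complement(s)} with s non-palindromic → one
  non-palindromic motif methylated on both strands;
* several palindromic survivors → either multiple independent motifs or
  base-dependent variants of one motif. These two are genuinely
  indistinguishable from instance frequencies (both present as two
  palindromic survivors realizing only the complementary combinations of
  the degenerate block), so the label is a declared heuristic: survivors
  sharing at least two fixed bases flanking the varying block on each
  side are reported as a base dependency, otherwise as multiple motifs.
  The resolved motif *set* — the substantive output — does not depend on
  the label.

Both thresholds (0.1 and 4) are configurable and reported beside raw
counts so users can re-threshold; the 4-fold bound is chosen so that a
dominant canonical instance with minor off-target instances (present at
~15% of the canonical site fraction) is never merged into true
degeneracy.

Enzyme-constraint trimming inverts the constrained-site computation: all
left/right trims of the apparent motif are tried, and if re-applying an
enzyme's context to a trimmed core reconstructs the apparent string
exactly, the most-trimmed core is returned (YNNGATCNNR → GATC under
MspJI; CCGATCGG → CGATCG under FspEI). The operation is idempotent and
returns its input when no trim reconstructs it.

## Simulator

### Minimal-examples experiment

Mock correctly-cut reads place the motif so both m5C geometry positions
are exactly 17th from their ends, with i.i.d. flanks at a chosen G+C and
degenerate positions drawn uniformly among permitted bases. Non-CCMD
reads are fully random except the two forced base-filter positions.
Reads are added one at a time — non-CCMD reads interleaved
deterministically so every prefix holds the target fraction — with the
consensus caller re-run after each addition; a deduction is *correct*
only when the trimmed consensus equals the planted motif string at its
exact geometric placement. Per replicate, the largest set size with an
incorrect call followed by `stability_window` (50) consecutive correct
sizes is recorded; the minimum sufficient set is that plus one, and the
experiment reports the mean over replicates (default 25). Replicates that
never stabilize within the read cap make the condition "not
determinable". Sets are nested prefixes of one per-replicate read stream;
duplicate reads are skipped so sizes count unique reads.

### Genome fixtures

A random genome (default 100 kb, 50% G+C) receives spaced planted motif
instances (default 150 per motif, ≥ 90 bp apart so excisions do not
overlap unless the experiment wants them to); each is fully methylated
with probability `methylation_fraction` (default 1.0), optionally
hemi-methylated. The digest realizes each expected cut independently:
dropped with probability `incomplete_digest`, otherwise slipped 1 bp
*beyond* the expected distance with probability 0.25 or 1 bp short with
probability 0.02 — an asymmetry mirroring the observed dominance of
one-base-long reads over one-base-short ones in real digests. Excised
fragments (20–80 bp, random strand) become reads with geometric copy
counts (mean 60), emulating the strong amplification of methyl-derived
families; background reads are random genomic windows across 26–80 bp
(Poisson per length, mean 15; geometric copies, mean 5), and a small
contaminant fraction (2%) of non-reference random reads exercises the
reference filter. All draws flow through one seeded generator, making
every fixture bit-reproducible.

What the fixtures deliberately do **not** model: platform-specific error
profiles (reads with errors are simply non-matching, like the
contaminants), activator-oligonucleotide or marker reads beyond the
generic contaminant class, off-target cleavage at sites that should be
uncleavable on one strand (observed in real data, mechanism unexplained),
k-mer composition bias of real genomes, and thermodynamic or kinetic
cleavage preferences. Passing end-to-end tests therefore demonstrate the
pipeline's correctness under its stated noise model, not robustness to
every artifact of real libraries.

## Problem sizes

Default test and acceptance runs use 100 kb single-record fixtures with
150 sites per motif, 20 random end-to-end recovery cases, 25-replicate
minimum-read experiments with a 10,000-read cap for the high-contamination
condition, and 100 × 2–3 kb tiling fixtures — sizes at which every result
in this repository recomputes from scratch in well under an hour on one
CPU, while keeping read counts and redundancy structure in the regimes
the filters are designed for.

## Known limitations

* Hemi-methylated sites are modeled in the digest (one cut, no excision)
  but not discoverable by the consensus pipeline, which requires
  both-strand excision; the read-cutting classifier will show them as
  one-cut fragments.
* Non-palindromic both-strand motifs are discovered as their degenerate
  strand-average and must be resolved by the deconvolution step.
* The discovery loop assumes distinct motifs mostly occupy distinct
  correctly-cut lengths; two motifs sharing a length are separable only
  when iteration plus subtraction leaves a scoring consensus, or by
  instance-frequency deconvolution of the merged call.
* Reference-free operation is not supported; exact matching to a trusted
  reference is the error model.
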