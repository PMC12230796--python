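# Methods

`tetrack` implements a reference-free inference chain for detecting, dating
and sourcing transposable-element (TE) invasions from time-stratified
sequencing data, together with a synthetic-data generator that provides
ground truth for every stage. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## The detection model

A TE family that invaded a population between two collection dates leaves
two complementary signatures:

1. **Coverage gaps.** Short reads of an *old* sample (collected before the
   invasion) aligned to the assembly of a *young* strain (collected after)
   leave zero-coverage gaps at every insertion site of the new family,
   because the old sample simply has no reads for that sequence. Extracting
   the gap sequences, clustering them by homology and collapsing each
   cluster to a consensus reconstructs the invader without any repeat
   library.
2. **Canonical vs degraded copies.** Copies of a recent invader diverge
   little from the family consensus; remnants of ancient invasions of
   related elements have decayed. A fixed divergence boundary of 1.5%
   (inclusive below = canonical) separates the two classes. Old samples
   carry only degraded copies; young samples additionally carry canonical
   ones.

Dating uses two per-sample metrics: the **copy number per haploid genome**
(mean read depth over the consensus divided by mean depth over single-copy
genes) and the **canonical fraction** (the averaged frequency of
diagnostic-SNP alleles private to canonical insertions). The invasion
window runs from the last sampled date at which no sample shows both
signals to the first date at which one does.

## Synthetic data: what it emulates, and what it does not

A TE family is modelled as a uniformly random consensus plus a single
**degraded ancestor** — the consensus mutated once at the family-level
divergence (default 8% substitutions). Degraded insertion loci are ancient
and fixed in the population, so their sequences (ancestor plus each locus's
private mutations, default 0.5%) are drawn **once per family and shared by
every sample**. Canonical copies are the consensus plus fresh private noise
(default 0.5%) per copy, drawn per sample, as recent insertions are.

This shared-ancestor structure is what makes the diagnostic-SNP machinery
non-trivial: at ~8% of consensus positions every degraded copy carries the
same non-consensus allele, old samples are near-fixed for it, and the
frequency of the consensus allele in a mixed young sample estimates the
canonical fraction of the family. Had degraded copies been mutated
independently, old samples would be fixed almost nowhere and the method
would have nothing to find.

Pooled samples are read mixtures over haploid genomes of identical copy
composition: with target canonical fraction *f* and `n_degraded` fixed
loci, the canonical copy count is the integer making
canonical/(canonical+degraded) closest to *f* (capped at 30). Reads are
single-end, uniformly positioned, with i.i.d. substitution errors (default
0.2% per base); pairing, quality strings, indel errors, GC bias, repeat
background and piRNA dynamics are all deliberately absent. Passing tests
therefore demonstrate correctness of the inference chain under its own
statistical assumptions, not robustness to every artefact of real
libraries — real data enters through the SAM and RepeatMasker adapters.

Default study conditions: 3 kb TE (the size of a typical DNA transposon of
this kind), 100 bp reads at 20-fold depth, canonical divergence 0.5%,
degraded (ancestor) divergence 8%, three single-copy genes of 2 kb as the
normalizer set. The within-genome copy-number trajectory during an
invasion is a free modelling knob: series simulations hold the degraded
copy count fixed and scale the canonical count with the trajectory
fraction.

## Alignment and scoring conventions

* Coordinates are 0-based half-open everywhere; SAM input and 1-based
  report columns convert at the boundary.
* The internal mapper is seed-and-extend: exact k-mer seeds (k = 31 for
  genome mapping at min identity 0.9; k = 13 with dense seeding and min
  identity 0.8 for the permissive consensus-mapping step, so reads from
  copies at up to ~20% divergence still anchor), candidates ranked by seed
  votes, each candidate fitted by edit-distance alignment (edlib), ties
  broken deterministically.
* **Affine-gap rescue.** Unit-cost edit paths will trade two substitutions
  for an indel pair, shifting a stretch of the read and corrupting
  per-position allele counts. Whenever a candidate alignment contains
  indels, the mapper also evaluates the gapless placement on the same
  diagonal and keeps it if it scores at least as well under the package's
  affine scheme (match +2, mismatch −3, gap existence 5, extension 2).
* **Read-end masking.** In the tracking workflows, base counts (not depth)
  within 5 bp of a read's alignment ends are masked: placement is least
  reliable there, and terminal misalignments otherwise leak minority
  alleles into low-depth sites. The pileup primitive itself defaults to no
  masking.
* Local alignment scores (gap clustering, annotation) use the same
  +2/−3/5/2 scheme; bit-scores use the Karlin–Altschul form
  (0.625·S − ln 0.41)/ln 2, so the clustering threshold of 1,000 bits
  corresponds to ~1,100 raw score (≈550 bp of exact match).
* Annotation divergence counts substitutions only, over aligned (non-gap)
  columns; indels reduce the covered consensus span (`te_span`) instead.
  Alignment ends are trimmed to the maximum-scoring segment (Kadane over
  cigar runs) before any statistic is computed; same-TE hits within 100 bp
  merge into one insertion.

## Thresholds and their provenance

| parameter | default | role |
|---|---|---|
| canonical boundary | 1.5% divergence, inclusive | canonical/degraded split |
| annotation filters | ≥300 bp, ≤20% divergence | drop sub-fragment noise |
| clustering threshold | 1,000 bits | homology edges between gap sequences |
| gap depth tolerance | 0 (strictly uncovered) | real libraries may need ≥1 |
| minimum gap length | 500 bp | below TE-fragment scale, above noise |
| gap merge separation | <50 covered bases | one stray read must not split a candidate |
| diagnostic SNP | old >0.95 fixed, young alt >0.1, depth ≥10 | site qualification |
| full-length span | >0.8 of consensus | cross-species comparison set |
| invasion call | canonical fraction ≥0.1 AND copies ≥0.5 | both metrics required |
| HT support | quantile rank ≤0.05 | TE less diverged than ≥95% of genes |

The boundary, annotation, SNP, full-length and HT values are the method's
published operating points; the gap-geometry values, the depth floor of 10
and the invasion-call thresholds are this package's declared
operationalizations of choices the method leaves open.

Two readings deserve a note. The diagnostic-SNP rule is stated in the
literature as a "minor allele frequency >0.95" in the old sample, which a
minor allele cannot satisfy; the only consistent reading — implemented
here — is that the old sample is near-fixed (>0.95) for one allele while
the young sample carries an alternative above 0.1. And the
presence/absence fallback (frequency 1.0 if any read aligns, 0.0
otherwise) is applied at series level only when the old reference sample
has **zero** aligned reads: for a family with an old-sample degraded
background but no diagnostic site, the canonical signal is reported as
absent rather than present, otherwise every ancient family would be
called a fresh invasion.

## The horizontal-transfer test

Nucleotide divergence is computed on a global alignment with terminal gap
runs excluded (truncated ends are length artefacts, not substitutions);
pairs whose divergence exceeds 0.25 are deemed unalignable (random
sequence pairs land near 0.30 under this metric and raise an error rather
than a number). The test ranks the divergence of the two most similar
cross-species insertions within the empirical ortholog divergence
distribution; exact ties count one half. At least 20 ortholog pairs are
required for the distribution to be meaningfully estimable.

## Numerical and degenerate-input conventions

Consensus calling drops alignment columns with >50% gaps (unique flanking
context votes itself out) and breaks base ties A<C<G<T. Copy number
includes uncovered consensus positions as zeros, and the gene normalizer
averages over the concatenated positions of all genes (length-weighted).
Zero gene depth, all-hitless similarity sets, empty FASTA records,
out-of-bounds coordinates and unalignable pairs raise explicit errors.
All randomness flows through a single seed per entry point
(`numpy.random.default_rng`); identical configuration and seed give
bit-identical outputs.

## Problem sizes used in the test suite

End-to-end checks run at desk scale: rediscovery on a 200 kb assembly with
five planted 3 kb copies at 20-fold depth; dated series of ten yearly
samples with a 5 kb neutral background, two fixed degraded loci and up to
eight canonical copies, twenty replicate seeds; twenty-replicate
canonical-fraction recovery at the 80:20 canonical:degraded composition.
These sizes recover the planted truth with comfortable statistical margins
while keeping the full suite in a few minutes.

## Known limitations

* The internal scanner assumes seeds survive in diverged copies; families
  beyond ~25% divergence from their consensus need the RepeatMasker
  adapter.
* The mapper reports one best locus per read; multi-mapping reads inside
  identical repeat copies are assigned deterministically, which is
  appropriate for consensus-space pileups but not for locus-resolved
  frequency estimation (explicitly out of scope).
* The geographic layer aggregates by declared region labels; no spatial
  interpolation or map rendering is attempted.
* Divergence-based dates inherit the sampling resolution of the series;
  the invasion window is bounded by adjacent sampling dates, never
  interpolated between them.
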