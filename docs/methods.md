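# Methods

## Model

An RCA concatemer read is modelled as `errors(rotate(T, φ) repeated p
times)`, where `T` is the circular template — an ordered cycle of `k`
genomic fragments (chromosome, 0-based half-open interval, strand),
`φ` a uniformly random start phase, and `p` the number of passes. Under
this model the read's sub-read alignments, sorted by query start, carry a
locus-label sequence that is the periodic extension of the fragment cycle
starting at an arbitrary rotation. The caller inverts the model
deterministically; no resampling or probabilistic scoring is involved.
All coordinates are 0-based half-open throughout (PAF convention).

Assumptions the caller makes:

- the aligner emits one primary alignment per pass per fragment, with
  boundary errors bounded by the offset tolerance;
- sub-reads of one read never legitimately visit the same locus on both
  strands (such reads are chimeric or inverted-duplication artifacts and
  are discarded as strand-discordant, even when the label sequence is
  periodic);
- a read that cannot be explained by a single cycle is discarded whole,
  never salvaged partially.

## Caller parameters

| parameter | default | role |
|---|---|---|
| `min_mapq` | 30 | sub-reads below this mapping quality are discarded |
| `max_offset` | 20 bp | start/end tolerance for two sub-reads to share a locus |
| `min_full_passes` | 2 | minimum full passes (min over fragments of full sub-read counts) |
| `max_query_overlap` | 20 bp | query overlap at a junction absorbed by threading |
| `max_junction_gap` | 50 bp | unaligned query at a junction absorbed by threading |
| `min_depth` | 4 | covering sub-reads required to call a variant |
| `min_af` | 0.75 | minimum alternate allele frequency |

The first two and the pass/variant thresholds are the established
operating point for this assay; the junction tolerances are alignment
soft-clip allowances (aligner end-trimming rarely exceeds a few tens of
bases on ~1 kb fragments).

"Full pass" is deliberately the *minimum* over fragments of full
(non-truncated) sub-read counts — the strictest reading, guaranteeing
every base of the circle was sequenced at least that many times.

## Numerical and tie-break choices

- **Cluster membership** is tested against the first-seen representative,
  not by complete linkage: deterministic, order-stable, O(n·k).
- **Partial flanking passes.** The first/last sub-read of a read may be a
  truncated pass (the concatemer starts or stops mid-fragment). Such a
  sub-read attaches to its cluster only when it matches one boundary
  within `max_offset` and is truncated on the other side by *more than
  2×max_offset* — jitter moves both ends by at most `max_offset`, so
  jitter alone can never masquerade as a partial pass. Partial members
  vote only for the boundary they fully reach and do not count as
  passes. Consequence: a read whose phase falls within
  (`max_offset`, 2×`max_offset`] of a fragment boundary is rejected
  (the flank is indistinguishable from a discordant locus); on default
  simulations this rejects ~5–10% of random-phase reads, a conservative
  and deterministic loss.
- **Boundary voting** is the mode of member starts and of member ends,
  independently; ties take the lower median of the tied values.
- **Threading** computes, per junction, the lower median of
  `qstart(next) − qend(prev)` over rank-adjacent sub-read pairs and
  assigns it entirely to the upstream fragment's 3′ genomic boundary in
  strand orientation (extension for gaps, trim for overlaps). Splitting
  the gap across both fragments would create half-base ambiguity and has
  no evidential basis. Out-of-tolerance junctions are flagged, not
  adjusted; an adjustment that would invert a fragment rejects the circle.
- **Variant calling** emits at most one variant per position (highest
  count, ties to the lexicographically smaller allele). Variants within
  `max_offset` of a voted boundary are suppressed: alignment-end jitter
  piles artifactual mismatches there. Insertions > 50 bp in one cs op are
  treated as unaligned junction sequence and ignored.
- **Consensus rotation.** The consensus starts at the voted start of the
  canonical first fragment (lexicographically smallest rotation) and
  follows the read's traversal orientation, so reads of the same molecule
  in the same orientation produce byte-identical strings; opposite-
  orientation reads produce reverse complements (equal as circular
  sequences).
- **Unique-molecule identity** is the full ordered fragment tuple,
  canonicalized over all rotations and the reverse traversal (order
  reversed, strands flipped): two circles joining the same fragments in
  different cyclic orders are distinct molecules. Fragment-level
  deduplication for coverage uses exact (chrom, start, end) and ignores
  strand. Boundary-jittered near-duplicates are *not* merged.
- **Size-ladder statistic**: 1 bp histogram over [0, 3000], centred
  moving average (window 11), peaks with prominence ≥ 5% of the maximum
  and pairwise separation ≥ 50 bp (well under one nucleosome repeat, so
  genuine rungs are never merged while noisy plateau tops do not
  double-count); the statistic is the mean successive peak spacing.
  Fewer than two peaks → explicitly undefined.

## What the simulator emulates — and what it does not

The simulator generates uniform-composition reference chromosomes
(4 autosomes + chrX, 400 kb each by default), circle templates, and reads
either as FASTQ (iid substitution/insertion/deletion errors) or directly
as PAF records with cs tags, bypassing the aligner. Direct-PAF is the
primary test path: it controls exactly what the caller sees.

Defaults encode the biology the catalog statistics measure:

- circle length = 188·m + Normal(0, 15) with nucleosome multiplicity m
  geometric(p = 0.13) capped at 16 — median ≈ 5 nucleosomes ≈ 0.95 kb;
- fragment count 1–7, heavily weighted to 1 (85% continuous);
- reads per circle = 1 + Poisson(0.117), so the expected single-event
  fraction is e^−0.117 ≈ 0.89;
- passes per read = 2 + Poisson(1.7);
- chrX sampled at half the autosomal per-base rate (male diploid copy
  number).

Alignment-boundary jitter is implemented as *subtractive* end-clipping
(uniform 0..J off each alignment end, the clipped bases becoming
unaligned query): extending an alignment past the truth would claim
query and reference bases that do not exist and break the invariant that
cs-implied spans equal the record's coordinates. Threading re-absorbs
the clipped gaps.

Not emulated: basecalling signal, homopolymer-structured error profiles,
chimeric reads, reference repeats/multi-mapping ambiguity, and
aligner-specific split heuristics. Passing tests therefore demonstrate
correctness of the decomposition logic under its stated assumptions, not
robustness to every real-data alignment pathology.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale: 200-circle
batches for recovery measurements, a 1,500-circle default-condition
catalog for event-count/size statistics, 5,000 lengths for the ladder
statistic, and 10,000 fragments for the X/autosome density ratio — sizes
at which the multinomial/binomial sampling error of each statistic is
comfortably inside the property bounds being asserted. Everything
completes in seconds on one CPU.

## Known limitations

- Reads whose phase falls in the narrow dead zone near a fragment
  boundary are rejected rather than recovered (see above).
- Long-form cs and CIGAR-only PAF records are accepted but carry no
  variant information; affected fragments are reference-only in the
  consensus.
- Circles with fragments shorter than ~2×`max_offset` cannot be reliably
  separated from jitter and are not specifically modelled.
- Single-pass (< 2 full passes) circles are out of scope by design, as is
  large ecDNA/double-minute reconstruction.
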