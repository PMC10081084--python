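# Methods

`insertra` characterizes a single semi-random transgene insertion in a
repeat-rich genomic region, entirely on synthetic genomes with planted ground
truth. This note documents the forward model, the analytic procedures, the
numerical choices, and what the synthetic study conditions do and do not show
about real data.

## The problem

piggyBac-class transposons integrate at TTAA motifs and duplicate the motif on
both sides of the cargo (target-site duplication, TSD). When the integration
lands in pericentromeric heterochromatin, the sequence immediately flanking the
transgene belongs to a family of near-identical repeats with many copies across
the genome. Junction evidence of a few hundred base pairs — inverse-PCR
products, clipped short reads — then matches every family copy at high
identity, and the insertion locus cannot be assigned. Resolution requires
evidence that reaches past the repetitive context into unique sequence (long
reads), or an orthogonal physical method (in situ hybridization, whose tally
arithmetic is the only part represented here).

## Forward model

### Host genome

Random uniform A/C/G/T background over ≥2 named chromosomes, with:

* **A repeat family** derived from one random ancestor by independent per-base
  substitution at rate *d* per copy (replacement uniform over the three
  alternatives). Two copies match at a site with probability
  `(1−d)² + d²/3`; the default *d* = 0.03 gives an expected pairwise identity
  of ≈ 0.941, so every copy pair sits inside the ≥ 0.90 identity band that
  defines the family. The substitution-only model keeps copies column-aligned,
  which lets planted motifs sit at fixed offsets in every copy.
* **Planted motifs.** Every copy carries the designated insertion TTAA at
  offset 375 (flanked by fixed C/G bases so the motif can never be part of a
  stray DraI site) and DraI (TTT^AAA) sites at offsets 0 and 744; other DraI
  occurrences inside copies are scrubbed. This makes the in-silico inverse PCR
  deterministic: both junction fragments are cut ~370 bp from the insertion
  point, inside the repeat copy.
* **A decoy repeat** (700 bp at 12% divergence) 140 bp upstream of the copy
  that hosts the insertion. It is too diverged to pass the candidate-identity
  threshold but extends the repetitive 5' context to ≈ 1.2 kb before unique
  sequence begins — the "unique island" structure that long reads must reach.
* **An endogenous gene** (promoter 600 bp, terminator 500 bp intervals on a
  different chromosome from the insertion): the donors of the construct's
  3n-class features.
* **Single-copy windows**, each verified unique genome-wide by exhaustive
  substring counting.

Two layouts ship as study conditions. *Full* (the ambiguity scenario): 1.5 Mb
haploid (≈ 3 Mb diploid), 12 repeat copies ≥ 80 kb apart on two chromosomes.
*Compact* (everything else, chosen so that repeated 30× simulations stay
desk-fast): 90 kb haploid, 6 copies ≥ 14 kb apart. The compact spacing and the
2 kb linkage window (below) preserve the geometric relations of the full
layout at smaller scale.

### Construct

ITR(250) — spacer(120) — marker "DsRed" role (680, class n) — spacer(60) —
promoter (600, class 3n, copied *verbatim* from the endogenous donor) —
payload "eGFP::I-PpoI" role (6200, class n) — terminator (500, 3n, verbatim
donor copy) — spacer(120) — ITR(250); 8 780 bp total. One DraI site is planted
in each terminal spacer (≈ 300 bp from either end) and one ScaI site in the 5'
spacer; all other DraI/ScaI occurrences in the synthetic parts are scrubbed
(donor-derived parts stay byte-identical to the genome). The construct is
forbidden from starting with A or ending with T, the only two ways a DraI site
could straddle a TSD junction. Outward-facing primer pairs near each ITR are
recorded for the inverse PCR.

### Insertion and reads

`insert_transgene` produces `left + TTAA + construct + TTAA + right` on one
haplotype (het) or both (hom); excising the construct plus one TSD copy
restores the input byte-exactly, which is asserted as an invariant.

Short reads: paired 2×150 bp from ~350 ± 50 bp fragments drawn
length-proportionally over both haplotypes; substitution-only errors (default
0.5%); constant Q30 (depth analysis is quality-agnostic). "30×" means expected
depth 30 at a locus present on both haplotypes. Long reads: ~8 ± 1.5 kb
(truncated to [2, 11] kb), mixed errors at default 8% split 40/30/30
substitution/insertion/deletion, constant Q12. An anchoring option constrains
a chosen number of reads to overlap the insertion region, emulating the
extraction of reads aligning to the expected insertion locus prior to
assembly; background reads at ~0.9× keep the genome-wide coverage in the
sub-10× regime.

All randomness fans out from one top-level seed through
`sha256(seed, labels…) mod 2³¹` child seeds; every generator is byte-
deterministic given the seed.

## Alignment core

A self-contained mapper keeps the pipeline free of external aligners.
Affine-gap local alignment (match +2, mismatch −3, gap open −5, extend −2; a
gap of length *g* costs `open + g·extend`) is implemented as a full dynamic
program with traceback (numba kernels); identity is matching columns over all
alignment columns. One scoring matrix is shared by every identity computation
in the package.

`map_read` seeds with exact 15-mers (forward-strand index; queries are
reverse-complemented), clusters seeds by diagonal, and extends candidates with
the full DP over a ±50 bp band window. Placements with ≤1 mismatch skip the DP:
any gapped alignment is bounded by `2L − 7` while such a placement scores
≥ `2L − 5`, so the shortcut is provably score-exact. The mapper reports *every*
locus tying the best score; mapq is 40 when unique and 0 otherwise — the
pipeline only consumes the unique/ambiguous distinction. An optional
secondary-reporting mode (score ≥ 70% of best, flagged secondary, mapq 0)
exists because multi-mapping inflation is invisible in a closed synthetic
genome if only tied-best placements are reported; the repeat-flank flagging
below is its consumer. `local_search` applies the same seed-and-extend
machinery to longer queries and reports identity and alignment length per hit,
ties broken by (reference name, start) so reports are reproducible.

Long-read work (assembly overlaps, consensus polishing, contig anchoring) uses
edit-distance alignment via edlib instead, which is the right tool for
indel-rich 8 kb sequences where affine scoring adds nothing.

## Junction evidence

Split reads are primary alignments with a soft clip ≥ 20 bp whose clipped
sequence maps to the other reference class (clips shorter than the seed length
are unverifiable, hence the default); discordant pairs have mates on different
classes, and both mates must map uniquely for the pair to count. Flank
consensus stacks junction-anchored genomic tails — clipped tails of
construct-anchored reads, plus the aligned genomic segments of genome-anchored
split reads, whose junction boundary is corrected by where their clip maps
inside the construct (a local aligner may extend a few coincidentally matching
bases across the junction; the clip's construct coordinate says exactly how
many). Majority vote per column, ties broken alphabetically; columns with < 2
supporting tails are trimmed, so the consensus grows outward from the junction
only as far as evidence reaches. With error-free reads the consensus is
byte-identical to the planted flank; the TSD call then simply asks whether the
5' consensus ends with TTAA and the 3' consensus begins with it.

Long-read assembly is greedy overlap-layout-consensus, adequate and auditable
at desk scale (tens of reads): reads containing a construct anchor (marker or
payload, matched permissively at ≥ 75% identity via edit-distance tiles of
≤ 400 bp so partial anchor coverage qualifies) are oriented to the anchor
strand; the pair with the best suffix–prefix overlap (≥ 500 bp at ≥ 80%
identity, offset estimated from shared 13-mers, validated by edit distance) is
merged repeatedly; the longest anchored contig is polished twice by pileup
majority vote (bases, deletions, and majority insertions). At 8% read error
and ~10× local depth the polished contig is ≥ 99.8% identical to the truth
haplotype over the construct span.

## Copy number

A heterozygous carrier holds construct-unique features once (n), ordinary loci
twice (2n), and promoter/terminator three times (two endogenous alleles + one
transgenic). Mean depth per feature is computed from uniquely placed
alignments (mapq > 0; M/D ops consume reference), normalized as
`cn = 2·depth / median(panel of 15 random 20 bp 2n loci)`. The median is
robust to a panel locus accidentally overlapping unannotated repeats; by
construction the panel's own estimates have median exactly 2. The panel is the
yardstick: dosage recovery is judged on the estimated features (marker,
payload, promoter, terminator), since a single 20 bp window at 30× carries
~17% depth noise individually.

Because the construct's 3n features are verbatim donor copies, reads interior
to them always tie between exactly two placements (construct copy ↔ endogenous
locus) and a plain mapq filter would discard them, making the 3n class
unrecoverable. Such two-way construct↔donor ties carry no dosage ambiguity, so
the pipeline reassigns them to the endogenous locus before depth is computed
and measures 3n dosage there, over the feature interior (trimmed by one read
length per side — feature-edge positions are partially covered by
construct-origin fragments that map construct-uniquely, which would dilute the
estimate by design rather than by noise).

Repeat-inflation flagging is the deliberate mirror image: per-base depth
counting *all* placements, secondaries included, flags maximal runs above
2× the 2n baseline (runs merged across < 10 bp gaps). Around an insertion
planted in the repeat cluster this marks the flanking repeat copy at several
times baseline while the copy-number features stay clean — separating dosage
signal from multi-mapping inflation.

## In-silico assays

Restriction digestion cuts at every motif occurrence (both strands for
non-palindromic motifs; DraI and ScaI presets are palindromic), preserving
`Σ fragment lengths = template length` as an invariant; circular templates are
supported for the inverse-PCR intermediate. A Southern fragment is
probe-positive when the probe aligns over ≥ 100 bp at ≥ 90% identity (declared,
configurable; exact containment short-circuits). With a payload probe the
positive count reads out insertion copy number: 1 / 0 / 2 for the single
insertion, wild type, and double insertion.

Inverse PCR digests the carrier haplotype, takes the unique fragment bearing
both primers, circularizes it, and walks from the forward primer through the
fragment junction to the reverse primer site. The genomic portion is split out
exactly using the enzyme's cut position inside the construct (the two cut ends
share motif bases, so naive longest-match splitting overshoots). The recovered
5'/3' flanks are byte-exact against the truth genome, and their concatenation
(dropping one TSD copy) reconstructs the ~744 bp pre-insertion locus — the
flank query used for candidate ranking.

The dot-plot operation reports every shared k-mer (both orientations) between
two sequences, is transpose-symmetric, and writes TSV or renders a scatter
image.

## Locus resolution

Candidates are `local_search` hits of the flank query against the clean
reference passing identity ≥ 0.90 and alignment length ≥ 700 columns, with a
TTAA required within ±4 bp of the junction-mapped position; ranking is by
score with (chrom, start) tie-breaks, so it is a total order independent of
input order. In both layouts every family copy passes — flank-only evidence is
ambiguous by construction.

Long-read integration locates the construct inside the contig (edit distance ≤
20% of construct length), chops the contig flanks into windows of the minimum
unique-flank size (default 500 bp, stride half a window), and searches each
window against the reference. A window that maps *uniquely* (exactly one hit
at ≥ 90% identity covering ≥ 80% of the window) and lies within the linkage
window of exactly one candidate (25 kb at full scale — generous relative to
the ≥ 80 kb copy spacing; 2 kb at compact scale, matching its 14 kb spacing)
resolves that candidate. Exactly one resolved candidate clears the ambiguity
flag; two or more are all flagged and ambiguity stands (a contradictory contig
is reported, never silently broken); a unique segment adjoining the junction
but linked to no candidate is reported as a flank-discordant novel locus,
never silently substituted.

Signal-tally summaries round percentages half away from zero, reproducing the
94% (59/63) and 70% (38/54) arithmetic of the reference tallies.

## Pipeline, configuration, reporting

`run_pipeline` orchestrates simulate → map → junctions → copy number → assays
→ resolve, writing FASTA/FASTQ/SAM/BED/TSV/JSON artifacts and a
schema-versioned JSON report with fixed key order; a rerun with the same
configuration is byte-identical. Configuration is a single YAML with sections
genome/construct/insertion/reads/analysis; unknown keys are errors (fail
fast). The `insertra` CLI exposes the stages; each error class maps to a
distinct exit code.

## Problem sizes and tolerances

Replicated analyses use 10 seeds: the ambiguity→resolution scenario at full
scale (12 candidates expected; resolution in ≥ 9/10), copy-number recovery at
30× on the compact layout (class means 1/2/3, feature MAE ≤ 0.25 copies), TSD
and byte-exact flank recovery at 20 random TTAA sites (12 kb windows around
each site keep the repeated simulations fast without changing the junction
physics). These sizes are the package's study conditions, chosen once with
the geometry above.

## Limitations

The synthetic model omits GC and coverage bias, PCR duplicates, realistic
base-quality profiles, structural variants beyond the single insertion, and
sequence context beyond uniform random background plus one repeat family;
passing tests demonstrate the *logic* of junction recovery, dosage estimation
and ambiguity resolution under controlled conditions, not performance on real
libraries. The mapper targets desk-scale genomes (≤ 5 Mb) and makes no claim
of parity with production aligners; the greedy assembler presumes tens, not
thousands, of reads. Repeat copies are column-aligned by construction
(substitution-only divergence); tandem-repeat expansion/contraction and
nested-element structure of real pericentromeric DNA are not modeled.
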