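# insertra

Characterization of a semi-random transgene insertion in a highly repetitive
genomic region — junction and flank recovery, coverage-class copy-number
estimation, repeat-ambiguity scoring of candidate loci, and long-read
resolution — exercised entirely on synthetic genomes with planted ground
truth.

## The problem

piggyBac-class transposons integrate wherever a TTAA motif allows, duplicating
the motif on both sides of the cargo (the target-site duplication, TSD). When
integration lands in pericentromeric heterochromatin, the immediate flanks
belong to a family of near-identical repeats: a recovered flank of a few
hundred base pairs matches *every* family copy at >90% identity, and the
insertion cannot be assigned to a locus. `insertra` implements the full
analytic workflow around this problem for vector-control–style transgenic
strains (the motivating system is a transgenic *Anopheles* sex-distorter
line), and — because real genomes of this kind are not desk-reproducible —
pairs it with a forward model that plants an insertion with complete ground
truth, so every claim the pipeline makes is testable.

## The core quantities

* **Copy number by coverage class.** In a heterozygous carrier, a
  construct-unique feature (fluorescent marker, effector payload) is present
  in one copy (*n*), an ordinary autosomal locus in two (*2n*), and a feature
  shared between the construct and an endogenous gene — the β2-tubulin
  promoter/terminator — in three (*3n*). With `d̄₂ₙ` the median depth of a
  panel of random single-copy 20 bp loci,

      cn(f) = 2 · depth(f) / d̄₂ₙ

  recovers 1 / 2 / 3 and, together with an in-silico Southern blot (number of
  probe-positive restriction fragments), establishes a single insertion.
* **Candidate-locus ambiguity.** The flank query recovered by in-silico
  inverse PCR is searched against the reference; hits with identity ≥ 0.90
  over ≥ 700 aligned columns that carry a junction TTAA are candidate loci.
  In the repeat cluster, every family copy qualifies.
* **Long-read resolution.** A greedy overlap-layout-consensus contig built
  from anchor-containing long reads is scanned for segments of ≥ 500 bp that
  map uniquely near exactly one candidate; that candidate is promoted to
  `long_read_resolved` and the ambiguity flag cleared.

All alignment runs on an in-package seed-and-extend mapper over an exact
k-mer index with affine-gap Smith–Waterman extension (match +2 / mismatch −3 /
gap −5 − 2g), reporting every tied-best locus so unique and ambiguous
placements are cleanly separated.

## Worked example

Run the complete pipeline on the default compact study genome (90 kb haploid,
6-copy repeat cluster, heterozygous insertion planted at the TTAA inside one
copy, 30× short reads + noisy long reads):

```bash
insertra all --seed 7 --out results/demo
# resolved; 6 candidate loci
```

`results/demo/report.json` (excerpts, as printed by the run above):

```json
"candidates":        6 loci, all identity >= 0.90 over 744 columns, all with TTAA,
"ambiguous":         false,
"resolved_locus":    {"chrom": "chr2", "start": 34003, "end": 34747,
                      "evidence_tier": "long_read_resolved", "rank": 1},
"tsd_call":          {"present_5prime": true, "present_3prime": true},
"copy_number_verdict": {
  "reference_2n_depth": 31.35,
  "features": {
    "DsRed_marker":       {"class": "n",  "cn": 0.841, "consistent": true},
    "eGFP_IPpoI_payload": {"class": "n",  "cn": 0.921, "consistent": true},
    "beta2_promoter":     {"class": "3n", "cn": 3.012, "consistent": true},
    "beta2_terminator":   {"class": "3n", "cn": 2.933, "consistent": true}},
  "repeat_inflated_flanks": [[33354, 33694], [34007, 34747]]},
"assay_summaries": {
  "inverse_pcr":    {"flank5_len": 376, "flank3_len": 372},
  "southern_DraI":  {"positive_fragments": [8160]}}
```

Reading it: flank evidence alone ties six repeat copies (the ambiguity);
the long-read contig resolves the planted locus chr2:34003–34747 — the truth
in `results/demo/truth.json` is site 34375, inside that interval. Marker and
payload sit at ~1 copy, the shared promoter/terminator at ~3, against a 2n
reference depth of 31.35×; the single DraI probe-positive fragment (8 160 bp)
confirms one insertion; and the immediate flanking repeat shows the
multi-mapping depth inflation (`repeat_inflated_flanks`) expected when an
insertion sits inside a repeat cluster.

The library surface mirrors the stages: `insertra.synthetic_data` (forward
model), `insertra.align_core` (mapper/search), `insertra.junction_evidence`
(split/discordant reads, flank consensus, TSD, long-read assembly),
`insertra.copy_number`, `insertra.insilico_assays` (digest/Southern, inverse
PCR, dot plots), `insertra.locus_resolver` (ranking, integration,
orchestration). See `docs/methods.md` for the model and every numerical
choice.

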