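"""Forward-model tests: repeat family statistics, genome/construct assembly,
insertion round-trips, and read simulators checked against their ground truth."""

import numpy as np
import pytest
from Bio import Align

from insertra.errors import BoundsError, LayoutError, MotifError, ParameterError
from insertra.seqs import count_occurrences, read_bed, revcomp, write_bed
from insertra.synthetic_data import (ConstructSpec, build_construct, build_host_genome,
                                     default_genome_spec, excise_transgene,
                                     insert_transgene, make_repeat_family,
                                     simulate_long_reads, simulate_short_reads)


def pairwise_identity(a: str, b: str) -> float:
    """Oracle: global pairwise alignment identity via Bio.Align."""
    aligner = Align.PairwiseAligner(mode="global", match_score=1, mismatch_score=0,
                                    open_gap_score=-5, extend_gap_score=-2)
    return aligner.score(a, b) / max(len(a), len(b))


class TestRepeatFamily:
    def test_zero_divergence_copies_identical(self):
        fam = make_repeat_family(100, 3, 0.0, seed=5)
        assert len(fam) == 3
        assert fam[0] == fam[1] == fam[2]
        assert len(fam[0]) == 100

    def test_mean_pairwise_identity_in_band(self):
        fam = make_repeat_family(750, 12, 0.04, seed=5)
        idents = [pairwise_identity(fam[i], fam[j])
                  for i in range(12) for j in range(i + 1, 12)]
        assert len(idents) == 66
        assert 0.90 <= np.mean(idents) <= 0.95

    def test_seeded_determinism(self):
        assert make_repeat_family(750, 12, 0.04, 9) == make_repeat_family(750, 12, 0.04, 9)

    @pytest.mark.parametrize("args", [(10, 3, 0.1), (100, 0, 0.1), (100, 3, 0.5)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ParameterError):
            make_repeat_family(*args, seed=1)


class TestHostGenome:
    def test_annotations_roundtrip_bed(self, compact_genome, tmp_path):
        path = tmp_path / "truth.bed"
        rows = compact_genome.truth_intervals()
        write_bed(path, rows)
        assert read_bed(path) == rows

    def test_repeat_copies_match_family_consensus(self, compact_genome):
        consensus = compact_genome.meta["family_consensus"]
        for ann in compact_genome.repeat_annotations:
            if ann.family_id.endswith("decoy"):
                continue
            copy = compact_genome.fetch(ann.chrom, ann.start, ann.end)
            assert pairwise_identity(copy, consensus) >= 0.90

    def test_unique_windows_occur_exactly_once(self, compact_genome):
        assert len(compact_genome.unique_windows) >= 15
        for chrom, s, e, _name in compact_genome.unique_windows:
            seq = compact_genome.chromosomes[chrom][s:e]
            assert count_occurrences(compact_genome.chromosomes, seq) == 1

    def test_repeat_cluster_spans_two_chromosomes(self, compact_genome):
        chroms = {a.chrom for a in compact_genome.repeat_annotations
                  if not a.family_id.endswith("decoy")}
        assert len(chroms) >= 2

    def test_overlapping_placement_rejected(self):
        spec = default_genome_spec("compact", seed=1)
        bad = list(spec.repeat.placements)
        bad[1] = (bad[0][0], bad[0][1] + 100)  # overlaps copy 0
        spec.repeat.placements = tuple(bad)
        with pytest.raises(LayoutError):
            build_host_genome(spec)


class TestConstruct:
    def test_length_conservation_and_itrs(self, construct):
        assert len(construct.full_sequence) == sum(len(f.sequence)
                                                   for f in construct.features)
        assert construct.full_sequence.startswith(construct.itr5)
        assert construct.full_sequence.endswith(construct.itr3)

    def test_3n_features_occur_twice_in_combined_reference(self, compact_genome,
                                                           construct):
        combined = {**compact_genome.chromosomes, "tg": construct.full_sequence}
        for name in ("beta2_promoter", "beta2_terminator"):
            seq = construct.feature(name).sequence
            assert count_occurrences(combined, seq, both_strands=False) == 2

    def test_empty_payload_still_valid(self, compact_genome):
        c = build_construct(ConstructSpec(seed=3, payload_len=0), compact_genome)
        assert c.full_sequence.startswith(c.itr5)
        assert c.full_sequence.endswith(c.itr3)

    def test_marker_is_unique_in_genome(self, compact_genome, construct):
        assert count_occurrences(compact_genome.chromosomes,
                                 construct.marker.sequence) == 0


class TestInsertion:
    def test_excision_roundtrip(self, compact_genome, construct, het_diploid):
        diploid, event = het_diploid
        hap = diploid.haplotypes["hapA"][event.chrom]
        restored = excise_transgene(hap, event.site, len(construct.full_sequence))
        assert restored == compact_genome.chromosomes[event.chrom]

    def test_het_length_difference(self, construct, het_diploid):
        diploid, event = het_diploid
        dA = len(diploid.haplotypes["hapA"][event.chrom])
        dB = len(diploid.haplotypes["hapB"][event.chrom])
        assert dA - dB == len(construct.full_sequence) + 4

    def test_tsd_duplicated_on_both_sides(self, construct, het_diploid):
        diploid, event = het_diploid
        hap = diploid.haplotypes["hapA"][event.chrom]
        L = len(construct.full_sequence)
        assert hap[event.site:event.site + 4] == "TTAA"
        assert hap[event.site + 4 + L:event.site + 8 + L] == "TTAA"

    def test_truth_records_surrounding_repeat(self, het_diploid):
        _, event = het_diploid
        assert event.repeat_family_id == "pericentromeric750"
        assert event.repeat_copy_id == 2

    def test_non_ttaa_site_rejected(self, compact_genome, construct):
        chrom = "chr2"
        seq = compact_genome.chromosomes[chrom]
        site = next(i for i in range(1000, 2000) if seq[i:i + 4] != "TTAA")
        with pytest.raises(MotifError):
            insert_transgene(compact_genome, construct, chrom, site)

    def test_site_near_chromosome_end_rejected(self, compact_genome, construct):
        with pytest.raises(BoundsError):
            insert_transgene(compact_genome, construct, "chr2", 2)


class TestShortReads:
    def test_error_free_reads_are_exact_substrings(self, het_diploid):
        diploid, _ = het_diploid
        rs = simulate_short_reads(diploid, 300, sub_error=0.0, seed=3)
        rs.validate()
        for r in rs.reads:
            hap, chrom, start, strand = r.truth_origin
            src = diploid.haplotypes[hap][chrom][start:start + len(r.sequence)]
            assert r.sequence == (src if strand == "+" else revcomp(src))

    def test_depth_matches_target_coverage(self, het_diploid):
        diploid, event = het_diploid
        l_dip = sum(len(s) for _, _, s in diploid.sequences())
        rs = simulate_short_reads(diploid, l_dip // 20, seed=5)  # 30x target
        # oracle: per-position depth over a unique 10 kb window from truth intervals
        lo, hi = 52_000, 62_000  # unique chr2 region in the compact layout
        depth = np.zeros(hi - lo)
        for r in rs.reads:
            hap, chrom, start, _ = r.truth_origin
            if chrom != "chr2":
                continue
            a, b = max(start, lo), min(start + 150, hi)
            if a < b:
                depth[a - lo:b - lo] += 1
        assert 24 <= depth.mean() <= 36  # 30x ± 20%

    def test_same_seed_identical_fastq(self, het_diploid, tmp_path):
        diploid, _ = het_diploid
        p1, p2 = tmp_path / "a1.fq", tmp_path / "a2.fq"
        q1, q2 = tmp_path / "b1.fq", tmp_path / "b2.fq"
        simulate_short_reads(diploid, 200, seed=9).write_fastq(p1, p2)
        simulate_short_reads(diploid, 200, seed=9).write_fastq(q1, q2)
        assert p1.read_bytes() == q1.read_bytes()
        assert p2.read_bytes() == q2.read_bytes()

    def test_bad_parameters(self, het_diploid):
        diploid, _ = het_diploid
        with pytest.raises(ParameterError):
            simulate_short_reads(diploid, 0)
        with pytest.raises(ParameterError):
            simulate_short_reads(diploid, 10, sub_error=0.5)


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, het_diploid):
        diploid, _ = het_diploid
        rs = simulate_long_reads(diploid, 20, error_rate=0.0, seed=4)
        for r in rs.reads:
            hap, chrom, start, strand = r.truth_origin
            src = diploid.haplotypes[hap][chrom][start:start + len(r.sequence)]
            assert r.sequence == (src if strand == "+" else revcomp(src))

    def test_anchored_read_spans_five_prime_junction(self, construct, het_diploid):
        diploid, event = het_diploid
        ci = diploid.construct_interval("hapA")
        # anchor tightly across the 5' junction so every read covers it
        rs = simulate_long_reads(diploid, 0, error_rate=0.0, seed=4,
                                 anchor_interval=("hapA", event.chrom,
                                                  ci[0] - 500, ci[0] + 500),
                                 n_anchored=5, min_anchor_overlap=1000)
        junction = "TTAA" + construct.itr5[:30]
        assert all(junction in r.sequence or junction in revcomp(r.sequence)
                   for r in rs.reads)

    def test_low_coverage_regime(self, het_diploid):
        diploid, _ = het_diploid
        rs = simulate_long_reads(diploid, 20, length_mean=8000, seed=6)
        total = sum(len(r.sequence) for r in rs.reads)
        l_dip = sum(len(s) for _, _, s in diploid.sequences())
        assert total / l_dip < 10  # oracle: total bases / genome length

    def test_error_rate_bounds(self, het_diploid):
        diploid, _ = het_diploid
        with pytest.raises(ParameterError):
            simulate_long_reads(diploid, 5, error_rate=0.5, seed=1)
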