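"""Junction-evidence tests: informative-read extraction against truth-derived
counts, flank consensus exactness, TSD detection, and long-read assembly."""

import edlib
import pytest

from insertra.errors import EvidenceError, ParameterError
from insertra.junction_evidence import (assemble_long_reads, build_flank_consensus,
                                        detect_tsd, extract_informative_reads)
from insertra.seqs import revcomp
from insertra.synthetic_data import simulate_long_reads, simulate_short_reads


@pytest.fixture(scope="module")
def informative(mapped):
    return extract_informative_reads(
        mapped.records, {mapped.construct.name}, 20,
        mapped.genome_index, mapped.construct_index,
        len(mapped.construct.full_sequence))


def anchors_for(construct):
    return {"marker": construct.marker.sequence,
            "payload": construct.feature("eGFP_IPpoI_payload").sequence}


class TestInformativeReads:
    def test_split_read_counts_match_truth(self, mapped, informative):
        """Oracle: reads whose truth interval straddles a junction by >= 20 bp
        on both sides are exactly the reads the extractor should report."""
        event = mapped.event
        L = len(mapped.construct.full_sequence)
        junctions = {"5prime": event.site + 4, "3prime": event.site + 4 + L}
        truth = {"5prime": set(), "3prime": set()}
        for r in mapped.reads.reads:
            hap, chrom, start, _ = r.truth_origin
            if hap != "hapA" or chrom != event.chrom:
                continue
            end = start + len(r.sequence)
            for side, j in junctions.items():
                if start <= j - 20 and end >= j + 20:
                    truth[side].add(r.id)
        for side in ("5prime", "3prime"):
            got = {s.read_id for s in informative.split_reads if s.side == side}
            assert len(truth[side]) >= 5
            assert got == truth[side]

    def test_discordant_pairs_present(self, informative):
        assert len(informative.discordant_pairs) >= 10
        for d in informative.discordant_pairs:
            assert d.construct_record.ref_name != d.genome_record.ref_name

    def test_wild_type_has_no_informative_reads(self, compact_genome, construct,
                                                mapped):
        from insertra.align_core import map_read
        from insertra.synthetic_data import DiploidGenome
        wt = DiploidGenome(haplotypes={"hapA": dict(compact_genome.chromosomes),
                                       "hapB": dict(compact_genome.chromosomes)},
                           event=None, construct=construct, modified_haps=())
        reads = simulate_short_reads(wt, 1500, sub_error=0.0, seed=21)
        recs = []
        for r in reads.reads:
            for rec in map_read(mapped.index, r.sequence, read_id=r.id):
                rec.is_paired = True
                rec.is_read1 = r.id.endswith("/1")
                recs.append(rec)
        info = extract_informative_reads(recs, {construct.name}, 20,
                                         mapped.genome_index,
                                         mapped.construct_index)
        assert info.split_reads == []
        assert info.discordant_pairs == []

    def test_min_clip_above_read_length_empties_split_list(self, mapped):
        info = extract_informative_reads(mapped.records, {mapped.construct.name},
                                         min_clip=200,
                                         genome_index=mapped.genome_index,
                                         construct_index=mapped.construct_index)
        assert info.split_reads == []
        assert len(info.discordant_pairs) >= 10


class TestFlankConsensus:
    def test_error_free_consensus_is_byte_exact(self, mapped, informative):
        event = mapped.event
        chrom_seq = mapped.genome.chromosomes[event.chrom]
        f5 = build_flank_consensus(informative, "5prime")
        f3 = build_flank_consensus(informative, "3prime")
        assert f5 == chrom_seq[event.site + 4 - len(f5):event.site + 4]
        assert f3 == chrom_seq[event.site:event.site + len(f3)]

    def test_noisy_reads_high_identity_consensus(self, mapped):
        """1% substitutions at full depth: consensus >= 99% identical to truth."""
        from insertra.align_core import map_read
        diploid, event = mapped.diploid, mapped.event
        reads = simulate_short_reads(diploid, 6000, sub_error=0.01, seed=31)
        recs = []
        for r in reads.reads:
            recs.extend(map_read(mapped.index, r.sequence, read_id=r.id))
        info = extract_informative_reads(recs, {mapped.construct.name}, 20,
                                         mapped.genome_index,
                                         mapped.construct_index,
                                         len(mapped.construct.full_sequence))
        f5 = build_flank_consensus(info, "5prime")
        truth = mapped.genome.chromosomes[event.chrom][
            event.site + 4 - len(f5):event.site + 4]
        matches = sum(a == b for a, b in zip(f5, truth))
        assert matches / len(truth) >= 0.99

    def test_two_reads_insufficient(self, informative):
        from insertra.junction_evidence import InformativeReadSet
        thin = InformativeReadSet(split_reads=[
            s for s in informative.split_reads
            if s.side == "5prime" and s.anchor_in_construct][:2])
        with pytest.raises(EvidenceError, match="2"):
            build_flank_consensus(thin, "5prime")


class TestDetectTsd:
    def test_planted_insertion_both_flags_true(self, mapped, informative):
        f5 = build_flank_consensus(informative, "5prime")
        f3 = build_flank_consensus(informative, "3prime")
        call = detect_tsd(f5, f3)
        assert call.present_5prime and call.present_3prime

    def test_non_ttaa_flanks_both_false(self):
        call = detect_tsd("ACGTACGTCCGG", "GGCCACGTACGT")
        assert not call.present_5prime and not call.present_3prime

    def test_empty_motif_rejected(self):
        with pytest.raises(ParameterError):
            detect_tsd("ACGTACGT", "ACGTACGT", motif="")


class TestAssembly:
    def test_error_free_tiling_reads_reconstruct_locus(self, mapped):
        from insertra.synthetic_data import Read, ReadSet
        diploid, event, construct = mapped.diploid, mapped.event, mapped.construct
        ci = diploid.construct_interval("hapA")
        hap = diploid.haplotypes["hapA"][event.chrom]
        # deterministic 8 kb reads tiling the insertion ±10 kb every 2 kb
        reads = ReadSet(platform="long", reads=[
            Read(f"tile{i}", hap[p:p + 8_000], "-" * 8_000, None,
                 ("hapA", event.chrom, p, "+"))
            for i, p in enumerate(range(ci[0] - 10_000, ci[1] + 2_100, 2_000))])
        contig = assemble_long_reads(reads, anchors_for(construct))
        assert construct.full_sequence in contig
        i = contig.find(construct.full_sequence)
        assert i >= 5_000  # 5' flank recovered
        assert len(contig) - i - len(construct.full_sequence) >= 5_000
        assert contig in diploid.haplotypes["hapA"][event.chrom]

    def test_single_read_returned_as_is(self, mapped):
        diploid, event, construct = mapped.diploid, mapped.event, mapped.construct
        ci = diploid.construct_interval("hapA")
        reads = simulate_long_reads(diploid, 0, error_rate=0.0, seed=43,
                                    anchor_interval=("hapA", event.chrom, *ci),
                                    n_anchored=1)
        contig = assemble_long_reads(reads, anchors_for(construct))
        seq = reads.reads[0].sequence
        assert contig in (seq, revcomp(seq))

    def test_noisy_assembly_high_identity(self, mapped):
        """8% mixed-error reads at ~10x local depth: >= 98% identity over the
        construct span (seeded)."""
        diploid, event, construct = mapped.diploid, mapped.event, mapped.construct
        ci = diploid.construct_interval("hapA")
        reads = simulate_long_reads(diploid, 0, error_rate=0.08, seed=47,
                                    anchor_interval=("hapA", event.chrom,
                                                     ci[0] - 2_000, ci[1] + 2_000),
                                    n_anchored=30)
        contig = assemble_long_reads(reads, anchors_for(construct))
        res = edlib.align(construct.full_sequence, contig, mode="HW")
        identity = 1 - res["editDistance"] / len(construct.full_sequence)
        assert identity >= 0.98

    def test_contig_never_longer_than_input(self, mapped):
        diploid, event, construct = mapped.diploid, mapped.event, mapped.construct
        ci = diploid.construct_interval("hapA")
        reads = simulate_long_reads(diploid, 0, error_rate=0.05, seed=49,
                                    anchor_interval=("hapA", event.chrom,
                                                     ci[0], ci[1]),
                                    n_anchored=8)
        contig = assemble_long_reads(reads, anchors_for(construct))
        assert len(contig) <= sum(len(r.sequence) for r in reads.reads)

    def test_no_anchored_reads_raises(self, mapped):
        reads = simulate_long_reads(mapped.diploid, 3, error_rate=0.0, seed=51)
        # background reads from a 180 kb diploid rarely touch the construct;
        # pick anchors absent from all of them
        with pytest.raises(EvidenceError):
            assemble_long_reads(reads, {"x": "ACGT" * 200})
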