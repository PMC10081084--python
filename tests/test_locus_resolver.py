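"""Resolver tests: candidate ranking and its tie-breaks, long-read
integration contracts (resolution, insufficient contig, contradictory
islands), tally arithmetic, and the end-to-end pipeline."""

import json

import pytest

from insertra.align_core import local_search
from insertra.errors import ConfigError, EvidenceError, ParameterError
from insertra.insilico_assays import combined_flank_query, recover_flanks
from insertra.locus_resolver import (ambiguity_resolution_scenario,
                                     integrate_long_read_evidence, load_config,
                                     rank_candidate_loci, run_pipeline,
                                     summarize_signal_counts)


@pytest.fixture(scope="module")
def flank_hits(mapped):
    diploid, event = mapped.diploid, mapped.event
    f5, f3 = recover_flanks(diploid.haplotypes["hapA"][event.chrom],
                            mapped.construct)
    query = combined_flank_query(f5, f3)
    hits = local_search(mapped.genome_index, query, min_score=500)
    return hits, len(f5) - 4


class TestRankCandidates:
    def test_every_repeat_copy_becomes_candidate(self, mapped, flank_hits):
        hits, joff = flank_hits
        cands = rank_candidate_loci(hits, mapped.genome, junction_offset=joff)
        n_copies = sum(1 for a in mapped.genome.repeat_annotations
                       if not a.family_id.endswith("decoy"))
        assert len(cands) == n_copies
        assert [c.rank for c in cands] == list(range(1, n_copies + 1))
        assert all(c.has_ttaa for c in cands)

    def test_strict_identity_keeps_only_true_locus(self, mapped, flank_hits):
        hits, joff = flank_hits
        cands = rank_candidate_loci(hits, mapped.genome, t_identity=1.0,
                                    junction_offset=joff)
        assert len(cands) == 1
        assert cands[0].start <= mapped.event.site < cands[0].end

    def test_ttaa_requirement_drops_mutated_copies(self, mapped, flank_hits):
        """Mutate the junction TTAA out of all but 3 copies: exactly 3 survive."""
        import copy as copymod
        hits, joff = flank_hits
        genome = copymod.deepcopy(mapped.genome)
        copies = [a for a in genome.repeat_annotations
                  if not a.family_id.endswith("decoy")]
        for a in copies[3:]:
            seq = genome.chromosomes[a.chrom]
            p = a.start + 375
            genome.chromosomes[a.chrom] = seq[:p] + "GGCC" + seq[p + 4:]
        cands = rank_candidate_loci(hits, genome, junction_offset=joff)
        assert len(cands) == 3

    def test_ranking_invariant_under_input_permutation(self, mapped, flank_hits):
        hits, joff = flank_hits
        a = rank_candidate_loci(hits, mapped.genome, junction_offset=joff)
        b = rank_candidate_loci(list(reversed(hits)), mapped.genome,
                                junction_offset=joff)
        assert [(c.chrom, c.start, c.rank) for c in a] == \
               [(c.chrom, c.start, c.rank) for c in b]

    def test_empty_input_empty_output(self, mapped):
        assert rank_candidate_loci([], mapped.genome) == []


@pytest.fixture(scope="module")
def setup(mapped, flank_hits):
    hits, joff = flank_hits
    cands = rank_candidate_loci(hits, mapped.genome, junction_offset=joff)
    diploid, event = mapped.diploid, mapped.event
    ci = diploid.construct_interval("hapA")
    hap = diploid.haplotypes["hapA"][event.chrom]
    contig = hap[ci[0] - 8_000:ci[1] + 8_000]  # ideal error-free contig
    return cands, contig


class TestIntegrateLongReads:
    def test_true_locus_resolved(self, mapped, setup):
        cands, contig = setup
        res = integrate_long_read_evidence(
            cands, contig, mapped.genome, linkage_window=2_000,
            construct_sequence=mapped.construct.full_sequence,
            genome_index=mapped.genome_index)
        assert not res["ambiguous"]
        loc = res["resolved_locus"]
        assert loc.chrom == mapped.event.chrom
        assert loc.start <= mapped.event.site < loc.end
        assert loc.evidence_tier == "long_read_resolved"

    def test_short_contig_stays_ambiguous(self, mapped, setup):
        cands, _ = setup
        for c in cands:
            c.evidence_tier = "flank_only"
        diploid, event = mapped.diploid, mapped.event
        ci = diploid.construct_interval("hapA")
        hap = diploid.haplotypes["hapA"][event.chrom]
        stub = hap[ci[0] - 300:ci[1] + 300]  # never reaches unique sequence
        res = integrate_long_read_evidence(
            cands, stub, mapped.genome, linkage_window=2_000,
            construct_sequence=mapped.construct.full_sequence,
            genome_index=mapped.genome_index)
        assert res["ambiguous"]
        assert res["resolved_locus"] is None

    def test_contradictory_contig_flags_both(self, mapped, setup):
        """A contig whose two flanks carry unique islands belonging to two
        different candidates resolves both: the contradiction is reported
        (ambiguous stays true, both flagged), never silently broken."""
        import copy as copymod
        cands, contig = setup
        cands = copymod.deepcopy(cands)
        for c in cands:
            c.evidence_tier = "flank_only"
        event = mapped.event
        other = next(c for c in cands if not (c.start <= event.site < c.end))
        # graft candidate B's own upstream flank onto the contig's 3' end
        graft = mapped.genome.chromosomes[other.chrom][
            other.start - 1_500:other.start - 100]
        res = integrate_long_read_evidence(
            cands, contig + graft, mapped.genome, linkage_window=2_000,
            construct_sequence=mapped.construct.full_sequence,
            genome_index=mapped.genome_index)
        assert res["ambiguous"]
        assert res["resolved_locus"] is None
        assert len(res["resolved_candidates"]) >= 2

    def test_contig_without_anchor_rejected(self, mapped, setup):
        cands, _ = setup
        with pytest.raises(EvidenceError):
            integrate_long_read_evidence(
                cands, "ACGT" * 500, mapped.genome,
                construct_sequence=mapped.construct.full_sequence,
                genome_index=mapped.genome_index)


class TestSummarizeSignalCounts:
    @pytest.mark.parametrize("positive,total,expected", [
        (59, 63, 94), (38, 54, 70), (0, 10, 0), (1, 2, 50), (1, 200, 1),
    ])
    def test_percentages(self, positive, total, expected):
        assert summarize_signal_counts([("x", positive, total)]) == [("x", expected)]

    def test_half_rounds_away_from_zero(self):
        assert summarize_signal_counts([("x", 1, 8)]) == [("x", 13)]  # 12.5 -> 13

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            summarize_signal_counts([("x", 0, 0)])


class TestScenario:
    def test_repeat_ambiguity_resolved_by_long_reads(self):
        """Core scenario at compact scale: flank-only evidence is ambiguous
        across every repeat copy; long reads resolve the planted locus."""
        r = ambiguity_resolution_scenario(seed=3, scale="compact")
        assert r["n_candidates"] >= 6
        assert r["flank_only_ambiguous"]
        assert r["resolved_correct"]


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            load_config({"genome": {"scale": "compact"}, "typo": 1})

    def test_nested_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            load_config({"reads": {"short": {"coverage": 30, "oops": 1}}})

    def test_full_scale_widens_linkage_window(self):
        assert load_config({"genome": {"scale": "full"}}
                           )["analysis"]["linkage_window"] == 25_000


@pytest.fixture(scope="module")
def pipeline_out(tmp_path_factory):
    out = tmp_path_factory.mktemp("e2e")
    report = run_pipeline(out_dir=out, seed=5, log=lambda *_: None)
    return out, report


class TestPipeline:
    def test_resolved_locus_matches_truth_json(self, pipeline_out):
        out, report = pipeline_out
        truth = json.loads((out / "truth.json").read_text())
        loc = report.resolved_locus
        assert loc is not None
        assert loc["chrom"] == truth["chrom"]
        assert loc["start"] <= truth["site"] < loc["end"]
        assert not report.ambiguous

    def test_copy_number_and_tsd_in_report(self, pipeline_out):
        _, report = pipeline_out
        feats = report.copy_number_verdict["features"]
        assert feats["DsRed_marker"]["consistent"]
        # single-seed 3n estimates carry fragment-sampling noise; the tight
        # multi-seed recovery bound lives in the acceptance suite
        assert 2.2 <= feats["beta2_promoter"]["cn"] <= 3.8
        assert report.tsd_call["present_5prime"] and report.tsd_call["present_3prime"]
        assert report.assay_summaries["southern_DraI"]["positive_fragments"]

    def test_expected_artifacts_written(self, pipeline_out):
        out, _ = pipeline_out
        for name in ("genome.fasta", "construct.fasta", "truth.bed", "truth.json",
                     "reads_R1.fastq", "reads_R2.fastq", "reads_long.fastq",
                     "alignments.sam", "junctions.tsv", "copy_number.tsv",
                     "contig.fasta", "dotplot_contig_vs_reference.tsv",
                     "report.json"):
            assert (out / name).exists(), name

    def test_wild_type_reports_no_evidence(self, tmp_path):
        report = run_pipeline(
            config={"insertion": {"site": None, "zygosity": "none"},
                    "reads": {"short": {"coverage": 8}, "long": {"n_background": 5}}},
            out_dir=tmp_path, seed=6, log=lambda *_: None)
        assert report.candidates == []
        assert report.resolved_locus is None
        assert any("no insertion evidence" in n for n in report.notes)
        assert report.assay_summaries["southern_DraI"]["positive_fragments"] == []

    def test_rerun_identical_report(self, pipeline_out, tmp_path):
        out, _ = pipeline_out
        rerun = run_pipeline(out_dir=tmp_path, seed=5, log=lambda *_: None)
        a = json.loads((out / "report.json").read_text())
        b = json.loads((tmp_path / "report.json").read_text())
        assert a == b
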