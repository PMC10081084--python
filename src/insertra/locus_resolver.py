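"""Candidate-locus ranking, long-read resolution, and pipeline orchestration.

The core analytic story: a flank query recovered from the junctions of an
insertion in a repeat cluster matches every family copy at high identity over
most of its length, so flank evidence alone leaves the locus ambiguous. A
long-read contig that reaches past the repetitive context into unique
sequence resolves it — a contig segment of ≥ ``unique_flank_min`` bp that
maps uniquely within ``linkage_window`` of exactly one candidate promotes
that candidate to ``long_read_resolved``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import edlib

from .align_core import KmerIndex, SearchHit, local_search
from .errors import ConfigError, EvidenceError, ParameterError
from .synthetic_data import HostGenome, TSD_MOTIF


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    identity: float
    aln_length: int
    has_ttaa: bool
    score: int = 0
    evidence_tier: str = "flank_only"  # or 'long_read_resolved'
    rank: int = 0
    resolving_distance: int | None = None  # junction↔unique-segment distance (bp)
    flank_discordant: bool = False

    def interval_distance(self, start: int, end: int) -> int:
        if end <= self.start:
            return self.start - end
        if start >= self.end:
            return start - self.end
        return 0


@dataclass
class ResolutionReport:
    schema_version: int = 1
    seed: int | None = None
    candidates: list = field(default_factory=list)
    ambiguous: bool = True
    resolved_locus: dict | None = None
    copy_number_verdict: dict | None = None
    tsd_call: dict | None = None
    assay_summaries: dict | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "candidates": self.candidates,
            "ambiguous": self.ambiguous,
            "resolved_locus": self.resolved_locus,
            "copy_number_verdict": self.copy_number_verdict,
            "tsd_call": self.tsd_call,
            "assay_summaries": self.assay_summaries,
            "notes": self.notes,
        }


def rank_candidate_loci(hits: list[SearchHit], genome: HostGenome,
                        t_identity: float = 0.90, t_length: int = 700,
                        require_ttaa: bool = True,
                        junction_offset: int | None = None,
                        motif: str = TSD_MOTIF, motif_tol: int = 4
                        ) -> list[CandidateLocus]:
    """Filter and rank flank-query hits into candidate insertion loci.

    A hit passes when identity ≥ ``t_identity`` and alignment length ≥
    ``t_length``. ``has_ttaa`` is true when the motif occurs within
    ``motif_tol`` bp of the junction-proximal position of the hit —
    ``junction_offset`` is the motif's start in query coordinates (for a
    combined 5'+3' flank query, the length of the 5' flank minus the motif
    length). Candidates are sorted by score descending, ties broken by
    (chrom, start); ranks are 1-based and contiguous.
    """
    out: list[CandidateLocus] = []
    for h in hits:
        if h.identity < t_identity or h.aln_length < t_length:
            continue
        has = _has_motif_at_junction(h, genome, junction_offset, motif, motif_tol)
        if require_ttaa and not has:
            continue
        out.append(CandidateLocus(chrom=h.ref_name, start=h.ref_start, end=h.ref_end,
                                  identity=h.identity, aln_length=h.aln_length,
                                  has_ttaa=has, score=h.score))
    out.sort(key=lambda c: (-c.score, c.chrom, c.start))
    for i, c in enumerate(out, 1):
        c.rank = i
    return out


def _has_motif_at_junction(hit: SearchHit, genome: HostGenome,
                           junction_offset: int | None, motif: str, tol: int) -> bool:
    seq = genome.chromosomes.get(hit.ref_name)
    if seq is None:
        return False

    def window_has(center: int) -> bool:
        lo = max(center - tol, 0)
        hi = min(center + len(motif) + tol, len(seq))
        return motif in seq[lo:hi]

    if junction_offset is None:
        return window_has(hit.ref_start) or window_has(hit.ref_end - len(motif))
    if hit.strand == "+":
        center = hit.ref_start + (junction_offset - hit.q_start)
    else:
        center = hit.ref_end - (junction_offset - hit.q_start) - len(motif)
    return window_has(center)


def integrate_long_read_evidence(candidates: list[CandidateLocus], contig: str,
                                 genome: HostGenome, unique_flank_min: int = 500,
                                 linkage_window: int = 25_000,
                                 construct_sequence: str | None = None,
                                 genome_index: KmerIndex | None = None,
                                 min_hit_identity: float = 0.90) -> dict:
    """Resolve flank ambiguity with a transgene-bearing contig.

    The construct span inside the contig is located by edit-distance
    alignment; the contig flanks beyond it are chopped into windows of
    ``unique_flank_min`` bp which are searched against the reference. A
    window that maps uniquely (exactly one hit at ≥ ``min_hit_identity``
    covering ≥80% of the window) and lies within ``linkage_window`` of
    exactly one candidate resolves it. Returns a dict with keys
    ``resolved_locus`` (CandidateLocus or None), ``ambiguous``,
    ``resolved_candidates`` (all candidates any window linked to) and
    ``novel_locus`` (set when unique segments adjoin the junction but no
    flank candidate — reported, never silently substituted).
    """
    if construct_sequence is None:
        raise ParameterError("construct_sequence is required to locate the anchor")
    res = edlib.align(construct_sequence, contig, mode="HW", task="locations")
    max_d = int(0.2 * len(construct_sequence))
    if res["editDistance"] < 0 or res["editDistance"] > max_d or not res["locations"]:
        raise EvidenceError("contig does not contain the construct anchor")
    c_start = res["locations"][0][0] or 0
    c_end = res["locations"][0][1] + 1
    index = genome_index or KmerIndex(genome.chromosomes)

    windows: list[tuple[str, int]] = []  # (window sequence, distance to junction)
    step = max(unique_flank_min // 2, 100)
    flank5 = contig[:c_start]
    for end in range(len(flank5), unique_flank_min - 1, -step):
        windows.append((flank5[end - unique_flank_min:end], len(flank5) - end))
    flank3 = contig[c_end:]
    for start in range(0, len(flank3) - unique_flank_min + 1, step):
        windows.append((flank3[start:start + unique_flank_min], start))

    resolved: dict[int, int] = {}  # candidate index -> best distance
    adjacent_unique: list[tuple[str, int, int, int]] = []
    for wseq, dist in windows:
        hits = local_search(index, wseq, min_score=int(0.8 * unique_flank_min))
        strong = [h for h in hits if h.identity >= min_hit_identity
                  and h.aln_length >= 0.8 * unique_flank_min]
        if len(strong) != 1:
            continue
        h = strong[0]
        linked = False
        for i, cand in enumerate(candidates):
            if cand.chrom != h.ref_name:
                continue
            gap = cand.interval_distance(h.ref_start, h.ref_end)
            if gap <= linkage_window:
                linked = True
                if i not in resolved or dist < resolved[i]:
                    resolved[i] = dist
        if not linked:
            adjacent_unique.append((h.ref_name, h.ref_start, h.ref_end, dist))

    out: dict = {"resolved_candidates": [], "novel_locus": None}
    for i, dist in sorted(resolved.items()):
        cand = candidates[i]
        cand.evidence_tier = "long_read_resolved"
        cand.resolving_distance = dist
        out["resolved_candidates"].append(cand)
    if len(resolved) == 1:
        out["resolved_locus"] = out["resolved_candidates"][0]
        out["ambiguous"] = False
    else:
        out["resolved_locus"] = None
        out["ambiguous"] = True
        if not resolved and adjacent_unique:
            ref, s, e, dist = min(adjacent_unique, key=lambda x: x[3])
            out["novel_locus"] = CandidateLocus(
                chrom=ref, start=s, end=e, identity=1.0, aln_length=e - s,
                has_ttaa=False, evidence_tier="long_read_resolved",
                resolving_distance=dist, flank_discordant=True)
    return out


def summarize_signal_counts(tallies: list[tuple[str, int, int]]
                            ) -> list[tuple[str, int]]:
    """Percentage of positive counts per label, rounded half away from zero."""
    out = []
    for label, positive, total in tallies:
        if total <= 0:
            raise ParameterError(f"total must be positive for {label!r}")
        if not 0 <= positive <= total:
            raise ParameterError(f"positive outside [0, total] for {label!r}")
        out.append((label, int(math.floor(100.0 * positive / total + 0.5))))
    return out


def ambiguity_resolution_scenario(seed: int, scale: str = "full",
                                  n_background_reads: int = 300,
                                  n_anchored_reads: int = 28,
                                  long_read_error: float = 0.08) -> dict:
    """One replicate of the core study scenario.

    A heterozygous insertion is planted inside one copy of the repeat family;
    the inverse-PCR flank query is ranked against the clean reference
    (flank-only evidence), then noisy long reads are assembled and integrated.
    Returns the candidate count, whether flank-only evidence is ambiguous,
    and whether long reads resolve the planted locus.
    """
    from . import insilico_assays as assays
    from . import junction_evidence as je
    from . import synthetic_data as sd

    genome = sd.build_host_genome(sd.default_genome_spec(scale, seed=seed))
    construct = sd.build_construct(sd.ConstructSpec(seed=seed), genome)
    chrom, site = genome.meta["true_insertion"]
    diploid, event = sd.insert_transgene(genome, construct, chrom, site, "het")

    f5, f3 = assays.recover_flanks(diploid.haplotypes["hapA"][chrom], construct)
    query = assays.combined_flank_query(f5, f3)
    genome_index = KmerIndex(genome.chromosomes)
    hits = local_search(genome_index, query, min_score=560)
    candidates = rank_candidate_loci(hits, genome, junction_offset=len(f5) - 4)
    flank_only_ambiguous = len(candidates) >= 2

    ci = diploid.construct_interval("hapA")
    reads = sd.simulate_long_reads(
        diploid, n_background_reads, error_rate=long_read_error, seed=seed,
        anchor_interval=("hapA", chrom, max(0, ci[0] - 2000), ci[1] + 2000),
        n_anchored=n_anchored_reads)
    anchors = {"marker": construct.marker.sequence,
               "payload": construct.feature("eGFP_IPpoI_payload").sequence}
    contig = je.assemble_long_reads(reads, anchors)
    linkage = 25_000 if scale == "full" else 2_000
    res = integrate_long_read_evidence(candidates, contig, genome,
                                       linkage_window=linkage,
                                       construct_sequence=construct.full_sequence,
                                       genome_index=genome_index)
    loc = res["resolved_locus"]
    resolved_correct = bool(loc and loc.chrom == chrom
                            and loc.start <= site < loc.end)
    long_read_depth = sum(len(r.sequence) for r in reads.reads) / sum(
        len(s) for _, _, s in diploid.sequences())
    return {
        "n_candidates": len(candidates),
        "flank_only_ambiguous": flank_only_ambiguous,
        "resolved": loc is not None,
        "resolved_correct": resolved_correct,
        "resolving_distance": loc.resolving_distance if loc else None,
        "contig_length": len(contig),
        "long_read_depth": long_read_depth,
        "truth": {"chrom": chrom, "site": site},
    }


# ---------------------------------------------------------------------------
# pipeline configuration


_CONFIG_SCHEMA: dict = {
    "seed": int,
    "out": str,
    "genome": {"scale": str},
    "construct": {"payload_len": int, "marker_len": int, "itr_len": int},
    "insertion": {"site": (str, int, type(None)), "chrom": (str, type(None)),
                  "zygosity": str},
    "reads": {
        "short": {"coverage": (int, float), "insert_mean": int, "insert_sd": int,
                  "read_len": int, "sub_error": (int, float)},
        "long": {"n_background": int, "n_anchored": int, "length_mean": int,
                 "length_sd": int, "error_rate": (int, float)},
    },
    "analysis": {"min_clip": int, "t_identity": (int, float), "t_length": int,
                 "require_ttaa": bool, "unique_flank_min": int,
                 "linkage_window": int, "cn_tolerance": (int, float),
                 "fold_threshold": (int, float), "secondary_frac": (int, float),
                 "n_reference_loci": int},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {"scale": "compact"},
    "construct": {},
    "insertion": {"site": "auto", "zygosity": "het"},
    "reads": {
        "short": {"coverage": 30, "insert_mean": 350, "insert_sd": 50,
                  "read_len": 150, "sub_error": 0.005},
        "long": {"n_background": 40, "n_anchored": 28, "length_mean": 8000,
                 "length_sd": 1500, "error_rate": 0.08},
    },
    "analysis": {"min_clip": 20, "t_identity": 0.90, "t_length": 700,
                 "require_ttaa": True, "unique_flank_min": 500,
                 "linkage_window": 2000, "cn_tolerance": 0.5,
                 "fold_threshold": 2.0, "secondary_frac": 0.7,
                 "n_reference_loci": 15},
}


def _validate_config(cfg: dict, schema: dict = _CONFIG_SCHEMA, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {path + key!r}")
        want = schema[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {path + key!r} must be a mapping")
            _validate_config(val, want, path + key + ".")
        elif not isinstance(val, want):
            raise ConfigError(f"config key {path + key!r} has wrong type")


def load_config(source=None) -> dict:
    """Merge a YAML file or dict over the defaults; unknown keys are errors."""
    import copy
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        import yaml
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = source
    _validate_config(user)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
    merge(cfg, user)
    # the full-scale genome spaces repeat copies ≥80 kb apart; the wider
    # linkage window applies unless the user pinned one explicitly
    user_window = isinstance(user.get("analysis"), dict) and \
        "linkage_window" in user["analysis"]
    if cfg["genome"]["scale"] == "full" and not user_window:
        cfg["analysis"]["linkage_window"] = 25_000
    return cfg


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config=None, out_dir=None, seed: int | None = None,
                 log=print, stop_after: str | None = None) -> ResolutionReport:
    """Run simulate → map → junctions → copy number → assays → resolve.

    ``config`` may be a YAML path, a dict of overrides, or None for the
    shipped defaults. Artifacts (FASTA/FASTQ/SAM/BED/TSV/JSON) are written
    under ``out_dir`` when given; ``stop_after`` ends the run after a named
    stage. Returns the ResolutionReport; determinism is guaranteed by the
    single config seed.
    """
    from collections import defaultdict

    from . import copy_number as cn
    from . import insilico_assays as assays
    from . import junction_evidence as je
    from . import synthetic_data as sd
    from .align_core import map_read, write_sam

    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    s0 = cfg["seed"]
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report = ResolutionReport(seed=s0)

    def _finish():
        if out:
            with open(out / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
                fh.write("\n")
        return report

    # -- simulate ----------------------------------------------------------
    log(f"[simulate] genome scale={cfg['genome']['scale']} seed={s0}")
    gspec = sd.default_genome_spec(cfg["genome"]["scale"], seed=s0)
    genome = sd.build_host_genome(gspec)
    cspec = sd.ConstructSpec(seed=s0, **{k: v for k, v in cfg["construct"].items()})
    construct = sd.build_construct(cspec, genome)
    ins_cfg = cfg["insertion"]
    wild_type = ins_cfg["zygosity"] == "none" or ins_cfg["site"] is None
    if wild_type:
        diploid = sd.DiploidGenome(
            haplotypes={"hapA": dict(genome.chromosomes),
                        "hapB": dict(genome.chromosomes)},
            event=None, construct=construct, modified_haps=())
        event = None
    else:
        if ins_cfg["site"] == "auto":
            chrom, site = genome.meta["true_insertion"]
        else:
            chrom, site = ins_cfg["chrom"], int(ins_cfg["site"])
        diploid, event = sd.insert_transgene(genome, construct, chrom, site,
                                             ins_cfg["zygosity"])
    rcfg = cfg["reads"]["short"]
    l_dip = sum(len(sq) for _, _, sq in diploid.sequences())
    n_pairs = max(1, int(rcfg["coverage"] * l_dip / (2 * 2 * rcfg["read_len"])))
    short = sd.simulate_short_reads(diploid, n_pairs, rcfg["insert_mean"],
                                    rcfg["insert_sd"], rcfg["read_len"],
                                    rcfg["sub_error"], seed=s0)
    lcfg = cfg["reads"]["long"]
    anchor = None
    n_anch = 0
    if not wild_type:
        ci = diploid.construct_interval("hapA")
        anchor = ("hapA", event.chrom, max(0, ci[0] - 2000), ci[1] + 2000)
        n_anch = lcfg["n_anchored"]
    long_reads = sd.simulate_long_reads(diploid, lcfg["n_background"],
                                        lcfg["length_mean"], lcfg["length_sd"],
                                        lcfg["error_rate"], seed=s0,
                                        anchor_interval=anchor, n_anchored=n_anch)
    if out:
        genome.write_fasta(out / "genome.fasta")
        sd.write_fasta(out / "construct.fasta", {construct.name: construct.full_sequence})
        from .seqs import write_bed, write_json
        write_bed(out / "truth.bed", genome.truth_intervals())
        write_json(out / "truth.json",
                   event.to_dict() if event else {"insertion": None})
        short.write_fastq(out / "reads_R1.fastq", out / "reads_R2.fastq")
        long_reads.write_fastq(out / "reads_long.fastq")
    if stop_after == "simulate":
        return _finish()

    # -- map ---------------------------------------------------------------
    log(f"[map] {len(short.reads)} short reads")
    refs = {**genome.chromosomes, construct.name: construct.full_sequence}
    index = KmerIndex(refs)
    genome_index = KmerIndex(genome.chromosomes)
    construct_index = KmerIndex({construct.name: construct.full_sequence})
    acfg = cfg["analysis"]
    by_read: dict[str, list] = defaultdict(list)
    for r in short.reads:
        recs = map_read(index, r.sequence, read_id=r.id,
                        secondary_frac=acfg["secondary_frac"])
        for rec in recs:
            rec.is_paired = True
            rec.is_read1 = r.id.endswith("/1")
        by_read[r.id] = recs
    donors = []
    for name in ("beta2_promoter", "beta2_terminator"):
        ci_ = construct.feature_interval(name)
        gch, gs, ge = genome.endogenous_features[name]
        donors.append((name, construct.name, ci_, gch, (gs, ge)))
    cn.rescue_construct_donor_ties(by_read, donors)
    records = [rec for recs in by_read.values() for rec in recs]
    if out:
        write_sam(out / "alignments.sam", records, refs)
    if stop_after == "map":
        return _finish()

    # -- junctions ---------------------------------------------------------
    log("[junctions] extracting informative reads")
    info = je.extract_informative_reads(records, {construct.name}, acfg["min_clip"],
                                        genome_index, construct_index,
                                        len(construct.full_sequence))
    tsd_call = None
    try:
        flank5 = je.build_flank_consensus(info, "5prime")
        flank3 = je.build_flank_consensus(info, "3prime")
        tsd_call = je.detect_tsd(flank5, flank3)
        report.tsd_call = {"motif": tsd_call.motif,
                           "present_5prime": tsd_call.present_5prime,
                           "present_3prime": tsd_call.present_3prime,
                           "flank5_len": len(flank5), "flank3_len": len(flank3)}
    except EvidenceError as exc:
        report.tsd_call = None
        report.notes.append(f"no junction evidence: {exc}")
    if out:
        import pandas as pd
        pd.DataFrame([{
            "read_id": s.read_id, "kind": "split", "side": s.side,
            "anchor_ref": s.anchor.ref_name, "anchor_pos": s.anchor.ref_start,
            "clip_len": len(s.clipped_seq)} for s in info.split_reads] + [{
            "read_id": d.read_id, "kind": "discordant", "side": d.side,
            "anchor_ref": d.construct_record.ref_name,
            "anchor_pos": d.construct_record.ref_start,
            "clip_len": 0} for d in info.discordant_pairs]
        ).to_csv(out / "junctions.tsv", sep="\t", index=False)
    if stop_after == "junctions":
        return _finish()

    # -- copy number -------------------------------------------------------
    log("[copynumber] feature depths")
    features = []
    for fname in ("DsRed_marker", "eGFP_IPpoI_payload"):
        a, b = construct.feature_interval(fname)
        features.append(cn.FeatureCoverage(fname, construct.name, a, b, "n"))
    trim = rcfg["read_len"]
    for name in ("beta2_promoter", "beta2_terminator"):
        gch, gs, ge = genome.endogenous_features[name]
        if ge - gs > 2 * trim + 40:  # measure dosage over the feature interior
            gs, ge = gs + trim, ge - trim
        features.append(cn.FeatureCoverage(name, gch, gs, ge, "3n"))
    features += cn.select_reference_loci(genome, acfg["n_reference_loci"],
                                         seed=s0)
    for f in features:
        f.mean_depth = cn.feature_depth(records, (f.ref_name, (f.start, f.end)))
    cn.estimate_copy_number(features, tolerance=acfg["cn_tolerance"])
    two_n_depths = sorted(f.mean_depth for f in features if f.expected_class == "2n")
    baseline = two_n_depths[len(two_n_depths) // 2]
    flagged = []
    if event is not None:
        prof = cn.depth_profile(records, event.chrom,
                                max(0, event.site - 2500), event.site + 2500)
        flagged = cn.flag_repetitive_flanks(prof, baseline, acfg["fold_threshold"])
    report.copy_number_verdict = {
        "reference_2n_depth": round(baseline, 3),
        "features": {f.feature_name: {
            "class": f.expected_class, "cn": round(f.cn_estimate, 3),
            "consistent": f.consistent} for f in features
            if f.expected_class in ("n", "3n")},
        "all_consistent": all(f.consistent for f in features),
        "repeat_inflated_flanks": [list(x) for x in flagged],
    }
    if out:
        cn.coverage_report(features).to_csv(out / "copy_number.tsv", sep="\t",
                                            index=False)
    if stop_after == "copynumber":
        return _finish()

    # -- in-silico assays --------------------------------------------------
    log("[assays] inverse PCR + Southern digest")
    flank_query = None
    junction_offset = None
    probe = construct.feature("eGFP_IPpoI_payload").sequence[:600]
    assay_summary: dict = {}
    if event is not None:
        hap_seq = diploid.haplotypes["hapA"][event.chrom]
        from .errors import InsertraError
        try:
            f5, f3 = assays.recover_flanks(hap_seq, construct)
            flank_query = assays.combined_flank_query(f5, f3)
            junction_offset = len(f5) - 4
            assay_summary["inverse_pcr"] = {"flank5_len": len(f5),
                                            "flank3_len": len(f3)}
        except InsertraError as exc:  # assay failure is reportable, not fatal
            assay_summary["inverse_pcr"] = {"error": str(exc)}
    for enz_name in ("DraI", "ScaI"):
        sizes = []
        for hap in ("hapA", "hapB"):
            for chrom, seq in diploid.haplotypes[hap].items():
                pred = assays.digest(seq, [assays.ENZYMES[enz_name]],
                                     source_ref=f"{hap}:{chrom}")
                sizes.extend(assays.southern_probe_fragments(pred, probe))
        assay_summary[f"southern_{enz_name}"] = {"positive_fragments": sorted(sizes)}
    report.assay_summaries = assay_summary
    if stop_after == "assays":
        return _finish()

    # -- resolve -----------------------------------------------------------
    log("[resolve] ranking candidates and integrating long reads")
    candidates: list[CandidateLocus] = []
    if flank_query is not None:
        hits = local_search(genome_index, flank_query,
                            min_score=int(0.8 * acfg["t_length"]))
        candidates = rank_candidate_loci(hits, genome, acfg["t_identity"],
                                         acfg["t_length"], acfg["require_ttaa"],
                                         junction_offset=junction_offset)
    report.ambiguous = len([c for c in candidates if c.has_ttaa]) >= 2
    resolution = None
    if candidates and long_reads.reads:
        anchors = {"marker": construct.marker.sequence,
                   "payload": construct.feature("eGFP_IPpoI_payload").sequence}
        try:
            contig = je.assemble_long_reads(long_reads, anchors)
            resolution = integrate_long_read_evidence(
                candidates, contig, genome, acfg["unique_flank_min"],
                acfg["linkage_window"], construct.full_sequence, genome_index)
            if out:
                sd.write_fasta(out / "contig.fasta", {"contig": contig})
                loc = resolution.get("resolved_locus")
                if loc is not None:
                    ref = genome.chromosomes[loc.chrom]
                    lo = max(0, loc.start - 15_000)
                    window = ref[lo:loc.end + 15_000]
                    assays.dotplot_to_tsv(
                        assays.dotplot_matrix(contig, window, k=15),
                        out / "dotplot_contig_vs_reference.tsv")
        except EvidenceError as exc:
            report.notes.append(f"long-read resolution unavailable: {exc}")
    report.candidates = [asdict(c) for c in candidates]
    if resolution is not None:
        report.ambiguous = resolution["ambiguous"]
        report.resolved_locus = (asdict(resolution["resolved_locus"])
                                 if resolution["resolved_locus"] else None)
        if resolution.get("novel_locus"):
            report.notes.append("unique long-read segment maps outside all flank "
                                "candidates (flank-discordant novel locus)")
            report.resolved_locus = None
    if not candidates:
        report.ambiguous = False
        report.notes.append("no insertion evidence" if wild_type
                            else "no candidates passed the flank thresholds")
    return _finish()
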