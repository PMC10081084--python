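"""Coverage-class copy-number estimation.

A heterozygous transgenic diploid carries construct-unique features (marker,
payload) in one copy (class n), ordinary autosomal loci in two (2n), and
features shared between the construct and an endogenous gene — promoter and
terminator — in three (3n: one transgenic plus two endogenous alleles). Mean
read depth over each feature, normalized to the median depth of a panel of
2n single-copy loci, estimates the copy number:

    cn = 2 · mean_depth / median(2n depths)

Design choices (the underlying wet-lab analysis left them open):

* the 2n normalizer is the *median* of the panel, robust to one locus
  accidentally overlapping unannotated repeats;
* feature depth counts only uniquely placed alignments (mapq > 0), while the
  repeat-inflation flagging below deliberately counts everything including
  multi-mapped placements — separating copy-number signal from multi-mapping
  inflation;
* because the construct's promoter/terminator are sequence-identical to their
  endogenous donors, reads interior to them always tie between exactly those
  two placements. Such two-way construct↔donor ties carry no positional
  ambiguity for dosage purposes, so :func:`rescue_construct_donor_ties`
  reassigns them to the endogenous locus (where the 3n signal is measured)
  before depth is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .align_core import AlignmentRecord
from .errors import BoundsError, DataError, LayoutError, ParameterError
from .seqs import child_rng, count_occurrences
from .synthetic_data import HostGenome

CLASS_VALUES = {"n": 1.0, "2n": 2.0, "3n": 3.0}


@dataclass
class FeatureCoverage:
    feature_name: str
    ref_name: str
    start: int
    end: int
    expected_class: str  # 'n' | '2n' | '3n' | 'unknown'
    mean_depth: float = 0.0
    cn_estimate: float | None = None
    consistent: bool | None = None


@dataclass
class DepthProfile:
    ref_name: str
    start: int
    depth: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.depth)


def _add_coverage(depth: np.ndarray, rec: AlignmentRecord, start: int, end: int) -> None:
    pos = rec.ref_start
    for op, n in rec.cigar:
        if op in "MD":  # reference-consuming
            a = max(pos, start)
            b = min(pos + n, end)
            if a < b:
                depth[a - start:b - start] += 1
            pos += n


def feature_depth(alignments, feature: tuple[str, tuple[int, int]],
                  min_mapq: int = 1,
                  reference_lengths: dict[str, int] | None = None) -> float:
    """Mean per-position depth of uniquely placed alignments over a feature.

    Positions are covered by reference-consuming ops (M/D). Alignments with
    mapq below ``min_mapq`` (default: exclude all ambiguous placements) and
    secondary records are ignored.
    """
    ref, (start, end) = feature
    if end <= start:
        raise ParameterError("feature interval is empty")
    if start < 0 or (reference_lengths and end > reference_lengths.get(ref, end)):
        raise BoundsError(f"feature {ref}:{start}-{end} outside reference")
    depth = np.zeros(end - start, dtype=np.int64)
    for rec in alignments:
        if rec.ref_name != ref or rec.is_secondary or rec.mapq < min_mapq:
            continue
        if rec.ref_start >= end or rec.ref_end <= start:
            continue
        _add_coverage(depth, rec, start, end)
    return float(depth.mean())


def depth_profile(alignments, ref: str, start: int, end: int) -> DepthProfile:
    """Per-base depth counting ALL alignments — secondaries and mapq-0
    placements included — over a window; the input to repeat flagging."""
    if end <= start:
        raise ParameterError("window is empty")
    depth = np.zeros(end - start, dtype=np.int64)
    for rec in alignments:
        if rec.ref_name != ref or rec.ref_start >= end or rec.ref_end <= start:
            continue
        _add_coverage(depth, rec, start, end)
    return DepthProfile(ref, start, depth)


def select_reference_loci(genome: HostGenome, n_loci: int = 15,
                          locus_length: int = 20, seed: int = 0
                          ) -> list[FeatureCoverage]:
    """Randomly drawn 2n reference loci: short windows outside every repeat
    annotation and endogenous feature, each verified (by exhaustive substring
    count) to occur exactly once genome-wide, pairwise non-overlapping,
    seeded-deterministic."""
    rng = child_rng(seed, "reference_loci")
    exclude: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for a in genome.repeat_annotations:
        exclude[a.chrom].append((a.start, a.end))
    for c, s, e in genome.endogenous_features.values():
        exclude[c].append((s, e))
    names = list(genome.chromosomes)
    loci: list[FeatureCoverage] = []
    attempts = 0
    while len(loci) < n_loci:
        attempts += 1
        if attempts > 10_000:
            raise LayoutError("insufficient unique sequence space for reference loci")
        chrom = names[int(rng.integers(0, len(names)))]
        seq = genome.chromosomes[chrom]
        start = int(rng.integers(0, len(seq) - locus_length))
        end = start + locus_length
        if any(s < end and start < e for s, e in exclude[chrom]):
            continue
        if any(l.ref_name == chrom and l.start < end and start < l.end for l in loci):
            continue
        if count_occurrences(genome.chromosomes, seq[start:end]) != 1:
            continue
        loci.append(FeatureCoverage(f"ref2n_{len(loci):02d}", chrom, start, end, "2n"))
    return loci


def estimate_copy_number(coverages: list[FeatureCoverage],
                         tolerance: float = 0.5) -> list[FeatureCoverage]:
    """Fill ``cn_estimate`` (and the class-consistency verdict) in place.

    The 2n normalizer is the median of the 2n features' mean depths; each
    feature's estimate is ``2 · mean_depth / normalizer``. A feature is
    class-consistent when its estimate is within ``tolerance`` copies of its
    class value (n→1, 2n→2, 3n→3).
    """
    two_n = [c.mean_depth for c in coverages if c.expected_class == "2n"]
    if len(two_n) < 5:
        raise ParameterError(f"need >=5 2n features, got {len(two_n)}")
    ref = median(two_n)
    if ref <= 0:
        raise DataError("2n reference depth is zero")
    for c in coverages:
        c.cn_estimate = 2.0 * c.mean_depth / ref
        val = CLASS_VALUES.get(c.expected_class)
        c.consistent = None if val is None else abs(c.cn_estimate - val) <= tolerance
    return coverages


def flag_repetitive_flanks(profile: DepthProfile, baseline: float,
                           fold_threshold: float = 2.0,
                           merge_gap: int = 10) -> list[tuple[int, int]]:
    """Maximal runs of positions whose all-alignment depth exceeds
    ``fold_threshold × baseline``, merged across gaps shorter than
    ``merge_gap``. Returns intervals in reference coordinates."""
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    if not np.isfinite(fold_threshold):
        return []
    mask = profile.depth > fold_threshold * baseline
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((profile.start + i, profile.start + j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def rescue_construct_donor_ties(records_by_read: dict[str, list[AlignmentRecord]],
                                donors: list[tuple[str, str, tuple[int, int],
                                                   str, tuple[int, int]]],
                                pad: int = 5) -> None:
    """Resolve two-way ties between a construct 3n feature and its endogenous
    donor locus in favor of the donor.

    ``donors``: (feature_name, construct_ref, (cs, ce), donor_chrom, (gs, ge)).
    A read tied exactly between the feature's construct interval and its donor
    interval is reassigned to the donor placement (mapq restored), and the
    construct-side record dropped, in place.
    """
    for read_id, recs in records_by_read.items():
        prim = [r for r in recs if not r.is_secondary]
        if len(prim) != 2 or prim[0].n_equal_best_hits != 2:
            continue
        for name, cref, (cs, ce), gchrom, (gs, ge) in donors:
            con = next((r for r in prim if r.ref_name == cref
                        and r.ref_start >= cs - pad and r.ref_end <= ce + pad), None)
            gen = next((r for r in prim if r.ref_name == gchrom
                        and r.ref_start >= gs - pad and r.ref_end <= ge + pad), None)
            if con is None or gen is None or con is gen:
                continue
            gen.mapq = 40
            gen.n_equal_best_hits = 1
            recs.remove(con)
            break


def coverage_report(coverages: list[FeatureCoverage]) -> "pandas.DataFrame":
    import pandas as pd
    return pd.DataFrame([{
        "feature": c.feature_name, "ref": c.ref_name, "start": c.start,
        "end": c.end, "class": c.expected_class,
        "mean_depth": round(c.mean_depth, 3),
        "cn_estimate": None if c.cn_estimate is None else round(c.cn_estimate, 3),
        "consistent": c.consistent,
    } for c in coverages])
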