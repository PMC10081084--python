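"""Shared fixtures: one compact study genome with a planted heterozygous
insertion, mapped error-free short reads, and a pure-Python affine-gap local
alignment oracle kept independent of the package's DP kernels."""

from __future__ import annotations

from collections import namedtuple

import pytest

from insertra.align_core import KmerIndex, map_read
from insertra.copy_number import rescue_construct_donor_ties
from insertra.synthetic_data import (ConstructSpec, build_construct, build_host_genome,
                                     default_genome_spec, insert_transgene,
                                     simulate_short_reads)

SEED = 7


def reference_local_align(a: str, b: str, match=2, mismatch=-3,
                          gap_open=-5, gap_extend=-2) -> int:
    """Independent full-DP affine-gap local alignment score (pure Python).

    A gap of length g costs gap_open + g*gap_extend. Deliberately written
    without any code shared with the package so it can serve as the oracle
    for mapper scores.
    """
    NEG = -(10**9)
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Ei[j - 1] + gap_extend, Hi[j - 1] + gap_open + gap_extend)
            f = max(Fp[j] + gap_extend, Hp[j] + gap_open + gap_extend)
            h = Hp[j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(h, e, f, 0)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best = h
    return best


Mapped = namedtuple("Mapped", "genome construct diploid event reads records "
                              "by_read refs index genome_index construct_index")


@pytest.fixture(scope="session")
def compact_genome():
    return build_host_genome(default_genome_spec("compact", seed=SEED))


@pytest.fixture(scope="session")
def construct(compact_genome):
    return build_construct(ConstructSpec(seed=SEED), compact_genome)


@pytest.fixture(scope="session")
def het_diploid(compact_genome, construct):
    chrom, site = compact_genome.meta["true_insertion"]
    diploid, event = insert_transgene(compact_genome, construct, chrom, site, "het")
    return diploid, event


@pytest.fixture(scope="session")
def mapped(compact_genome, construct, het_diploid):
    """Error-free 30x short reads mapped against genome+construct, with
    construct↔donor ties rescued — the input shared by the junction and
    copy-number test groups."""
    diploid, event = het_diploid
    refs = {**compact_genome.chromosomes, construct.name: construct.full_sequence}
    index = KmerIndex(refs)
    genome_index = KmerIndex(compact_genome.chromosomes)
    construct_index = KmerIndex({construct.name: construct.full_sequence})
    l_dip = sum(len(s) for _, _, s in diploid.sequences())
    reads = simulate_short_reads(diploid, l_dip // 20, sub_error=0.0, seed=11)
    by_read = {}
    for r in reads.reads:
        recs = map_read(index, r.sequence, read_id=r.id, secondary_frac=0.7)
        for rec in recs:
            rec.is_paired = True
            rec.is_read1 = r.id.endswith("/1")
        by_read[r.id] = recs
    donors = []
    for name in ("beta2_promoter", "beta2_terminator"):
        ci = construct.feature_interval(name)
        gch, gs, ge = compact_genome.endogenous_features[name]
        donors.append((name, construct.name, ci, gch, (gs, ge)))
    rescue_construct_donor_ties(by_read, donors)
    records = [rec for recs in by_read.values() for rec in recs]
    return Mapped(compact_genome, construct, diploid, event, reads, records,
                  by_read, refs, index, genome_index, construct_index)
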