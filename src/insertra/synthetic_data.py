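"""Forward model: host genome, transgene construct, planted insertion, reads.

Everything downstream of this module is tested against the ground truth it
records. The model emulates the study system: a multi-chromosome host genome
whose pericentromeric region carries a cluster of near-identical ~750 bp
repeat copies (the ambiguity source), a piggyBac-style construct inserted
heterozygously at a TTAA motif with target-site duplication, Illumina-like
paired short reads and Nanopore-like noisy long reads.

Scenario geometry (defaults; see docs/methods.md for rationale):

* the repeat family has 12 copies (full scale) or 6 (compact scale) at 4%
  per-base divergence from a common ancestor — expected pairwise identity
  ``(1-d)^2 + d^2/3`` ≈ 0.922;
* the designated insertion TTAA sits at offset 375 of one "true" copy, so
  both ~370 bp inverse-PCR flanks are intra-family sequence and the combined
  flank query matches every copy over >700 bp;
* a 700 bp decoy repeat at 12% divergence sits 140 bp upstream of the true
  copy, extending the repetitive 5' context to ~1.2 kb before unique sequence
  (the "unique island" that long reads need to reach);
* DraI (TTT^AAA) sites are planted at fixed offsets inside the repeat ancestor
  and the construct spacers so the in-silico inverse PCR and Southern digest
  are deterministic.

Coordinates are 0-based half-open. All randomness fans out from one seed via
:func:`insertra.seqs.child_seed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BoundsError, ConfigError, LayoutError, MotifError, ParameterError
from .seqs import (child_rng, child_seed, count_occurrences, encode, mutate_substitutions,
                   random_sequence, revcomp, scrub_motif, write_fasta, write_fastq)

TSD_MOTIF = "TTAA"
DRAI_MOTIF = "TTTAAA"  # cuts TTT^AAA
SCAI_MOTIF = "AGTACT"  # cuts AGT^ACT

SHORT_READ_QUAL = chr(30 + 33)  # constant Q30
LONG_READ_QUAL = chr(12 + 33)  # constant Q12


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RepeatAnnotation:
    chrom: str
    start: int
    end: int
    family_id: str
    copy_id: int


@dataclass
class HostGenome:
    """Named chromosomes plus the ground-truth annotations used by every test."""

    chromosomes: dict[str, str]
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)
    endogenous_features: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    unique_windows: list[tuple[str, int, int, str]] = field(default_factory=list)
    ploidy_labels: tuple[str, ...] = ("hapA", "hapB")
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise LayoutError("duplicate chromosome names")
        for name, seq in self.chromosomes.items():
            if not seq or set(seq) - set("ACGT"):
                raise LayoutError(f"chromosome {name} empty or not uppercase ACGT")
        for ann in self.repeat_annotations:
            L = len(self.chromosomes[ann.chrom])
            if not (0 <= ann.start < ann.end <= L):
                raise LayoutError(f"annotation outside {ann.chrom}: {ann}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise BoundsError(f"{chrom}:{start}-{end} outside chromosome")
        return seq[start:end]

    def truth_intervals(self) -> list[tuple]:
        rows = [(a.chrom, a.start, a.end, f"repeat:{a.family_id}:{a.copy_id}")
                for a in self.repeat_annotations]
        rows += [(c, s, e, f"feature:{name}")
                 for name, (c, s, e) in self.endogenous_features.items()]
        rows += [(c, s, e, name) for c, s, e, name in self.unique_windows]
        return sorted(rows)

    def repeat_at(self, chrom: str, pos: int) -> RepeatAnnotation | None:
        for a in self.repeat_annotations:
            if a.chrom == chrom and a.start <= pos < a.end:
                return a
        return None

    def write_fasta(self, path) -> None:
        write_fasta(path, self.chromosomes)


@dataclass
class Feature:
    name: str
    sequence: str
    copy_class: str  # 'n' | '2n' | '3n' | 'unknown'
    role: str = ""  # 'itr' | 'marker' | 'promoter' | 'payload' | 'terminator' | 'spacer'


@dataclass
class TransgeneConstruct:
    features: list[Feature]
    full_sequence: str = ""
    itr5: str = ""
    itr3: str = ""
    primers: dict[str, str] = field(default_factory=dict)
    name: str = "transgene"

    def __post_init__(self):
        if not self.full_sequence:
            self.full_sequence = "".join(f.sequence for f in self.features)
        if not self.itr5:
            self.itr5 = next(f.sequence for f in self.features if f.role == "itr")
        if not self.itr3:
            self.itr3 = next(f.sequence for f in reversed(self.features) if f.role == "itr")

    def feature_interval(self, name: str) -> tuple[int, int]:
        pos = 0
        for f in self.features:
            if f.name == name:
                return pos, pos + len(f.sequence)
            pos += len(f.sequence)
        raise KeyError(name)

    def feature(self, name: str) -> Feature:
        return next(f for f in self.features if f.name == name)

    @property
    def marker(self) -> Feature:
        return next(f for f in self.features if f.role == "marker")

    def validate(self) -> None:
        if not self.full_sequence.startswith(self.itr5):
            raise ConfigError("full_sequence must begin with itr5")
        if not self.full_sequence.endswith(self.itr3):
            raise ConfigError("full_sequence must end with itr3")
        markers = [f for f in self.features if f.role == "marker"]
        if len(markers) != 1:
            raise ConfigError("construct needs exactly one marker (n-class) feature")


@dataclass
class InsertionEvent:
    chrom: str
    site: int  # 0-based start of the TTAA motif in the unmodified chromosome
    zygosity: str  # 'het' | 'hom'
    tsd: str = TSD_MOTIF
    repeat_family_id: str | None = None
    repeat_copy_id: int | None = None

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "site": self.site, "zygosity": self.zygosity,
                "tsd": self.tsd, "repeat_family_id": self.repeat_family_id,
                "repeat_copy_id": self.repeat_copy_id}


@dataclass
class DiploidGenome:
    """Two haplotypes; the insertion is applied to hapA (and hapB when hom)."""

    haplotypes: dict[str, dict[str, str]]
    event: InsertionEvent
    construct: TransgeneConstruct
    modified_haps: tuple[str, ...]

    def construct_interval(self, hap: str) -> tuple[int, int] | None:
        """Span of the construct (excluding TSDs) on a modified haplotype."""
        if hap not in self.modified_haps:
            return None
        s = self.event.site
        return s + 4, s + 4 + len(self.construct.full_sequence)

    def sequences(self) -> list[tuple[str, str, str]]:
        return [(hap, chrom, seq) for hap, chroms in self.haplotypes.items()
                for chrom, seq in chroms.items()]


@dataclass
class Read:
    id: str
    sequence: str
    quality: str
    mate_id: str | None
    truth_origin: tuple[str, str, int, str]  # (haplotype, chrom, start, strand)


@dataclass
class ReadSet:
    reads: list[Read]
    platform: str  # 'short_paired' | 'long'

    def validate(self) -> None:
        byid = {r.id: r for r in self.reads}
        for r in self.reads:
            if len(r.quality) != len(r.sequence):
                raise ParameterError(f"quality/sequence length mismatch for {r.id}")
            if r.mate_id is not None and byid[r.mate_id].mate_id != r.id:
                raise ParameterError(f"asymmetric mate link for {r.id}")

    def write_fastq(self, path1, path2=None) -> None:
        if self.platform == "short_paired" and path2 is not None:
            write_fastq(path1, ((r.id, r.sequence, r.quality)
                                for r in self.reads if r.id.endswith("/1")))
            write_fastq(path2, ((r.id, r.sequence, r.quality)
                                for r in self.reads if r.id.endswith("/2")))
        else:
            write_fastq(path1, ((r.id, r.sequence, r.quality) for r in self.reads))


# ---------------------------------------------------------------------------
# generator specs


@dataclass
class RepeatClusterSpec:
    family_id: str = "pericentromeric750"
    ancestor_length: int = 750
    # 3% per-copy divergence -> expected pairwise identity (1-d)^2 + d^2/3 ≈ 0.941,
    # keeping every copy pair inside the >=0.90 identity band that defines the family
    divergence: float = 0.03
    placements: tuple = ()  # ((chrom, pos), ...)
    true_copy: int = 0  # index into placements: the copy that hosts the insertion
    ttaa_offset: int = 375
    drai_offsets: tuple[int, int] = (0, 744)
    decoy: tuple | None = None  # (chrom, pos, length, divergence)


@dataclass
class EndogenousGeneSpec:
    chrom: str = "chr3"
    promoter_pos: int = 10_000
    promoter_len: int = 600
    terminator_pos: int = 12_000
    terminator_len: int = 500


@dataclass
class GenomeSpec:
    chromosomes: tuple = (("chr2", 70_000), ("chr3", 20_000))
    repeat: RepeatClusterSpec = field(default_factory=RepeatClusterSpec)
    endogenous: EndogenousGeneSpec = field(default_factory=EndogenousGeneSpec)
    n_unique_windows: int = 15
    unique_window_len: int = 20
    seed: int = 0


def default_genome_spec(scale: str = "compact", seed: int = 0) -> GenomeSpec:
    """Study-condition genome layouts.

    ``compact`` — 90 kb haploid, 6 repeat copies; sized so that 30× short-read
    simulations and full pipeline runs stay desk-fast while preserving the
    ambiguity structure.
    ``full`` — 1.5 Mb haploid (≈3 Mb diploid), 12 repeat copies ≥80 kb apart;
    the scale used for the ambiguity→resolution scenario.
    """
    if scale == "compact":
        placements = tuple(("chr2", p) for p in (6_000, 20_000, 34_000, 48_000, 62_000))
        placements += (("chr3", 4_000),)
        repeat = RepeatClusterSpec(placements=placements, true_copy=2,
                                   decoy=("chr2", 33_160, 700, 0.12))
        return GenomeSpec(chromosomes=(("chr2", 70_000), ("chr3", 20_000)),
                          repeat=repeat, seed=seed)
    if scale == "full":
        placements = tuple(("chr2", 100_000 + 80_000 * i) for i in range(10))
        placements += (("chr3", 150_000), ("chr3", 350_000))
        repeat = RepeatClusterSpec(placements=placements, true_copy=4,
                                   decoy=("chr2", 419_160, 700, 0.12))
        endo = EndogenousGeneSpec(chrom="chr3", promoter_pos=420_000,
                                  terminator_pos=423_000)
        return GenomeSpec(chromosomes=(("chr2", 1_000_000), ("chr3", 500_000)),
                          repeat=repeat, endogenous=endo, seed=seed)
    raise ConfigError(f"unknown genome scale {scale!r}")


@dataclass
class ConstructSpec:
    itr_len: int = 250
    spacer_a_len: int = 120
    marker_len: int = 680
    spacer_b_len: int = 60
    payload_len: int = 6_200
    spacer_c_len: int = 120
    drai_spacer_offset: int = 57
    scai_spacer_offset: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# operations


def _repeat_ancestor(length: int, spec: RepeatClusterSpec, seed: int) -> str:
    """Random ancestor with the designated TSD TTAA and DraI sites planted."""
    rng = child_rng(seed, "ancestor")
    anc = random_sequence(length, rng)
    protected: list[int] = []
    if spec is not None:
        s = list(anc)
        off = spec.ttaa_offset
        if off + 4 <= length:
            # flank the motif with C/G so the TTAA can never be part of a
            # stray TTTAAA (DraI) site that scrubbing would then destroy
            if off >= 1:
                s[off - 1] = "C"
            s[off:off + 4] = TSD_MOTIF
            if off + 4 < length:
                s[off + 4] = "G"
        for d in spec.drai_offsets:
            if d + len(DRAI_MOTIF) <= length:
                s[d:d + len(DRAI_MOTIF)] = DRAI_MOTIF
                protected.append(d)
        anc = "".join(s)
        anc = scrub_motif(anc, DRAI_MOTIF, protect=protected)
    return anc


def make_repeat_family(ancestor_length: int, n_copies: int, divergence: float,
                       seed: int, _spec: RepeatClusterSpec | None = None) -> list[str]:
    """Derive ``n_copies`` sequences from one random ancestor.

    Substitution-only model: each copy mutates every ancestor base
    independently with probability ``divergence``, drawing the replacement
    uniformly from the three alternatives. Two copies therefore match at a
    site with probability ``(1-d)^2 + d^2/3``; at d = 0.04 the expected
    pairwise identity is ≈ 0.922, inside the 0.90–0.95 band of the emulated
    repeat family. Substitution-only means copies stay column-aligned, which
    keeps planted motif offsets valid in every copy.
    """
    if ancestor_length < 50:
        raise ParameterError("ancestor_length must be >= 50")
    if not 0 <= divergence <= 0.3:
        raise ParameterError("divergence must be in [0, 0.3]")
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    anc = _repeat_ancestor(ancestor_length, _spec, seed)
    copies = []
    for i in range(n_copies):
        rng = child_rng(seed, "copy", i)
        copies.append(mutate_substitutions(anc, divergence, rng))
    return copies


def _patch_copy(copy: str, spec: RepeatClusterSpec) -> str:
    """Re-impose the planted motifs after divergence, scrub stray DraI sites."""
    s = list(copy)
    off = spec.ttaa_offset
    if off + 4 <= len(s):
        if off >= 1:
            s[off - 1] = "C"
        s[off:off + 4] = TSD_MOTIF
        if off + 4 < len(s):
            s[off + 4] = "G"
    protected = []
    for d in spec.drai_offsets:
        if d + len(DRAI_MOTIF) <= len(s):
            s[d:d + len(DRAI_MOTIF)] = DRAI_MOTIF
            protected.append(d)
    return scrub_motif("".join(s), DRAI_MOTIF, protect=protected)


def build_host_genome(spec: GenomeSpec) -> HostGenome:
    """Assemble the host genome from a spec; returns genome plus truth annotations.

    Repeat copies are embedded at the configured placements (across ≥2
    chromosomes to model cross-chromosome ambiguity), each patched so the
    insertion-site TTAA and the two DraI sites sit at the same offsets in
    every copy. Endogenous promoter/terminator intervals (the 3n donors) are
    annotated once, and ``n_unique_windows`` single-copy windows are selected
    and verified unique genome-wide.
    """
    chrom_names = [c for c, _ in spec.chromosomes]
    if len(chrom_names) < 2:
        raise LayoutError("genome spec must name at least 2 chromosomes")
    rng = child_rng(spec.seed, "background")
    chromosomes = {name: random_sequence(length, child_rng(spec.seed, "chrom", name))
                   for name, length in spec.chromosomes}

    rep = spec.repeat
    fam_seed = child_seed(spec.seed, "repeat_family")
    copies = make_repeat_family(rep.ancestor_length, len(rep.placements),
                                rep.divergence, fam_seed, _spec=rep)
    copies = [_patch_copy(c, rep) for c in copies]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(chrom: str, start: int, seq: str, what: str) -> None:
        end = start + len(seq)
        if chrom not in chromosomes or not (0 <= start and end <= len(chromosomes[chrom])):
            raise LayoutError(f"{what} outside {chrom}: {start}-{end}")
        for s0, e0 in occupied[chrom]:
            if start < e0 and s0 < end:
                raise LayoutError(f"{what} overlaps existing placement on {chrom}")
        chromosomes[chrom] = chromosomes[chrom][:start] + seq + chromosomes[chrom][end:]
        occupied[chrom].append((start, end))

    annotations = []
    for i, ((chrom, pos), seq) in enumerate(zip(rep.placements, copies)):
        place(chrom, pos, seq, f"repeat copy {i}")
        annotations.append(RepeatAnnotation(chrom, pos, pos + len(seq), rep.family_id, i))
    if len({a.chrom for a in annotations}) < 2:
        raise LayoutError("repeat copies must span at least 2 chromosomes")

    if rep.decoy is not None:
        dchrom, dpos, dlen, ddiv = rep.decoy
        anc = _repeat_ancestor(rep.ancestor_length, rep, fam_seed)[:dlen]
        decoy_seq = mutate_substitutions(anc, ddiv, child_rng(spec.seed, "decoy"))
        decoy_seq = scrub_motif(decoy_seq, DRAI_MOTIF)
        place(dchrom, dpos, decoy_seq, "decoy repeat")
        annotations.append(RepeatAnnotation(dchrom, dpos, dpos + dlen,
                                            rep.family_id + "_decoy", 0))

    endo = spec.endogenous
    features = {}
    for name, pos, length in (("beta2_promoter", endo.promoter_pos, endo.promoter_len),
                              ("beta2_terminator", endo.terminator_pos, endo.terminator_len)):
        end = pos + length
        for s0, e0 in occupied[endo.chrom]:
            if pos < e0 and s0 < end:
                raise LayoutError(f"{name} overlaps a placement on {endo.chrom}")
        occupied[endo.chrom].append((pos, end))
        features[name] = (endo.chrom, pos, end)

    genome = HostGenome(chromosomes=chromosomes, repeat_annotations=annotations,
                        endogenous_features=features)
    genome.meta["spec"] = spec
    true_chrom, true_pos = rep.placements[rep.true_copy]
    genome.meta["true_insertion"] = (true_chrom, true_pos + rep.ttaa_offset)
    genome.meta["family_consensus"] = _repeat_ancestor(rep.ancestor_length, rep, fam_seed)

    # single-copy reference windows, verified unique genome-wide
    wlen = spec.unique_window_len
    windows: list[tuple[str, int, int, str]] = []
    attempts = 0
    while len(windows) < spec.n_unique_windows:
        attempts += 1
        if attempts > 5000:
            raise LayoutError("could not find enough unique single-copy windows")
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, len(chromosomes[chrom]) - wlen))
        end = start + wlen
        if any(s0 < end and start < e0 for s0, e0 in occupied[chrom]):
            continue
        if any(c == chrom and s0 < end and start < e0 for c, s0, e0, _ in windows):
            continue
        if count_occurrences(chromosomes, chromosomes[chrom][start:end]) != 1:
            continue
        windows.append((chrom, start, end, f"unique_window:{len(windows)}"))
    genome.unique_windows = windows
    genome.validate()
    return genome


def build_construct(spec: ConstructSpec, genome: HostGenome) -> TransgeneConstruct:
    """Assemble the transgene construct.

    The 3n-class promoter/terminator are copied *verbatim* from the host's
    endogenous placements (so a heterozygous carrier holds three copies of
    each: two endogenous alleles plus one in the transgene). Marker and
    payload are construct-unique (n class). One DraI site is planted in each
    terminal spacer and one ScaI site in the 5' spacer; all other DraI/ScaI
    occurrences in the synthetic (non-donor) parts are scrubbed so digestion
    patterns are deterministic.
    """
    if genome is None or "beta2_promoter" not in genome.endogenous_features:
        raise ConfigError("construct requires a host genome with endogenous 3n donors")
    rng = child_rng(spec.seed, "construct")

    def rand(n):
        return random_sequence(n, rng)

    def donor(name):
        c, s, e = genome.endogenous_features[name]
        return genome.fetch(c, s, e)

    def plant(seq: str, motif: str, offset: int) -> str:
        return seq[:offset] + motif + seq[offset + len(motif):]

    spacer_a = plant(rand(spec.spacer_a_len), DRAI_MOTIF, spec.drai_spacer_offset)
    spacer_a = plant(spacer_a, SCAI_MOTIF, spec.scai_spacer_offset)
    spacer_c = plant(rand(spec.spacer_c_len), DRAI_MOTIF, spec.drai_spacer_offset)

    feats = [
        Feature("itr5", rand(spec.itr_len), "n", "itr"),
        Feature("spacer_a", spacer_a, "n", "spacer"),
        Feature("DsRed_marker", rand(spec.marker_len), "n", "marker"),
        Feature("spacer_b", rand(spec.spacer_b_len), "n", "spacer"),
        Feature("beta2_promoter", donor("beta2_promoter"), "3n", "promoter"),
        Feature("eGFP_IPpoI_payload", rand(spec.payload_len), "n", "payload"),
        Feature("beta2_terminator", donor("beta2_terminator"), "3n", "terminator"),
        Feature("spacer_c", spacer_c, "n", "spacer"),
        Feature("itr3", rand(spec.itr_len), "n", "itr"),
    ]
    # scrub stray enzyme sites in synthetic parts only (donors must stay verbatim)
    protected_sites: set[int] = set()
    pos = 0
    donor_spans = []
    for f in feats:
        if f.role in ("promoter", "terminator"):
            donor_spans.append((pos, pos + len(f.sequence)))
        if f.name == "spacer_a":
            protected_sites.add((DRAI_MOTIF, pos + spec.drai_spacer_offset))
            protected_sites.add((SCAI_MOTIF, pos + spec.scai_spacer_offset))
        if f.name == "spacer_c":
            protected_sites.add((DRAI_MOTIF, pos + spec.drai_spacer_offset))
        pos += len(f.sequence)
    full = "".join(f.sequence for f in feats)
    for motif in (DRAI_MOTIF, SCAI_MOTIF):
        protect = {p for m, p in protected_sites if m == motif}
        # also protect any occurrence overlapping a donor span
        start = 0
        while True:
            i = full.find(motif, start)
            if i < 0:
                break
            if any(s - len(motif) < i < e for s, e in donor_spans):
                protect.add(i)
            start = i + 1
        full = scrub_motif(full, motif, protect=sorted(protect))
    # DraI can only straddle a TSD junction as T|TTAA|A, i.e. when the construct
    # starts with A (5' junction) or ends with T (3' junction); forbid both so
    # boundary fragments are identical for every insertion site
    if full[0] == "A":
        full = "C" + full[1:]
    if full[-1] == "T":
        full = full[:-1] + "G"
    # re-split the scrubbed sequence back into features
    pos = 0
    for f in feats:
        f.sequence = full[pos:pos + len(f.sequence)]
        pos += len(f.sequence)

    L = len(full)
    primers = {
        "pB5_fwd": revcomp(full[180:201]),
        "pB5_rev": full[230:251],
        "pB3_fwd": full[L - 201:L - 180],
        "pB3_rev": revcomp(full[L - 251:L - 230]),
    }
    construct = TransgeneConstruct(features=feats, full_sequence=full, primers=primers)
    construct.validate()
    return construct


def insert_transgene(genome: HostGenome, construct: TransgeneConstruct,
                     chrom: str, site: int, zygosity: str = "het"
                     ) -> tuple[DiploidGenome, InsertionEvent]:
    """Plant the construct at a TTAA motif with target-site duplication.

    The modified haplotype is ``left + TTAA + construct + TTAA + right``:
    piggyBac integration duplicates the TTAA on both sides of the insert.
    Excising the construct plus exactly one TSD copy restores the original
    chromosome byte-identically (see :func:`excise_transgene`).
    """
    if zygosity not in ("het", "hom"):
        raise ParameterError(f"zygosity must be het|hom, got {zygosity!r}")
    seq = genome.chromosomes[chrom]
    if site < 4 or site + 8 > len(seq):
        raise BoundsError(f"site {site} too close to end of {chrom}")
    if seq[site:site + 4] != TSD_MOTIF:
        raise MotifError(f"{chrom}:{site} does not carry the TTAA motif")
    modified = seq[:site + 4] + construct.full_sequence + TSD_MOTIF + seq[site + 4:]
    hapA = dict(genome.chromosomes)
    hapA[chrom] = modified
    hapB = dict(genome.chromosomes)
    mods = ("hapA",)
    if zygosity == "hom":
        hapB[chrom] = modified
        mods = ("hapA", "hapB")
    ann = genome.repeat_at(chrom, site)
    event = InsertionEvent(chrom=chrom, site=site, zygosity=zygosity,
                           repeat_family_id=ann.family_id if ann else None,
                           repeat_copy_id=ann.copy_id if ann else None)
    diploid = DiploidGenome(haplotypes={"hapA": hapA, "hapB": hapB},
                            event=event, construct=construct, modified_haps=mods)
    return diploid, event


def excise_transgene(haplotype_seq: str, site: int, construct_len: int) -> str:
    """Remove the construct plus one TSD copy; inverse of :func:`insert_transgene`."""
    return haplotype_seq[:site + 4] + haplotype_seq[site + 8 + construct_len:]


# ---------------------------------------------------------------------------
# read simulation


def simulate_short_reads(diploid: DiploidGenome, n_pairs: int, insert_mean: int = 350,
                         insert_sd: int = 50, read_len: int = 150,
                         sub_error: float = 0.005, seed: int = 0) -> ReadSet:
    """Illumina-like paired-end reads (substitution-only errors, constant Q30).

    Fragments are drawn uniformly over both haplotypes proportional to length;
    the two mates are the fragment ends, the second reverse-complemented, with
    the fragment orientation itself randomized. Fragment length is normal
    (``insert_mean`` ± ``insert_sd``) clipped below at ``read_len`` so
    overlapping mates are permitted.
    """
    if n_pairs <= 0:
        raise ParameterError("n_pairs must be positive")
    if not 0 <= sub_error <= 0.05:
        raise ParameterError("sub_error must be in [0, 0.05]")
    rng = child_rng(seed, "short_reads")
    seqs = diploid.sequences()
    lengths = np.array([len(s) for _, _, s in seqs], dtype=np.float64)
    probs = lengths / lengths.sum()
    src = rng.choice(len(seqs), size=n_pairs, p=probs)
    frag_lens = np.clip(np.rint(rng.normal(insert_mean, insert_sd, n_pairs)),
                        read_len, None).astype(np.int64)
    flips = rng.random(n_pairs) < 0.5
    reads: list[Read] = []
    qual = SHORT_READ_QUAL * read_len
    for i in range(n_pairs):
        hap, chrom, seq = seqs[src[i]]
        flen = min(int(frag_lens[i]), len(seq))
        start = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[start:start + flen]
        left = frag[:read_len]
        right = revcomp(frag[-read_len:])
        if flips[i]:
            r1_seq, r1_origin = right, (hap, chrom, start + flen - read_len, "-")
            r2_seq, r2_origin = left, (hap, chrom, start, "+")
        else:
            r1_seq, r1_origin = left, (hap, chrom, start, "+")
            r2_seq, r2_origin = right, (hap, chrom, start + flen - read_len, "-")
        rid = f"frag{i:07d}"
        r1 = mutate_substitutions(r1_seq, sub_error, rng)
        r2 = mutate_substitutions(r2_seq, sub_error, rng)
        reads.append(Read(f"{rid}/1", r1, qual, f"{rid}/2", r1_origin))
        reads.append(Read(f"{rid}/2", r2, qual, f"{rid}/1", r2_origin))
    return ReadSet(reads=reads, platform="short_paired")


def _apply_long_read_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Mixture error model: 40% substitutions, 30% 1-bp insertions, 30% 1-bp
    deletions at total per-base rate ``rate``."""
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    u = rng.random(codes.size)
    sub = u < 0.4 * rate
    ins = (u >= 0.4 * rate) & (u < 0.7 * rate)
    dele = (u >= 0.7 * rate) & (u < rate)
    shift = rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)
    codes[sub] = (codes[sub] + shift) % 4
    counts = np.ones(codes.size, dtype=np.int64)
    counts[dele] = 0
    counts[ins] += 1
    out = np.repeat(codes, counts)
    if ins.any():
        slots = np.cumsum(counts)[ins] - 1  # the duplicated slot after each kept base
        out[slots] = rng.integers(0, 4, size=slots.size, dtype=np.uint8)
    return "".join("ACGT"[c] for c in out)


def simulate_long_reads(diploid: DiploidGenome, n_reads: int, length_mean: int = 8_000,
                        length_sd: int = 1_500, error_rate: float = 0.08, seed: int = 0,
                        anchor_interval: tuple[str, str, int, int] | None = None,
                        n_anchored: int = 0, min_anchor_overlap: int = 1_000) -> ReadSet:
    """Nanopore-like long reads (mixed substitution/indel errors, constant Q12).

    ``n_reads`` background reads are drawn uniformly over both haplotypes.
    With ``anchor_interval`` = (hap, chrom, start, end), ``n_anchored``
    additional reads are constrained to overlap that interval by at least
    ``min_anchor_overlap`` bp — emulating the extraction of reads that align
    to the expected insertion region before assembly.
    """
    if n_reads < 0 or n_anchored < 0 or (n_reads + n_anchored) == 0:
        raise ParameterError("need a positive number of reads")
    if not 0 <= error_rate <= 0.15:
        raise ParameterError("error_rate must be in [0, 0.15]")
    rng = child_rng(seed, "long_reads")
    seqs = diploid.sequences()
    lengths = np.array([len(s) for _, _, s in seqs], dtype=np.float64)
    probs = lengths / lengths.sum()
    lo, hi = max(500, length_mean // 4), length_mean + 2 * length_sd
    reads: list[Read] = []

    def emit(idx: int, hap: str, chrom: str, seq: str, start: int, rlen: int) -> None:
        frag = seq[start:start + rlen]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_long_read_errors(frag, error_rate, rng)
        reads.append(Read(f"long{idx:05d}", frag, LONG_READ_QUAL * len(frag), None,
                          (hap, chrom, start, strand)))

    for i in range(n_reads):
        hap, chrom, seq = seqs[int(rng.choice(len(seqs), p=probs))]
        rlen = min(int(np.clip(rng.normal(length_mean, length_sd), lo, hi)), len(seq))
        start = int(rng.integers(0, len(seq) - rlen + 1))
        emit(i, hap, chrom, seq, start, rlen)
    if n_anchored:
        if anchor_interval is None:
            raise ParameterError("n_anchored requires anchor_interval")
        hap, chrom, a_lo, a_hi = anchor_interval
        seq = diploid.haplotypes[hap][chrom]
        for j in range(n_anchored):
            rlen = int(np.clip(rng.normal(length_mean, length_sd), lo, hi))
            ov = min(min_anchor_overlap, rlen, a_hi - a_lo)
            s_lo = max(0, a_lo - (rlen - ov))
            s_hi = min(len(seq) - rlen, a_hi - ov)
            if s_hi < s_lo:
                s_lo = s_hi = max(0, min(a_lo, len(seq) - rlen))
            start = int(rng.integers(s_lo, s_hi + 1))
            emit(n_reads + j, hap, chrom, seq, start, rlen)
    return ReadSet(reads=reads, platform="long")
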