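"""Construct–genome junction evidence from read alignments.

Covers the "informative read" analysis: split reads (soft-clipped alignments
whose clipped tail maps to the other reference class), discordant mate pairs
bridging construct and genome, junction-anchored flank consensus building,
TTAA target-site-duplication detection, and a greedy overlap-layout-consensus
assembly of long reads into a transgene-bearing contig.

Short-read consensus building exploits the substitution-only error model of
the simulator: clipped tails are justified at the construct boundary and
majority-voted column by column. Long-read overlaps and consensus polishing
use edit-distance alignments (edlib), which tolerate the indel-rich error
model of the long-read simulator.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import pysam

from .align_core import AlignmentRecord, KmerIndex, map_read
from .errors import EvidenceError, FormatError, ParameterError
from .seqs import revcomp
from .synthetic_data import ReadSet, TSD_MOTIF

_CIGAR_OPS = "MIDNSHP=XB"


@dataclass
class SplitRead:
    read_id: str
    side: str  # '5prime' | '3prime'
    anchor_in_construct: bool
    clip_is_leading: bool
    clipped_seq: str  # ref-forward orientation
    anchor: AlignmentRecord
    clip_hit: AlignmentRecord | None = None  # where the clip maps on the other class


@dataclass
class DiscordantPair:
    read_id: str
    side: str
    construct_record: AlignmentRecord
    genome_record: AlignmentRecord


@dataclass
class InformativeReadSet:
    split_reads: list[SplitRead] = field(default_factory=list)
    discordant_pairs: list[DiscordantPair] = field(default_factory=list)
    construct_length: int | None = None

    def split_by_side(self, side: str) -> list[SplitRead]:
        return [s for s in self.split_reads if s.side == side]


@dataclass
class TSDCall:
    motif: str
    present_5prime: bool
    present_3prime: bool
    flank5: str
    flank3: str

    @property
    def is_complete(self) -> bool:
        return self.present_5prime and self.present_3prime


def records_from_sam(path) -> list[AlignmentRecord]:
    """Parse a SAM file back into AlignmentRecords (any standards-compliant
    producer works; NH tags are honored when present)."""
    records = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for seg in fh:
                if seg.is_unmapped:
                    continue
                cigar = [( _CIGAR_OPS[op], n) for op, n in (seg.cigartuples or [])]
                rec = AlignmentRecord(
                    read_id=seg.query_name,
                    ref_name=seg.reference_name,
                    ref_start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=cigar,
                    score=seg.get_tag("AS") if seg.has_tag("AS") else 0,
                    identity=0.0,
                    n_equal_best_hits=seg.get_tag("NH") if seg.has_tag("NH") else 1,
                    mapq=seg.mapping_quality,
                    seq=seg.query_sequence or "",
                    is_secondary=seg.is_secondary,
                    is_paired=seg.is_paired,
                    is_read1=not seg.is_read2,
                )
                records.append(rec)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse SAM {path}: {exc}") from exc
    return records


def _clip_maps_to(clip_seq: str, index: KmerIndex | None, min_score: int) -> AlignmentRecord | None:
    if index is None:
        return AlignmentRecord(read_id="", ref_name="", ref_start=0, strand="+",
                               cigar=[("M", len(clip_seq))], score=0, identity=1.0)
    if len(clip_seq) < index.k:
        return None
    hits = map_read(index, clip_seq, min_chain_seeds=1)
    if hits and hits[0].score >= min_score:
        return hits[0]
    return None


def extract_informative_reads(alignments, construct_names: set[str],
                              min_clip: int = 20,
                              genome_index: KmerIndex | None = None,
                              construct_index: KmerIndex | None = None,
                              construct_length: int | None = None
                              ) -> InformativeReadSet:
    """Extract split reads and discordant pairs at the construct boundary.

    ``alignments`` may be a SAM path or an iterable of AlignmentRecords.
    Split criterion: a primary alignment on one reference class carrying a
    soft clip of ≥ ``min_clip`` bp whose clipped sequence maps to the other
    class (verified through the provided indexes when given). Discordant
    criterion: the two mates of a pair place on different classes. Records
    are labeled 5prime/3prime by the construct coordinate of their anchor.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = records_from_sam(alignments)
    construct_names = set(construct_names)
    out = InformativeReadSet()
    primaries = [r for r in alignments if not r.is_secondary]
    if construct_length is None and construct_index is not None:
        construct_length = max(len(s) for s in construct_index.seqs.values())

    def construct_side(pos: int) -> str:
        if construct_length:
            return "5prime" if pos < construct_length / 2 else "3prime"
        return "5prime"

    for rec in primaries:
        in_construct = rec.ref_name in construct_names
        for leading in (True, False):
            op, n = rec.cigar[0] if leading else rec.cigar[-1]
            if op != "S" or n < min_clip:
                continue
            clip_seq = rec.seq[:n] if leading else rec.seq[len(rec.seq) - n:]
            other_index = genome_index if in_construct else construct_index
            # a clip is informative when it belongs to the other reference class
            hit = _clip_maps_to(clip_seq, other_index, min_score=int(1.2 * n))
            if hit is None:
                continue
            if in_construct:
                side = "5prime" if leading else "3prime"
            else:
                side = construct_side(hit.ref_start)
            out.split_reads.append(SplitRead(
                read_id=rec.read_id, side=side, anchor_in_construct=in_construct,
                clip_is_leading=leading, clipped_seq=clip_seq, anchor=rec,
                clip_hit=hit if other_index is not None else None))
    out.construct_length = construct_length

    pairs: dict[str, dict[bool, AlignmentRecord]] = defaultdict(dict)
    for rec in primaries:
        # discordance is only evidence when both mates place uniquely
        if rec.is_paired and rec.mapq > 0:
            pairs.setdefault(_pair_key(rec.read_id), {})[rec.is_read1] = rec
    for key, mates in pairs.items():
        if len(mates) != 2:
            continue
        a, b = mates[True], mates[False]
        a_in = a.ref_name in construct_names
        b_in = b.ref_name in construct_names
        if a_in == b_in:
            continue
        c_rec, g_rec = (a, b) if a_in else (b, a)
        out.discordant_pairs.append(DiscordantPair(
            read_id=key, side=construct_side(c_rec.ref_start),
            construct_record=c_rec, genome_record=g_rec))
    return out


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def build_flank_consensus(informative: InformativeReadSet, side: str,
                          min_reads: int = 3, min_column_support: int = 2) -> str:
    """Majority-vote consensus of clipped genomic tails, anchored at the
    construct boundary.

    For the 5' side the tails all *end* at the junction (the consensus is the
    genomic sequence immediately upstream, ending with the TSD copy); for the
    3' side they all *begin* there. Columns supported by fewer than
    ``min_column_support`` tails are trimmed, so the consensus grows outward
    from the junction only as far as the evidence reaches. Ties are broken
    alphabetically.
    """
    if side not in ("5prime", "3prime"):
        raise ParameterError("side must be 5prime|3prime")
    clen = informative.construct_length
    tails = []
    for s in informative.split_by_side(side):
        if s.anchor_in_construct:
            # construct-anchored: the clipped tail is genomic and abuts the
            # construct terminus exactly (the TSD base cannot extend into the
            # construct by design), so the tail is junction-anchored as-is
            if side == "5prime" and s.clip_is_leading and s.anchor.ref_start == 0:
                tails.append(s.clipped_seq)
            elif (side == "3prime" and not s.clip_is_leading and clen
                  and s.anchor.ref_end == clen):
                tails.append(s.clipped_seq)
            continue
        # genome-anchored: the aligned genomic segment ends at the junction,
        # except that the local aligner may have extended a few coincidentally
        # matching construct bases; where the clip maps inside the construct
        # tells us exactly how many, so the boundary can be corrected
        if s.clip_hit is None or s.anchor.mapq == 0:
            continue
        qs, qe = s.anchor.query_span()
        if side == "5prime" and not s.clip_is_leading:
            g = s.clip_hit.ref_start
            if g <= 6:
                tails.append(s.anchor.seq[:qe - g])
        elif side == "3prime" and s.clip_is_leading and clen:
            g = clen - s.clip_hit.ref_end
            if 0 <= g <= 6:
                tails.append(s.anchor.seq[qs + g:])
    if len(tails) < min_reads:
        raise EvidenceError(
            f"only {len(tails)} junction-anchored reads on the {side} side "
            f"(need >= {min_reads})")
    length = max(len(t) for t in tails)
    consensus = []
    for col in range(length):
        votes = Counter()
        for t in tails:
            if side == "5prime":
                # right-justified: column 0 is adjacent to the junction
                if col < len(t):
                    votes[t[len(t) - 1 - col]] += 1
            else:
                if col < len(t):
                    votes[t[col]] += 1
        if sum(votes.values()) < min_column_support:
            break
        top = max(votes.values())
        base = min(b for b, v in votes.items() if v == top)
        consensus.append(base)
    if side == "5prime":
        return "".join(reversed(consensus))
    return "".join(consensus)


def detect_tsd(flank5: str, flank3: str, motif: str = TSD_MOTIF) -> TSDCall:
    """Is the target-site duplication present on both junction consensi?

    A genuine piggyBac insertion duplicates the motif: the 5' flank consensus
    ends with it and the 3' flank consensus begins with it.
    """
    if not motif:
        raise ParameterError("motif must be non-empty")
    if len(flank5) < len(motif) or len(flank3) < len(motif):
        raise ParameterError("flank consensi shorter than the motif")
    return TSDCall(motif=motif,
                   present_5prime=flank5.endswith(motif),
                   present_3prime=flank3.startswith(motif),
                   flank5=flank5, flank3=flank3)


# ---------------------------------------------------------------------------
# long-read assembly


def _edlib_identity(query: str, target: str, mode: str) -> tuple[float, tuple[int, int]]:
    res = edlib.align(query, target, mode=mode, task="locations")
    if res["editDistance"] < 0:
        return 0.0, (0, 0)
    loc = res["locations"][0] if res["locations"] else (0, len(target) - 1)
    loc = (loc[0] or 0, loc[1] if loc[1] is not None else len(target) - 1)
    return 1.0 - res["editDistance"] / max(len(query), 1), loc


def _estimate_offset(a: str, b: str, k: int = 13) -> tuple[int, int] | None:
    """Median diagonal of shared k-mers: approximate start of b within a."""
    pos_a: dict[str, int] = {}
    for i in range(0, len(a) - k + 1):
        pos_a.setdefault(a[i:i + k], i)
    diags = []
    for j in range(0, len(b) - k + 1, 3):
        i = pos_a.get(b[j:j + k])
        if i is not None:
            diags.append(i - j)
    if len(diags) < 5:
        return None
    diags.sort()
    return diags[len(diags) // 2], len(diags)


def _merge(a: str, b: str, offset: int) -> str:
    """Merge b into a given b's estimated start offset within a (may be <0)."""
    if offset < 0:
        return _merge(b, a, -offset)
    ov_a = a[offset:]
    res = edlib.align(ov_a, b, mode="SHW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return a + b  # degenerate; polishing cleans up
    end_in_b = res["locations"][0][1] + 1
    if end_in_b >= len(b):
        return a
    return a + b[end_in_b:]


def _polish(contig: str, members: list[str]) -> str:
    """One round of pileup polishing: majority base / deletion / insertion."""
    votes = [Counter() for _ in range(len(contig))]
    insertions: dict[int, Counter] = defaultdict(Counter)
    coverage = [0] * len(contig)
    for read in members:
        res = edlib.align(read, contig, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        start = res["locations"][0][0] or 0
        ci, ri = start, 0
        pending_ins = ""
        for n, op in _parse_cigar(res["cigar"]):
            if op == "=" or op == "M" or op == "X":
                for _ in range(n):
                    if pending_ins:
                        insertions[ci][pending_ins] += 1
                        pending_ins = ""
                    if ci < len(contig):
                        votes[ci][read[ri]] += 1
                        coverage[ci] += 1
                    ci += 1
                    ri += 1
            elif op == "I":
                pending_ins += read[ri:ri + n]
                ri += n
            elif op == "D":
                for _ in range(n):
                    if ci < len(contig):
                        votes[ci]["-"] += 1
                        coverage[ci] += 1
                    ci += 1
    out = []
    for i, v in enumerate(votes):
        ins = insertions.get(i)
        if ins:
            seq, cnt = ins.most_common(1)[0]
            if cnt * 2 > max(coverage[i], 1):
                out.append(seq)
        if not v:
            out.append(contig[i])
            continue
        top = max(v.values())
        base = min(b for b, c in v.items() if c == top)
        if base != "-":
            out.append(base)
    return "".join(out)


def _parse_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def assemble_long_reads(reads: ReadSet, anchor_sequences: dict[str, str],
                        min_overlap: int = 500, min_overlap_identity: float = 0.80,
                        anchor_min_identity: float = 0.75, anchor_min_len: int = 400,
                        polish_rounds: int = 2) -> str:
    """Greedy overlap-layout-consensus assembly of anchor-containing long reads.

    Reads containing one of the ``anchor_sequences`` (marker/payload features;
    matched permissively at ≥ ``anchor_min_identity`` to tolerate long-read
    error) are oriented to the anchor's forward strand and merged greedily:
    at every step the pair with the highest-scoring suffix–prefix overlap of
    ≥ ``min_overlap`` bp at ≥ ``min_overlap_identity`` is merged. The final
    contig is polished by pileup majority vote over its member reads and the
    longest anchor-containing contig is returned.
    """
    if reads.platform != "long":
        raise ParameterError("assemble_long_reads expects a long-read ReadSet")
    # tile the anchors so reads containing only part of a long anchor still
    # qualify; edit-distance matching tolerates the indel-rich error model
    tiles: list[str] = []
    for seq in anchor_sequences.values():
        step = min(max(anchor_min_len, 1), len(seq))
        tiles.extend(seq[i:i + step] for i in range(0, max(len(seq) - step, 0) + 1, step))
    oriented: list[str] = []
    for read in reads.reads:
        best = (0.0, "+")
        for tile in tiles:
            if len(tile) > len(read.sequence):
                continue
            for strand, target in (("+", read.sequence), ("-", revcomp(read.sequence))):
                res = edlib.align(tile, target, mode="HW",
                                  k=int(len(tile) * (1 - anchor_min_identity)))
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / len(tile)
                    if ident > best[0]:
                        best = (ident, strand)
        if best[0] >= anchor_min_identity:
            oriented.append(read.sequence if best[1] == "+" else revcomp(read.sequence))
    if not oriented:
        raise EvidenceError("no long reads contain a construct anchor")
    if len(oriented) == 1:
        return oriented[0]

    contigs: dict[int, str] = {i: s for i, s in enumerate(oriented)}
    members: dict[int, list[str]] = {i: [s] for i, s in enumerate(oriented)}
    next_id = len(oriented)
    cache: dict[tuple[int, int], tuple | None] = {}

    def pair_score(i: int, j: int):
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        a, b = contigs[key[0]], contigs[key[1]]
        result = None
        est = _estimate_offset(a, b)
        if est is not None:
            offset, _n = est
            ov = (min(len(a) - offset, len(b)) if offset >= 0
                  else min(len(b) + offset, len(a)))
            if ov >= min_overlap:
                a_ov = a[offset:offset + ov] if offset >= 0 else b[-offset:-offset + ov]
                b_ov = b[:ov] if offset >= 0 else a[:ov]
                ident, _ = _edlib_identity(a_ov, b_ov, "NW")
                if ident >= min_overlap_identity:
                    result = (ov * ident, key[0], key[1], offset)
        cache[key] = result
        return result

    while len(contigs) > 1:
        best = None
        ids = sorted(contigs)
        for x, i in enumerate(ids):
            for j in ids[x + 1:]:
                cand = pair_score(i, j)
                if cand and (best is None or cand[0] > best[0]):
                    best = cand
        if best is None:
            break
        _, i, j, offset = best
        merged = _merge(contigs[i], contigs[j], offset)
        new_members = members[i] + members[j]
        for k in list(cache):
            if i in k or j in k:
                del cache[k]
        del contigs[i], contigs[j], members[i], members[j]
        contigs[next_id] = merged
        members[next_id] = new_members
        next_id += 1

    # pick the longest contig (every contig here contains ≥1 anchored read)
    order = max(contigs, key=lambda x: len(contigs[x]))
    contig, group = contigs[order], members[order]
    for _ in range(polish_rounds):
        contig = _polish(contig, group)
    return contig
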