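"""Self-contained read mapper and local-similarity search.

The pipeline never shells out to an external aligner: this module provides

* :func:`smith_waterman` — optimal affine-gap local alignment (full dynamic
  program, numba-accelerated) with traceback; it is both the extension engine
  and the in-package full-DP reference that seeded mapping is checked against;
* :class:`KmerIndex` — an exact k-mer position index over the forward strand
  of a set of named references (queries are reverse-complemented, so minus
  strand hits are found without indexing both strands);
* :func:`map_read` — seed / chain / banded-extend read mapping that reports
  *every* locus tying the best score (``n_equal_best_hits``, mapq 0 when
  ambiguous), the qualitative unique-vs-ambiguous discrimination the analysis
  relies on;
* :func:`local_search` — BLAST-like similarity search reporting identity and
  alignment length per hit, used for flank queries and probe matching.

Scoring defaults (match +2, mismatch −3, gap open −5, gap extend −2) are shared
with the synthetic-data generators so every identity in the package is computed
under one model. A gap of length g costs ``open + g·extend``. Identity is the
fraction of matching columns over all alignment columns (including gaps);
``aln_length`` is that column count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from . import _kernels
from .errors import ParameterError
from .seqs import encode, revcomp


class Scoring(NamedTuple):
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()

_OP_CODES = {"M": 0, "I": 1, "D": 2, "S": 4}


@dataclass
class Alignment:
    """Traceback of one local alignment of query ``a`` against target ``b``."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    cigar: list  # [(op, length)] over the aligned core only (M/I/D)
    n_match: int
    aln_length: int  # alignment columns, gaps included

    @property
    def identity(self) -> float:
        return self.n_match / self.aln_length if self.aln_length else 0.0


@dataclass
class AlignmentRecord:
    """One read-to-reference placement with clip structure and hit multiplicity."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    strand: str  # '+' or '-'
    cigar: list  # [(op, length)], op in M/I/D/S, query given in ref-forward orientation
    score: int
    identity: float
    n_equal_best_hits: int = 1
    mapq: int = 40
    seq: str = ""  # read sequence, ref-forward orientation
    is_secondary: bool = False
    # pairing metadata (set by the pipeline, not the mapper)
    is_paired: bool = False
    is_read1: bool = True
    mate_ref: str | None = None
    mate_pos: int = -1
    mate_strand: str = "+"
    mate_unmapped: bool = False

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    def query_span(self) -> tuple[int, int]:
        """Aligned query interval (ref-forward orientation), excluding soft clips."""
        lead = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        qlen = sum(n for op, n in self.cigar if op in "MIS")
        tail = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
        return lead, qlen - tail


@dataclass(order=True)
class SearchHit:
    sort_key: tuple = field(init=False, repr=False)
    query_id: str = field(compare=False, default="query")
    ref_name: str = field(compare=False, default="")
    ref_start: int = field(compare=False, default=0)
    ref_end: int = field(compare=False, default=0)
    q_start: int = field(compare=False, default=0)
    q_end: int = field(compare=False, default=0)
    strand: str = field(compare=False, default="+")
    identity: float = field(compare=False, default=0.0)
    aln_length: int = field(compare=False, default=0)
    score: int = field(compare=False, default=0)

    def __post_init__(self):
        self.sort_key = (-self.score, self.ref_name, self.ref_start)


# ---------------------------------------------------------------------------
# Smith–Waterman with traceback


def _traceback(a: np.ndarray, b: np.ndarray, bi: int, bj: int,
               ptr_h: np.ndarray, ptr_e: np.ndarray, ptr_f: np.ndarray):
    ops: list[tuple[str, int]] = []
    n_match = 0
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                if a[i - 1] == b[j - 1]:
                    n_match += 1
                ops.append(("M", 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # horizontal run: consumes reference (deletion from query)
            ops.append(("D", 1))
            ext = ptr_e[i, j]
            j -= 1
            if not ext:
                state = "H"
        else:  # vertical run: consumes query (insertion relative to reference)
            ops.append(("I", 1))
            ext = ptr_f[i, j]
            i -= 1
            if not ext:
                state = "H"
    ops.reverse()
    # run-length encode
    cigar: list[tuple[str, int]] = []
    for op, n in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))
    aln_length = sum(n for _, n in ops)
    return i, j, cigar, n_match, aln_length


def smith_waterman(a: str, b: str, scoring: Scoring = DEFAULT_SCORING):
    """Optimal local alignment of ``a`` vs ``b``.

    Returns ``(score, Alignment)``. Full O(len(a)·len(b)) dynamic program —
    exact, no heuristics; intended for desk-scale sequences (≤ a few kb).
    """
    if not a or not b:
        raise ParameterError("smith_waterman requires non-empty sequences")
    ca, cb = encode(a), encode(b)
    scoring = Scoring(*scoring)
    score, bi, bj, ph, pe, pf = _kernels.sw_affine(
        ca, cb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    ai, aj, cigar, n_match, aln_length = _traceback(ca, cb, bi, bj, ph, pe, pf)
    aln = Alignment(int(score), ai, bi, aj, bj, cigar, n_match, aln_length)
    return int(score), aln


# ---------------------------------------------------------------------------
# k-mer index


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out |= codes[j:j + n].astype(np.int64) << (2 * (k - 1 - j))
    return out


class KmerIndex:
    """Exact k-mer → position map over the forward strand of named references."""

    def __init__(self, references: dict[str, str], k: int = 15):
        if not 8 <= k <= 31:
            raise ParameterError(f"k must be in [8, 31], got {k}")
        self.k = k
        self.names: list[str] = list(references)
        self.seqs: dict[str, str] = dict(references)
        self.codes: dict[str, np.ndarray] = {n: encode(s) for n, s in references.items()}
        all_codes, all_ref, all_pos = [], [], []
        for ri, name in enumerate(self.names):
            kc = _kmer_codes(self.codes[name], k)
            all_codes.append(kc)
            all_ref.append(np.full(kc.size, ri, dtype=np.int32))
            all_pos.append(np.arange(kc.size, dtype=np.int32))
        cat = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
        order = np.argsort(cat, kind="stable")
        self._sorted_codes = cat[order]
        self._ref_ids = np.concatenate(all_ref)[order] if all_codes else np.empty(0, np.int32)
        self._positions = np.concatenate(all_pos)[order] if all_codes else np.empty(0, np.int32)

    def n_indexed_positions(self, name: str | None = None) -> int:
        if name is None:
            return int(self._sorted_codes.size)
        ri = self.names.index(name)
        return int((self._ref_ids == ri).sum())

    def n_distinct_kmers(self) -> int:
        return int(np.unique(self._sorted_codes).size)

    def lookup(self, query_codes: np.ndarray):
        """All index matches for the query's k-mers.

        Returns (q_pos, ref_id, ref_pos) arrays, one row per match.
        """
        kc = _kmer_codes(query_codes, self.k)
        lo = np.searchsorted(self._sorted_codes, kc, side="left")
        hi = np.searchsorted(self._sorted_codes, kc, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int32)
            return e, e, e
        q_pos = np.repeat(np.arange(kc.size, dtype=np.int32), counts)
        block_starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        idx = np.arange(total, dtype=np.int64) + np.repeat(lo - block_starts, counts)
        return q_pos, self._ref_ids[idx], self._positions[idx]

    def query_kmer(self, kmer: str) -> list[tuple[str, int]]:
        """Positions of one exact k-mer (forward strand); convenience accessor."""
        q, r, p = self.lookup(encode(kmer))
        return [(self.names[ri], int(pp)) for ri, pp in zip(r, p)]


def index_reference(references: dict[str, str], k: int = 15) -> KmerIndex:
    return KmerIndex(references, k)


# ---------------------------------------------------------------------------
# candidate clustering shared by map_read / local_search


def _cluster_candidates(q_pos, ref_ids, ref_pos, band: int):
    """Group seed matches into (ref_id, diagonal) clusters.

    Returns list of (ref_id, diag_median, n_seeds, rp_min, rp_max).
    """
    if q_pos.size == 0:
        return []
    diags = ref_pos.astype(np.int64) - q_pos.astype(np.int64)
    out = []
    for ri in np.unique(ref_ids):
        mask = ref_ids == ri
        d = np.sort(diags[mask])
        rp = ref_pos[mask]
        qp = q_pos[mask]
        order = np.argsort(diags[mask], kind="stable")
        d_sorted = diags[mask][order]
        rp_sorted = rp[order]
        # split where consecutive diagonals jump by more than band/2
        breaks = np.where(np.diff(d_sorted) > max(band // 2, 8))[0] + 1
        start = 0
        for stop in list(breaks) + [d_sorted.size]:
            seg_d = d_sorted[start:stop]
            seg_rp = rp_sorted[start:stop]
            out.append((int(ri), int(np.median(seg_d)), int(seg_d.size),
                        int(seg_rp.min()), int(seg_rp.max())))
            start = stop
    return out


# ---------------------------------------------------------------------------
# read mapping


def _ungapped_fast_path(read_codes, ref_codes, diag, scoring):
    """Exact result without DP when the read places with ≤1 mismatch.

    Any alignment containing a gap scores at most ``match·L + gap_open +
    gap_extend`` (= 2L − 7 under defaults), while an ungapped placement with
    ≤1 mismatch scores ≥ 2L − 5, so the gapless optimum is the global local
    optimum at this locus and the DP can be skipped without changing scores.
    """
    L = read_codes.size
    if diag < 0 or diag + L > ref_codes.size:
        return None
    window = ref_codes[diag:diag + L]
    mism = np.nonzero(read_codes != window)[0]
    if mism.size > 1:
        return None
    if mism.size == 1 and (scoring.mismatch - scoring.match
                           <= scoring.gap_open + scoring.gap_extend):
        return None  # unusual scoring where a gap is cheaper than a mismatch
    m, x = scoring.match, scoring.mismatch
    if mism.size == 0:
        return (m * L, 0, L, diag, diag + L, [("M", L)], L, L)
    p = int(mism[0])
    full = m * L + x - m
    pre = m * p
    post = m * (L - p - 1)
    best = max(full, pre, post)
    if best == full:
        return (full, 0, L, diag, diag + L, [("M", L)], L - 1, L)
    if best == pre and pre >= post:
        return (pre, 0, p, diag, diag + p, [("M", p)], p, p) if p else None
    q0 = p + 1
    return (post, q0, L, diag + q0, diag + L, [("M", L - q0)], L - q0, L - q0)


def _extend_candidate(read_codes, ref_codes, diag, read_len, band, scoring):
    w_lo = max(diag - band, 0)
    w_hi = min(diag + read_len + band, ref_codes.size)
    if w_hi <= w_lo:
        return None
    window = ref_codes[w_lo:w_hi]
    score, bi, bj, ph, pe, pf = _kernels.sw_affine(
        read_codes, window, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    if score <= 0:
        return None
    ai, aj, cigar, n_match, aln_len = _traceback(read_codes, window, bi, bj, ph, pe, pf)
    return int(score), ai, bi, w_lo + aj, w_lo + bj, cigar, n_match, aln_len


def map_read(index: KmerIndex, read: str, *, read_id: str = "read",
             min_chain_seeds: int = 2, band: int = 50,
             scoring: Scoring = DEFAULT_SCORING,
             secondary_frac: float | None = None,
             max_candidates: int = 64) -> list[AlignmentRecord]:
    """Map one read: seed, chain co-diagonal seeds, banded extension.

    Returns the best-scoring placement at every locus tying the maximum score
    (sorted by (ref_name, ref_start)); ``n_equal_best_hits`` is the tie count
    and mapq is 0 whenever it exceeds 1. Unaligned read ends are reported as
    soft clips. With ``secondary_frac`` set, near-best placements scoring at
    least ``secondary_frac * best`` are appended as secondary records (mapq 0);
    the default leaves them unreported.
    """
    if len(read) < index.k:
        raise ParameterError("read shorter than index k")
    placements = {}  # (ref_id, approx_start) -> (score, strand, aln fields)
    for strand in "+-":
        oriented = read if strand == "+" else revcomp(read)
        rc = encode(oriented)
        q_pos, ref_ids, ref_pos = index.lookup(rc)
        clusters = _cluster_candidates(q_pos, ref_ids, ref_pos, band)
        clusters = [c for c in clusters if c[2] >= min_chain_seeds]
        clusters.sort(key=lambda c: -c[2])
        for ri, diag, _n, _lo, _hi in clusters[:max_candidates]:
            ref_codes = index.codes[index.names[ri]]
            ext = _ungapped_fast_path(rc, ref_codes, diag, scoring)
            if ext is None:
                ext = _extend_candidate(rc, ref_codes, diag, len(read), band, scoring)
            if ext is None:
                continue
            score, a0, a1, b0, b1, cigar, n_match, aln_len = ext
            key = (ri, b0 // 32)  # collapse duplicate clusters at one locus
            prev = placements.get(key)
            if prev is None or score > prev[0]:
                placements[key] = (score, strand, oriented, ri, a0, a1, b0, b1,
                                   cigar, n_match, aln_len)
    if not placements:
        return []
    entries = list(placements.values())
    best = max(e[0] for e in entries)
    keep = [e for e in entries if e[0] == best]
    if secondary_frac is not None:
        thresh = secondary_frac * best
        secondaries = [e for e in entries if e[0] < best and e[0] >= thresh]
    else:
        secondaries = []
    n_best = len(keep)
    records = []
    for is_sec, group in ((False, keep), (True, secondaries)):
        for score, strand, oriented, ri, a0, a1, b0, b1, cigar, n_match, aln_len in group:
            full = list(cigar)
            if a0 > 0:
                full.insert(0, ("S", a0))
            if a1 < len(read):
                full.append(("S", len(read) - a1))
            records.append(AlignmentRecord(
                read_id=read_id, ref_name=index.names[ri], ref_start=b0,
                strand=strand, cigar=full, score=score,
                identity=n_match / aln_len if aln_len else 0.0,
                n_equal_best_hits=n_best,
                mapq=40 if (n_best == 1 and not is_sec) else 0,
                seq=oriented, is_secondary=is_sec,
            ))
    records.sort(key=lambda r: (r.is_secondary, r.ref_name, r.ref_start))
    return records


# ---------------------------------------------------------------------------
# BLAST-like local search


def local_search(index: KmerIndex, query: str, min_score: int, *,
                 query_id: str = "query", band: int = 60,
                 scoring: Scoring = DEFAULT_SCORING,
                 max_candidates: int = 4096) -> list[SearchHit]:
    """Seed-extend-merge similarity search of ``query`` against the index.

    Hits report identity over alignment columns and the column count
    (``aln_length``); sorted by score descending, ties broken by
    (ref_name, ref_start). Monotone: raising ``min_score`` can only shrink
    the hit list.
    """
    if len(query) < index.k:
        raise ParameterError("query shorter than index k")
    hits: list[SearchHit] = []
    for strand in "+-":
        oriented = query if strand == "+" else revcomp(query)
        qc = encode(oriented)
        q_pos, ref_ids, ref_pos = index.lookup(qc)
        clusters = _cluster_candidates(q_pos, ref_ids, ref_pos, band)
        clusters.sort(key=lambda c: -c[2])
        for ri, diag, _n, _lo, _hi in clusters[:max_candidates]:
            ref_codes = index.codes[index.names[ri]]
            ext = _extend_candidate(qc, ref_codes, diag, len(query), band, scoring)
            if ext is None:
                continue
            score, a0, a1, b0, b1, cigar, n_match, aln_len = ext
            if score < min_score:
                continue
            qs, qe = (a0, a1) if strand == "+" else (len(query) - a1, len(query) - a0)
            hits.append(SearchHit(
                query_id=query_id, ref_name=index.names[ri],
                ref_start=b0, ref_end=b1, q_start=qs, q_end=qe, strand=strand,
                identity=n_match / aln_len if aln_len else 0.0,
                aln_length=aln_len, score=score,
            ))
    # merge hits at one locus (overlapping ref intervals on the same reference)
    hits.sort(key=lambda h: (h.ref_name, h.ref_start, -h.score))
    merged: list[SearchHit] = []
    for h in hits:
        if merged:
            m = merged[-1]
            if m.ref_name == h.ref_name and h.ref_start < m.ref_end:
                ov = min(m.ref_end, h.ref_end) - h.ref_start
                if ov > 0.5 * min(m.ref_end - m.ref_start, h.ref_end - h.ref_start):
                    if h.score > m.score:
                        merged[-1] = h
                    continue
        merged.append(h)
    merged.sort()
    return merged


# ---------------------------------------------------------------------------
# SAM output


def sam_header(references: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in references.items()],
    })


def _to_segment(rec: AlignmentRecord, header: pysam.AlignmentHeader,
                qual: str | None = None) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_id
    flag = 0
    if rec.strand == "-":
        flag |= 16
    if rec.is_secondary:
        flag |= 256
    if rec.is_paired:
        flag |= 1
        flag |= 64 if rec.is_read1 else 128
        if rec.mate_strand == "-":
            flag |= 32
        if rec.mate_unmapped:
            flag |= 8
    seg.flag = flag
    seg.reference_id = header.get_tid(rec.ref_name)
    seg.reference_start = rec.ref_start
    seg.mapping_quality = rec.mapq
    seg.cigartuples = [(_OP_CODES[op], n) for op, n in rec.cigar]
    seg.query_sequence = rec.seq
    if qual is not None:
        seg.query_qualities = pysam.qualitystring_to_array(qual)
    if rec.is_paired and rec.mate_ref is not None:
        seg.next_reference_id = header.get_tid(rec.mate_ref)
        seg.next_reference_start = rec.mate_pos
    seg.set_tag("NH", rec.n_equal_best_hits)
    seg.set_tag("AS", rec.score)
    return seg


def write_sam(path, records: Iterable[AlignmentRecord],
              references: dict[str, str]) -> None:
    """Write records as SAM (text). @SQ lines come from the reference set;
    soft clips are S ops and the NH tag carries the equal-best hit count."""
    header = sam_header(references)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(_to_segment(rec, header))
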