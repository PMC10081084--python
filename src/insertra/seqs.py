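"""Low-level sequence utilities: encoding, reverse complement, seeded RNG fan-out,
and plain-text IO helpers (FASTA / FASTQ / BED / JSON).

Coordinates are 0-based half-open everywhere in memory; BED output keeps that
convention and SAM output (see :mod:`insertra.align_core`) is 1-based.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# uint8 byte value -> 2-bit code (A=0, C=1, G=2, T=3); 255 marks non-ACGT
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 array of 2-bit codes. Raises on non-ACGT characters."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains characters outside A/C/G/T")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def child_seed(seed: int, *labels) -> int:
    """Derive a per-operation seed from a top-level seed.

    Deterministic scheme: SHA-256 of ``seed`` plus the string labels, reduced
    mod 2**31. Every stochastic operation in the package draws its own child
    seed this way, so one pipeline seed reproduces every artifact.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for lab in labels:
        h.update(b"/")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def child_rng(seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *labels))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-base substitutions at ``rate``; the replacement base is
    drawn uniformly from the three alternatives."""
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes[hit] = (codes[hit] + shift) % 4
    return decode(codes)


def scrub_motif(seq: str, motif: str, protect: Sequence[int] = (),
                rng: np.random.Generator | None = None) -> str:
    """Destroy every occurrence of ``motif`` except those starting at positions
    in ``protect``, by substituting the middle base. Deterministic if rng is None."""
    protected = set(int(p) for p in protect)
    s = list(seq)
    mid = len(motif) // 2
    start = 0
    text = seq
    while True:
        i = text.find(motif, start)
        if i < 0:
            break
        if i not in protected:
            old = s[i + mid]
            alts = [b for b in ALPHABET if b != old]
            s[i + mid] = alts[0] if rng is None else alts[int(rng.integers(0, 3))]
            text = "".join(s)
            start = i  # re-scan: the edit may have created no new site here
        else:
            start = i + 1
    return "".join(s)


def count_occurrences(genome: dict[str, str] | str, pattern: str,
                      both_strands: bool = True) -> int:
    """Exhaustive (overlap-aware) substring count over one or more sequences."""
    seqs = [genome] if isinstance(genome, str) else list(genome.values())
    pats = [pattern]
    rc = revcomp(pattern)
    if both_strands and rc != pattern:
        pats.append(rc)
    total = 0
    for s in seqs:
        for p in pats:
            start = 0
            while True:
                i = s.find(p, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


# ---------------------------------------------------------------------------
# plain-text IO


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in items),
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """reads: iterable of (id, sequence, quality string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """intervals: (chrom, start, end, name[, extra...]); 0-based half-open."""
    df = pd.DataFrame(list(intervals))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", header=None)
    out = []
    for row in df.itertuples(index=False):
        row = list(row)
        row[1] = int(row[1])
        row[2] = int(row[2])
        out.append(tuple(row))
    return out


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
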