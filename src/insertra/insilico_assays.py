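"""Deterministic emulations of the molecular assays used to characterize the
insertion: restriction digestion with Southern-probe fragment prediction,
inverse PCR across the construct junctions, and k-mer dot plots.

Enzymes are modeled as ``(motif, cut_offset)`` pairs; DraI (TTT^AAA) and ScaI
(AGT^ACT) ship as named presets. Non-palindromic motifs are searched on both
strands (the reverse-strand cut lands at ``occurrence + len(motif) - offset``);
the shipped presets are palindromic so each site yields one cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field


from .align_core import KmerIndex, local_search
from .errors import AssayFailureError, ParameterError, PrimerError
from .seqs import revcomp
from .synthetic_data import TSD_MOTIF, TransgeneConstruct

ENZYMES: dict[str, tuple[str, int]] = {
    "DraI": ("TTTAAA", 3),
    "ScaI": ("AGTACT", 3),
}


@dataclass
class FragmentPrediction:
    source_ref: str
    fragments: list[tuple[int, int, int]]  # (start, end, length); end may wrap if circular
    sequences: list[str]
    circular: bool = False
    probe_positive: list[int] = field(default_factory=list)  # fragment indices

    @property
    def lengths(self) -> list[int]:
        return [f[2] for f in self.fragments]


@dataclass
class Amplicon:
    sequence: str
    primer_pair: tuple[str, str]
    template_description: str


def _cut_positions(sequence: str, recognition_sites) -> list[int]:
    cuts = set()
    for motif, offset in recognition_sites:
        if not motif or not 0 <= offset <= len(motif):
            raise ParameterError(f"bad recognition site {(motif, offset)!r}")
        rc = revcomp(motif)
        start = 0
        while True:
            i = sequence.find(motif, start)
            if i < 0:
                break
            cuts.add(i + offset)
            start = i + 1
        if rc != motif:
            start = 0
            while True:
                i = sequence.find(rc, start)
                if i < 0:
                    break
                cuts.add(i + len(motif) - offset)
                start = i + 1
    return sorted(c for c in cuts if 0 < c < len(sequence))


def digest(sequence: str, recognition_sites, circular: bool = False,
           source_ref: str = "template") -> FragmentPrediction:
    """Cut at every recognition-site occurrence; fragments returned 5'→3'.

    No sites on a linear molecule → a single fragment equal to the input.
    A circular molecule with one site → one linear fragment of full length.
    Fragment lengths always sum to the template length (conservation), and for
    a linear template concatenating the fragments in order restores it.
    """
    L = len(sequence)
    cuts = _cut_positions(sequence, recognition_sites)
    if not cuts:
        return FragmentPrediction(source_ref, [(0, L, L)], [sequence], circular)
    frags: list[tuple[int, int, int]] = []
    seqs: list[str] = []
    if circular:
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + L]):
            b_mod = b % L if b != L else L
            frags.append((a, b_mod, b - a))
            seqs.append(sequence[a:] + sequence[:b_mod] if b > L else sequence[a:b])
    else:
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            frags.append((a, b, b - a))
            seqs.append(sequence[a:b])
    return FragmentPrediction(source_ref, frags, seqs, circular)


def southern_probe_fragments(prediction: FragmentPrediction, probe: str,
                             min_overlap: int = 100, min_identity: float = 0.90,
                             k: int = 15) -> list[int]:
    """Sizes of probe-positive fragments, sorted ascending.

    A fragment is positive when the probe aligns to it over ≥ ``min_overlap``
    columns at ≥ ``min_identity`` (exact containment short-circuits the
    alignment). With a construct-unique probe, the positive count equals the
    number of insertions carried by the digested molecule. Fragment indices
    are also recorded on ``prediction.probe_positive``.
    """
    if len(probe) < min_overlap:
        raise ParameterError("probe shorter than min_overlap")
    probe_rc = revcomp(probe)
    positive: list[int] = []
    for i, frag in enumerate(prediction.sequences):
        if probe in frag or probe_rc in frag:
            positive.append(i)
            continue
        if len(frag) < k:
            continue
        hits = local_search(KmerIndex({"frag": frag}, k=k), probe,
                            min_score=min_overlap)
        if any(h.aln_length >= min_overlap and h.identity >= min_identity
               for h in hits):
            positive.append(i)
    prediction.probe_positive = positive
    return sorted(prediction.fragments[i][2] for i in positive)


# ---------------------------------------------------------------------------
# inverse PCR


def _find_once(template: str, pattern: str) -> int:
    i = template.find(pattern)
    if i < 0:
        return -1
    if template.find(pattern, i + 1) >= 0:
        return -2
    return i


def inverse_pcr(haplotype_seq: str, enzyme: tuple[str, int], fwd_primer: str,
                rev_primer: str, max_product: int = 10_000,
                description: str = "inverse PCR") -> Amplicon:
    """Digest → self-circularize the boundary fragment → amplify outward.

    The relevant fragment is the unique digestion fragment carrying both
    primers; it is circularized and the amplicon is the circular path from the
    forward primer through the fragment junction to the reverse primer binding
    site. The product therefore spans the genomic flank adjacent to the
    construct end the primers face. Products longer than ``max_product`` fail
    the assay (a real PCR would not amplify them).
    """
    pred = digest(haplotype_seq, [enzyme])
    carriers = []
    for i, frag in enumerate(pred.sequences):
        if fwd_primer in frag or revcomp(fwd_primer) in frag:
            carriers.append(i)
    if len(carriers) != 1:
        raise PrimerError(
            f"forward primer found on {len(carriers)} fragments (need exactly 1)")
    frag = pred.sequences[carriers[0]]
    template = frag if fwd_primer in frag else revcomp(frag)
    p = _find_once(template, fwd_primer)
    if p < 0:
        raise PrimerError("forward primer not unique on the boundary fragment")
    rc_rev = revcomp(rev_primer)
    if _find_once(template, rc_rev) == -2:
        raise PrimerError("reverse primer not unique on the boundary fragment")
    doubled = template + template
    q = doubled.find(rc_rev, p + len(fwd_primer))
    if q < 0 or q >= p + len(template):
        raise PrimerError("reverse primer absent from the boundary fragment")
    product = doubled[p:q + len(rc_rev)]
    if len(product) > max_product:
        raise AssayFailureError(
            f"amplicon of {len(product)} bp exceeds the {max_product} bp PCR limit")
    return Amplicon(product, (fwd_primer, rev_primer), description)


def extract_genomic_flank(amplicon: Amplicon, construct: TransgeneConstruct,
                          side: str, enzyme: tuple[str, int] | None = None) -> str:
    """Genomic portion of an inverse-PCR product, in reference orientation.

    For the 5' junction the returned flank *ends* with the TSD motif
    (…genomic…TTAA abutting itr5); for the 3' junction it *begins* with it.
    The construct-derived piece at the far end of the circularized product is
    delimited exactly by the enzyme's cut position inside the construct (the
    circularization junction), so the split is unambiguous even though the
    two cut ends share motif bases.
    """
    enzyme = enzyme or ENZYMES["DraI"]
    full = construct.full_sequence
    cuts = _cut_positions(full, [enzyme])
    if side == "5prime":
        pattern = TSD_MOTIF + full[:16]
    elif side == "3prime":
        pattern = full[-16:] + TSD_MOTIF
    else:
        raise ParameterError("side must be 5prime|3prime")
    seq = amplicon.sequence
    if pattern not in seq:
        seq = revcomp(seq)
        if pattern not in seq:
            raise AssayFailureError(f"no {side} junction pattern in amplicon")
    j = seq.index(pattern)
    if side == "5prime":
        # layout: [construct piece ending at a construct cut][genomic…TTAA][itr5…]
        start = full.find(seq[:24])
        if start < 0:
            raise AssayFailureError("amplicon does not begin inside the construct")
        after = [c for c in cuts if c > start]
        if not after:
            raise AssayFailureError("no enzyme cut downstream of the reverse primer")
        return seq[after[0] - start:j + 4]
    # layout: […itr3][TTAA…genomic][construct piece starting at a construct cut]
    end_anchor = seq[-24:]
    i = full.find(end_anchor)
    if i < 0:
        raise AssayFailureError("amplicon does not end inside the construct")
    end = i + 24
    before = [c for c in cuts if c < end]
    if not before:
        raise AssayFailureError("no enzyme cut upstream of the reverse primer")
    piece_len = end - before[-1]
    return seq[j + 16:len(seq) - piece_len]


def recover_flanks(haplotype_seq: str, construct: TransgeneConstruct,
                   enzyme: tuple[str, int] | None = None,
                   max_product: int = 10_000) -> tuple[str, str]:
    """Run both junction inverse PCRs and return (flank5, flank3).

    flank5 ends with the TSD; flank3 begins with it. Primers come from the
    construct's designed primer set (outward-facing, near each ITR).
    """
    enzyme = enzyme or ENZYMES["DraI"]
    a5 = inverse_pcr(haplotype_seq, enzyme, construct.primers["pB5_fwd"],
                     construct.primers["pB5_rev"], max_product, "5prime junction")
    a3 = inverse_pcr(haplotype_seq, enzyme, construct.primers["pB3_fwd"],
                     construct.primers["pB3_rev"], max_product, "3prime junction")
    return (extract_genomic_flank(a5, construct, "5prime"),
            extract_genomic_flank(a3, construct, "3prime"))


def combined_flank_query(flank5: str, flank3: str) -> str:
    """Reconstruct the pre-insertion locus sequence: 5' flank (with its
    terminal TSD) followed by the 3' flank minus its leading TSD copy."""
    if not flank5.endswith(TSD_MOTIF) or not flank3.startswith(TSD_MOTIF):
        raise ParameterError("flanks do not carry junction TSD copies")
    return flank5 + flank3[4:]


# ---------------------------------------------------------------------------
# dot plot


def dotplot_matrix(seq_a: str, seq_b: str, k: int = 15) -> list[tuple[int, int, str]]:
    """Every exact shared k-mer between two sequences, both orientations.

    Returns (pos_a, pos_b, strand) triples; strand '-' means
    ``seq_a[pos_a:pos_a+k] == revcomp(seq_b[pos_b:pos_b+k])``. The dot plot of
    A vs B is the transpose of B vs A.
    """
    if k < 11:
        raise ParameterError("k must be >= 11")
    from collections import defaultdict
    pos_b: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq_b) - k + 1):
        pos_b[seq_b[j:j + k]].append(j)
    out: list[tuple[int, int, str]] = []
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i:i + k]
        for j in pos_b.get(kmer, ()):
            out.append((i, j, "+"))
        rc = revcomp(kmer)
        for j in pos_b.get(rc, ()):
            out.append((i, j, "-"))
    return out


def dotplot_to_tsv(matches, path) -> None:
    import pandas as pd
    pd.DataFrame(matches, columns=["pos_a", "pos_b", "strand"]).to_csv(
        path, sep="\t", index=False)


def plot_dotplot(matches, path, title: str = "dot plot") -> None:
    """Render matches as a scatter image (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fwd = [(a, b) for a, b, s in matches if s == "+"]
    rev = [(a, b) for a, b, s in matches if s == "-"]
    fig, ax = plt.subplots(figsize=(6, 6))
    if fwd:
        ax.scatter(*zip(*fwd), s=1, c="tab:blue", label="+")
    if rev:
        ax.scatter(*zip(*rev), s=1, c="tab:red", label="-")
    ax.set_xlabel("sequence A position")
    ax.set_ylabel("sequence B position")
    ax.set_title(title)
    ax.legend(markerscale=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
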