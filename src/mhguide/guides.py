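"""CRISPR guide enumeration for MMEJ deletion recreation.

Guides are selected so that the blunt double-strand break falls between
the two microhomology copies: the cut must lie within the deleted segment,
outside the first 3 bp of the inner µH copy (so at least 3 bp of µH is
retained on either side of the break), and within 50 bp of at least one µH
copy so that the heterology resected before annealing stays short.  For
large deletions the 50 bp rule still admits one candidate near each copy,
from which a two-cut experiment can be assembled.

SpCas9 recognizes an NGG PAM and cuts bluntly 3 bp upstream of it; xCas9
(PAMs NGN, GAA, GAT) is treated as cutting at the same offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

from .io_formats import GenomeSequence, revcomp
from .microhomology import CanonicalVariant, FlankConfig

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SPCAS9_PAMS = ("NGG",)
XCAS9_PAMS = ("NGN", "GAA", "GAT")


@dataclass(frozen=True)
class PamMotif:
    """A PAM with its blunt-cut geometry.

    ``cut_offset`` is the (negative) distance from the motif start to the
    cut on the protospacer side: for NGG-class nucleases the cut falls 3 bp
    upstream of the PAM, i.e. ``cut_offset = -3``.
    """

    motif: str
    cut_offset: int = -3
    protospacer_len: int = 20

    def __post_init__(self):
        bad = set(self.motif) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in PAM motif: {bad}")

    def __len__(self) -> int:
        return len(self.motif)


def iupac_match(seq: str, motif: str) -> bool:
    """Exact IUPAC match; N in the genome matches nothing."""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC[m] and b != "N" for b, m in zip(seq, motif))


def expand_iupac(motif: str) -> List[str]:
    """All concrete ACGT words matching an IUPAC motif."""
    words = [""]
    for m in motif:
        words = [w + b for w in words for b in IUPAC[m]]
    return words


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM whose cut could recreate the deletion via MMEJ.

    ``cut_pos`` is a 0-based inter-base coordinate (the break sits between
    genome positions ``cut_pos - 1`` and ``cut_pos``).  ``dist_left`` /
    ``dist_right`` count the intervening bases between the cut and the
    left/right µH copy span (0 when the cut is inside or adjacent).
    Off-target fields are filled in by :mod:`mhguide.offtarget`, nested-µH
    fields by :mod:`mhguide.nested`.
    """

    variant_id: str
    chrom: str
    protospacer: str
    pam: str
    motif: str
    strand: str
    pam_start: int
    cut_pos: int
    dist_left: int
    dist_right: int
    valid: bool
    offtarget_count: int = -1
    is_unique: bool = False
    nested_count: int = -1
    nested_strength: float = 0.0
    nested_strength_sum: float = 0.0

    @property
    def guide_id(self) -> str:
        return f"{self.variant_id}:{self.cut_pos}{self.strand}"

    @property
    def word(self) -> str:
        """Protospacer+PAM as a single strand-oriented word."""
        return self.protospacer + self.pam


def scan_pams(
    genome: GenomeSequence,
    chrom: str,
    window: Tuple[int, int],
    motifs: Sequence[PamMotif],
) -> Iterator[Tuple[PamMotif, str, int]]:
    """Find all PAM occurrences on both strands within a window.

    Yields ``(motif, strand, pam_start)``.  Minus-strand hits are located
    by matching the reverse-complement of the motif on the plus strand;
    ``pam_start`` is always the plus-strand start of the matched word.
    The window is clipped to the contig.
    """
    seq, w_start = genome.fetch_clipped(chrom, window[0], window[1])
    for motif in motifs:
        m = len(motif)
        rc_motif = revcomp(motif.motif)
        for i in range(len(seq) - m + 1):
            word = seq[i:i + m]
            if iupac_match(word, motif.motif):
                yield motif, "+", w_start + i
            if iupac_match(word, rc_motif):
                yield motif, "-", w_start + i


def cut_position(motif: PamMotif, strand: str, pam_start: int) -> int:
    """Inter-base cut coordinate for a PAM occurrence.

    On the plus strand the cut is ``|cut_offset|`` bp upstream of the PAM
    (between protospacer positions 17 and 18 for SpCas9).  On the minus
    strand the PAM was matched as its reverse complement on the plus
    strand at ``pam_start``, so the cut mirrors to
    ``pam_start + |motif| + |cut_offset|``.
    """
    if strand == "+":
        return pam_start + motif.cut_offset
    return pam_start + len(motif) - motif.cut_offset


def _guide_sequences(
    genome: GenomeSequence,
    chrom: str,
    motif: PamMotif,
    strand: str,
    pam_start: int,
) -> Tuple[str, str] | None:
    """(protospacer, pam) oriented 5'->3' on the guide strand; None if off-contig."""
    m, plen = len(motif), motif.protospacer_len
    try:
        if strand == "+":
            protospacer = genome.fetch(chrom, pam_start - plen, pam_start)
            pam = genome.fetch(chrom, pam_start, pam_start + m)
        else:
            pam = revcomp(genome.fetch(chrom, pam_start, pam_start + m))
            protospacer = revcomp(genome.fetch(chrom, pam_start + m, pam_start + m + plen))
    except IndexError:
        return None
    if "N" in protospacer or "N" in pam:
        return None
    return protospacer, pam


def mh_copy_spans(canon: CanonicalVariant) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Genomic spans of the (left copy, right copy) of the selected µH."""
    var, mh = canon.variant, canon.best_mh
    s, e, L = var.start, var.end, mh.mhL
    if mh.config is FlankConfig.OUTER_RIGHT:
        return (s, s + L), (e, e + L)       # inner copy at 5' end, outer downstream
    return (s - L, s), (e - L, e)           # outer copy upstream, inner at 3' end


def _span_distance(cut: int, span: Tuple[int, int]) -> int:
    """Intervening bases between an inter-base cut and a copy span."""
    a, b = span
    if cut < a:
        return a - cut
    if cut > b:
        return cut - b
    return 0


def allowed_cut_interval(canon: CanonicalVariant) -> Tuple[int, int]:
    """Inclusive inter-base cut interval preserving ≥3 bp of µH at the break.

    The first 3 bp of the inner µH copy (junction-proximal) are protected;
    with a µH shorter than 3 bp the whole inner copy is protected.  The cut
    may fall anywhere else within the deleted segment, boundary included.
    """
    var, mh = canon.variant, canon.best_mh
    s, e = var.start, var.end
    protected = min(3, mh.mhL)
    if mh.config is FlankConfig.OUTER_RIGHT:
        return s + protected, e
    return s, e - protected


def enumerate_guides(
    genome: GenomeSequence,
    canon: CanonicalVariant,
    motifs: Sequence[PamMotif] = (PamMotif("NGG"),),
    max_cut_dist: int = 50,
    require_both_within: bool = False,
    restrict_near_mh: bool = False,
) -> List[GuideCandidate]:
    """All PAM-bearing cut sites inside the deletion, flagged for validity.

    Every candidate whose cut lies within the deleted segment (boundaries
    included) is returned; ``valid`` marks those that also respect the
    protected 3 bp of inner µH and the ``max_cut_dist`` rule.  Candidates
    whose protospacer would run off the contig are dropped.

    With ``restrict_near_mh`` (used for very long deletions) only the
    neighbourhood within ``max_cut_dist`` of each µH copy is scanned, so
    interior candidates — which could never be valid — are not enumerated.
    """
    var = canon.variant
    s, e = var.start, var.end
    max_reach = max(len(m) + m.protospacer_len for m in motifs) + abs(
        max(m.cut_offset for m in motifs)) + 1
    lo, hi = allowed_cut_interval(canon)
    left_span, right_span = mh_copy_spans(canon)
    if restrict_near_mh:
        windows = [
            (left_span[0] - max_cut_dist - max_reach, left_span[1] + max_cut_dist + max_reach),
            (right_span[0] - max_cut_dist - max_reach, right_span[1] + max_cut_dist + max_reach),
        ]
    else:
        windows = [(s - max_reach, e + max_reach)]

    hits = []
    seen = set()
    for window in windows:
        for hit in scan_pams(genome, var.chrom, window, motifs):
            key = (hit[0].motif, hit[1], hit[2])
            if key not in seen:
                seen.add(key)
                hits.append(hit)

    out: List[GuideCandidate] = []
    for motif, strand, pam_start in hits:
        cut = cut_position(motif, strand, pam_start)
        if cut < s or cut > e:
            continue  # cut must fall within the variant sequence
        seqs = _guide_sequences(genome, var.chrom, motif, strand, pam_start)
        if seqs is None:
            continue
        protospacer, pam = seqs
        d_left = _span_distance(cut, left_span)
        d_right = _span_distance(cut, right_span)
        within = (max(d_left, d_right) if require_both_within
                  else min(d_left, d_right)) <= max_cut_dist
        valid = lo <= cut <= hi and within
        out.append(GuideCandidate(
            variant_id=var.id, chrom=var.chrom,
            protospacer=protospacer, pam=pam, motif=motif.motif,
            strand=strand, pam_start=pam_start, cut_pos=cut,
            dist_left=d_left, dist_right=d_right, valid=valid,
        ))
    out.sort(key=lambda g: (g.cut_pos, g.strand, g.motif, g.pam_start))
    return out
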