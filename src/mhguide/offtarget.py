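"""Exact (0-mismatch) genome-wide occurrence counting of guide words.

A guide is usable only if its protospacer+PAM word occurs at exactly one
position in the genome over both strands; any additional exact occurrence
is a perfect off-target.  Counting is done with a fixed-length word index
built once per genome: every position on the plus strand and every
position on the minus strand contributes one word, words containing N are
skipped, and a palindromic word is counted once per strand occurrence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence

from .io_formats import GenomeSequence, revcomp
from .guides import GuideCandidate, PamMotif, expand_iupac


@dataclass
class KmerIndex:
    """Exact-occurrence counts of all L-mers over both genome strands."""

    L: int
    counts: Counter

    def count(self, word: str) -> int:
        return self.counts.get(word, 0)


def build_index(genome: GenomeSequence, L: int) -> KmerIndex:
    """Index every L-long word of both strands of the genome."""
    if L < 1:
        raise ValueError("word length must be >= 1")
    counts: Counter = Counter()
    for chrom, clen in genome.contigs.items():
        seq = genome.fetch(chrom, 0, clen)
        rc = revcomp(seq)
        for strand_seq in (seq, rc):
            for i in range(len(strand_seq) - L + 1):
                word = strand_seq[i:i + L]
                if "N" not in word:
                    counts[word] += 1
    return KmerIndex(L, counts)


def count_occurrences(
    index: KmerIndex,
    protospacer: str,
    pam: str,
    motif: str,
    expand_pam: bool = True,
) -> int:
    """Genome-wide exact occurrences of a protospacer+PAM word.

    With ``expand_pam`` every concrete realization of the motif's ambiguous
    positions is summed (any NGG licenses cleavage at the protospacer);
    without it only the literal observed word is counted.  The guide is
    unique iff the total is 1 — its own genomic site.
    """
    if len(protospacer) + len(motif) != index.L:
        raise ValueError(
            f"word length {len(protospacer) + len(motif)} does not match index L={index.L}")
    if expand_pam:
        return sum(index.count(protospacer + p) for p in expand_iupac(motif))
    return index.count(protospacer + pam)


def annotate_offtargets(
    guides: Sequence[GuideCandidate],
    index: KmerIndex,
    expand_pam: bool = True,
) -> List[GuideCandidate]:
    """Fill ``offtarget_count`` / ``is_unique`` on a list of guide candidates."""
    from dataclasses import replace

    out = []
    for g in guides:
        c = count_occurrences(index, g.protospacer, g.pam, g.motif, expand_pam)
        out.append(replace(g, offtarget_count=c, is_unique=(c == 1)))
    return out


def index_length(motifs: Sequence[PamMotif]) -> int:
    """Word length for a motif set; motifs must agree on total length."""
    lengths = {len(m) + m.protospacer_len for m in motifs}
    if len(lengths) != 1:
        raise ValueError("all PAM motifs must yield the same word length for one index")
    return lengths.pop()
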