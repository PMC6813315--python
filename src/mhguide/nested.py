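"""Nested microhomologies: competing MMEJ outcomes inside the deletion.

After a cut, MMEJ can anneal any pair of exact repeats with one copy on
each side of the break.  Repeat pairs lying between the two target µH
copies whose mutual gap is smaller than the target heterology are
preferred competitors (shorter intervening sequence anneals first), so
they are detected and scored for every candidate cut.  A nested µH must
be an exact repeat of at least 3 bp.

The strength of a competitor follows the microhomology pattern score used
for repair-outcome ranking: ``100 * exp(-del_len/20) * (2*n_GC + n_AT)``,
where ``del_len`` is the deletion the competitor would create (its gap
plus its length) — longer resections decay exponentially, GC pairs anneal
more stably and count double.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .io_formats import GenomeSequence
from .microhomology import CanonicalVariant, FlankConfig
from .guides import GuideCandidate, mh_copy_spans


@dataclass(frozen=True)
class NestedMH:
    """A pair of identical exact repeats straddling a cut.

    Spans are genomic, half-open; ``gap`` counts the bases between the two
    copies; ``pattern_score`` ranks the competing repair outcome.
    """

    left_span: Tuple[int, int]
    right_span: Tuple[int, int]
    seq: str
    gap: int
    pattern_score: float

    @property
    def length(self) -> int:
        return self.left_span[1] - self.left_span[0]


def pattern_score(mh_seq: str, resulting_del_len: int) -> float:
    """Microhomology pattern score: length-decayed, GC-weighted."""
    n_gc = sum(b in "GC" for b in mh_seq)
    n_at = sum(b in "AT" for b in mh_seq)
    return 100.0 * math.exp(-resulting_del_len / 20.0) * (2 * n_gc + n_at)


def _pair_valid(seq: str, a1: int, a2: int, length: int) -> bool:
    if length < 1 or a1 < 0 or a2 + length > len(seq) or a1 + length > a2:
        return False
    return seq[a1:a1 + length] == seq[a2:a2 + length] and "N" not in seq[a1:a1 + length]

def maximal_repeat_pairs(seq: str, min_len: int) -> List[Tuple[int, int, int]]:
    """All maximal exact repeat pairs ``(a1, a2, length)`` in a sequence.

    A pair is two non-overlapping identical substrings; it is maximal when
    neither extending one base leftward nor one base rightward yields
    another valid (identical, non-overlapping, in-bounds) pair.  Copies
    abutted inside a tandem run are therefore reported even though the
    underlying match run continues.
    """
    out = []
    L = len(seq)
    for a1 in range(L):
        for a2 in range(a1 + min_len, L):
            # longest common extension on this offset pair
            k = 0
            while a2 + k < L and seq[a1 + k] == seq[a2 + k] and seq[a1 + k] != "N":
                k += 1
            length = min(k, a2 - a1)  # cap so copies never overlap
            if length < min_len:
                continue
            if not _pair_valid(seq, a1, a2, length):
                continue
            ext_left = _pair_valid(seq, a1 - 1, a2 - 1, length + 1)
            ext_right = _pair_valid(seq, a1, a2, length + 1)
            if not ext_left and not ext_right:
                out.append((a1, a2, length))
    return sorted(set(out))


def search_region(canon: CanonicalVariant) -> Tuple[int, int]:
    """Genomic span between the proximal edges of the two target µH copies."""
    (l_a, l_b), (r_a, r_b) = mh_copy_spans(canon)
    return l_b, r_a


def find_nested(
    genome: GenomeSequence,
    canon: CanonicalVariant,
    cut_pos: int,
    min_len: int = 3,
) -> List[NestedMH]:
    """Exact repeat pairs straddling ``cut_pos`` that out-compete the target µH.

    The search is confined to the heterology between the target µH copies;
    one copy must end at or before the cut and the other start at or after
    it, and the pair's gap must be strictly smaller than the target µH
    distance.  With abutted target copies (distance 0) the result is empty
    by definition.
    """
    target_dist = canon.best_mh.dist
    if target_dist <= 0:
        return []
    r0, r1 = search_region(canon)
    seq = genome.fetch(canon.variant.chrom, r0, r1)
    out: List[NestedMH] = []
    for a1, a2, length in maximal_repeat_pairs(seq, min_len):
        g_a1, g_a2 = r0 + a1, r0 + a2
        b1 = g_a1 + length
        if not (b1 <= cut_pos <= g_a2):
            continue
        gap = g_a2 - b1
        if gap >= target_dist:
            continue
        mh_seq = seq[a1:a1 + length]
        out.append(NestedMH(
            left_span=(g_a1, b1),
            right_span=(g_a2, g_a2 + length),
            seq=mh_seq,
            gap=gap,
            pattern_score=pattern_score(mh_seq, gap + length),
        ))
    return out


def summarize_nested(nested: Sequence[NestedMH]) -> Tuple[int, float, float]:
    """(count, strength = max pattern score, auxiliary sum of scores)."""
    if not nested:
        return 0, 0.0, 0.0
    scores = [n.pattern_score for n in nested]
    return len(nested), max(scores), sum(scores)


def annotate_nested(
    genome: GenomeSequence,
    canon: CanonicalVariant,
    guides: Sequence[GuideCandidate],
    min_len: int = 3,
) -> List[GuideCandidate]:
    """Fill nested-µH fields on each guide candidate."""
    out = []
    for g in guides:
        count, strength, total = summarize_nested(
            find_nested(genome, canon, g.cut_pos, min_len))
        out.append(replace(g, nested_count=count, nested_strength=strength,
                           nested_strength_sum=total))
    return out


def variant_nested_summary(
    guides: Sequence[GuideCandidate],
) -> Tuple[int, float, Optional[GuideCandidate]]:
    """Variant-level nested summary: values of the best (fewest-nested) guide.

    Only guides passing all positional and uniqueness filters compete;
    ties break on cut position then strand for determinism.  Returns
    ``(nested_count, nested_strength, best_guide)`` or ``(-1, 0.0, None)``
    when no eligible guide exists.
    """
    eligible = [g for g in guides if g.valid and g.is_unique and g.nested_count >= 0]
    if not eligible:
        return -1, 0.0, None
    best = min(eligible, key=lambda g: (g.nested_count, g.cut_pos, g.strand))
    return best.nested_count, best.nested_strength, best
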