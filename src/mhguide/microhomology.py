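"""Detection, scoring and selection of microhomologies flanking a deletion.

A deletion is MMEJ-compatible when a short identical sequence (a
microhomology, µH) is present at both deletion junctions: one copy inside
the deleted segment and one in the retained flank.  Two alignments are
possible and both are evaluated:

* ``OUTER_RIGHT`` — the 3' flank aligns with the 5' end of the deleted
  sequence; the inner µH copy sits at the deletion's 5' end and the outer
  copy immediately downstream of the deletion.
* ``OUTER_LEFT`` — the 5' flank aligns with the 3' end of the deleted
  sequence; the inner copy sits at the deletion's 3' end and the outer copy
  immediately upstream.

The µH is extended junction-outward as far as possible, absorbing at most
``max_mismatch`` mismatches (default 1), each of which must be preceded by
at least ``anchor_before_mismatch`` consecutive matches and followed by at
least one match.  The µH score is the number of matching bases in the full
µH plus the length of the first exact stretch; the configuration with the
stronger score is selected.

Because the same deletion can be written at several coordinates in a
repeat, deletions are canonicalized by shifting them left and right through
every equivalent representation and keeping the one whose selected µH
scores highest (leftmost on ties).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Tuple

from .io_formats import DeletionVariant, GenomeSequence


class FlankConfig(enum.Enum):
    """Which flank pairs with which end of the deleted sequence."""

    OUTER_LEFT = "outer_left"    # 5' flank ~ 3' end of deletion
    OUTER_RIGHT = "outer_right"  # 3' flank ~ 5' end of deletion


@dataclass(frozen=True)
class MicrohomologyResult:
    """Per-configuration µH metrics.

    ``mhL`` is the full µH length (mismatches included), ``mh1L`` the first
    exact stretch, ``dist`` the heterology between the two copies
    (deletion length minus ``mhL``), and ``mh_seq`` the retained-flank copy
    in genomic 5'->3' orientation.
    """

    config: FlankConfig
    mhL: int
    mh1L: int
    matches: int
    mismatches: int
    score: int
    hom: float
    gc: float
    dist: int
    mh_seq: str

    @property
    def dist_exact(self) -> int:
        """Heterology realized by the first exact stretch alone."""
        return self.dist + (self.mhL - self.mh1L)


def _zero_result(config: FlankConfig, n: int) -> MicrohomologyResult:
    return MicrohomologyResult(config, 0, 0, 0, 0, 0, 0.0, 0.0, n, "")


def extend_microhomology(
    inner_seq: str,
    flank_seq: str,
    max_mismatch: int = 1,
    anchor_before_mismatch: int = 1,
) -> Tuple[int, int, int]:
    """Extend a µH junction-outward; returns ``(mhL, mh1L, matches)``.

    Both sequences are read with position 0 adjacent to the junction.  The
    walk compares position by position; a mismatch is absorbed only while
    fewer than ``max_mismatch`` have been used, at least
    ``anchor_before_mismatch`` consecutive matches immediately precede it,
    and at least one match follows (a trailing mismatch is trimmed).  N
    never matches anything, itself included.  The full µH never exceeds
    ``len(inner_seq)`` so the two copies cannot overlap.
    """
    n = min(len(inner_seq), len(flank_seq))
    if n == 0:
        return 0, 0, 0

    mhL = 0          # end of µH = position after last match
    mh1L: Optional[int] = None
    matches = 0
    matches_in_mh = 0
    used_mismatch = 0
    run = 0          # consecutive matches immediately before current position
    for i in range(n):
        a, b = inner_seq[i], flank_seq[i]
        if a == b and a != "N":
            run += 1
            matches += 1
            mhL = i + 1
            matches_in_mh = matches
        else:
            if mh1L is None:
                mh1L = i
            if used_mismatch < max_mismatch and run >= anchor_before_mismatch:
                used_mismatch += 1
                run = 0
                continue  # absorbed; only counts toward mhL if a match follows
            break
    if mh1L is None:
        mh1L = mhL
    mh1L = min(mh1L, mhL)
    return mhL, mh1L, matches_in_mh


def find_flanking_mh(
    genome: GenomeSequence,
    variant: DeletionVariant,
    max_mismatch: int = 1,
    anchor_before_mismatch: int = 1,
) -> Tuple[MicrohomologyResult, MicrohomologyResult]:
    """Evaluate both flanking configurations for a deletion.

    Returns ``(OUTER_LEFT result, OUTER_RIGHT result)``.  A flank truncated
    by the contig edge simply limits how far that configuration can extend.
    """
    n = variant.n
    s, e = variant.start, variant.end
    deleted = variant.deleted_seq

    # OUTER_RIGHT: deletion prefix vs right flank, walking rightward
    right_flank, _ = genome.fetch_clipped(variant.chrom, e, e + n)
    mhL, mh1L, matches = extend_microhomology(
        deleted, right_flank, max_mismatch, anchor_before_mismatch)
    right = _build_result(FlankConfig.OUTER_RIGHT, genome, variant, mhL, mh1L, matches)

    # OUTER_LEFT: deletion suffix vs left flank, walking leftward
    left_flank, _ = genome.fetch_clipped(variant.chrom, s - n, s)
    mhL, mh1L, matches = extend_microhomology(
        deleted[::-1], left_flank[::-1], max_mismatch, anchor_before_mismatch)
    left = _build_result(FlankConfig.OUTER_LEFT, genome, variant, mhL, mh1L, matches)
    return left, right


def _build_result(
    config: FlankConfig,
    genome: GenomeSequence,
    variant: DeletionVariant,
    mhL: int,
    mh1L: int,
    matches: int,
) -> MicrohomologyResult:
    n = variant.n
    if mhL == 0:
        return _zero_result(config, n)
    if config is FlankConfig.OUTER_RIGHT:
        mh_seq = genome.fetch(variant.chrom, variant.end, variant.end + mhL)
    else:
        mh_seq = genome.fetch(variant.chrom, variant.start - mhL, variant.start)
    gc = sum(b in "GC" for b in mh_seq) / mhL
    mismatches = mhL - matches
    return MicrohomologyResult(
        config=config,
        mhL=mhL,
        mh1L=mh1L,
        matches=matches,
        mismatches=mismatches,
        score=matches + mh1L,
        hom=matches / mhL,
        gc=gc,
        dist=n - mhL,
        mh_seq=mh_seq,
    )


def select_configuration(
    left: MicrohomologyResult,
    right: MicrohomologyResult,
) -> MicrohomologyResult:
    """Pick the configuration with the stronger score.

    Ties break on larger first exact stretch, then OUTER_LEFT — a fixed,
    documented rule so the pipeline is deterministic.
    """
    if right.score > left.score:
        return right
    if right.score == left.score and right.mh1L > left.mh1L:
        return right
    return left


@dataclass(frozen=True)
class CanonicalVariant:
    """A deletion at its canonical (µH-maximizing) coordinates."""

    variant: DeletionVariant
    shift_offset: int
    best_mh: MicrohomologyResult
    left_mh: MicrohomologyResult
    right_mh: MicrohomologyResult

    @property
    def has_mh(self) -> bool:
        return self.best_mh.mhL > 0


def shift_range(genome: GenomeSequence, variant: DeletionVariant) -> Tuple[int, int]:
    """Inclusive range of starts reachable by shifting the deletion.

    A left shift by one is legal while the base before the deletion equals
    the last deleted base; a right shift while the first deleted base
    equals the base after the deletion.  Every representation in the range
    removes the same sequence content.
    """
    seqs = genome
    chrom, n = variant.chrom, variant.n
    lo = variant.start
    while lo > 0 and seqs.fetch(chrom, lo - 1, lo) == seqs.fetch(chrom, lo + n - 1, lo + n):
        lo -= 1
    hi = variant.start
    clen = genome.length(chrom)
    while hi + n < clen and seqs.fetch(chrom, hi, hi + 1) == seqs.fetch(chrom, hi + n, hi + n + 1):
        hi += 1
    return lo, hi


def canonicalize(
    genome: GenomeSequence,
    variant: DeletionVariant,
    max_mismatch: int = 1,
    anchor_before_mismatch: int = 1,
) -> CanonicalVariant:
    """Choose, among equivalent coordinate representations, the one whose
    selected µH scores highest; ties go to the leftmost start.
    """
    lo, hi = shift_range(genome, variant)
    best: Optional[Tuple[int, CanonicalVariant]] = None
    for start in range(lo, hi + 1):
        rep = replace(
            variant,
            start=start,
            deleted_seq=genome.fetch(variant.chrom, start, start + variant.n),
        )
        left, right = find_flanking_mh(genome, rep, max_mismatch, anchor_before_mismatch)
        sel = select_configuration(left, right)
        cand = CanonicalVariant(rep, start - variant.start, sel, left, right)
        if best is None or sel.score > best[0]:
            best = (sel.score, cand)
    assert best is not None
    return best[1]
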