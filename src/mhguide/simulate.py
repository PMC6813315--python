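"""Synthetic genomes and deletion loci with planted, machine-checkable truth.

The generator writes a microhomology structure directly into a random
background sequence:

* two identical µH copies of length ``m`` separated by ``d`` heterologous
  bases (the deletion removes one copy plus the heterology),
* optionally a PAM positioned so that its blunt cut is valid for the
  planted µH,
* optionally a nested exact repeat pair inside the heterology,
* optionally extra genome-wide copies of the guide word (perfect
  off-targets).

Single bases adjacent to the planted locus are constrained so that the µH
cannot extend past the planted length, the unplanted flanking
configuration scores zero, and the representation cannot shift further
left than intended — so the planted values are true of the sequence by
construction.  A light rejection loop re-samples the rare draws where the
random background still violates a constraint, using simple slice
comparisons independent of the analysis code.

The module also estimates background µH frequencies (the chance that a
random, structureless locus looks µH-flanked) and the closed-form
availability of a 'GG' PAM dinucleotide for abutted-µH deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import binomtest

from .io_formats import DeletionVariant, GenomeSequence, revcomp
from .microhomology import FlankConfig

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_bases(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def make_genome(length: int, gc: float = 0.5, seed=0, name: str = "chrS") -> GenomeSequence:
    """Uniform i.i.d. random genome with the given GC fraction."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed)
    return GenomeSequence({name: random_bases(rng, length, gc)})


def _base_not(rng: np.random.Generator, *forbidden: str) -> str:
    allowed = [b for b in "ACGT" if b not in forbidden]
    return allowed[rng.integers(len(allowed))]


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """Ground-truth structure to write into a genome.

    ``mh_len``/``mh_dist`` are the µH length and inter-copy heterology
    (deletion length = ``mh_len + mh_dist``).  ``pam`` plants a plus-strand
    NGG whose cut is the distal deletion boundary for OUTER_RIGHT (the
    proximal boundary for OUTER_LEFT), ``nested=(length, gap)`` plants an
    exact repeat pair inside the heterology, and ``offtarget_copies``
    duplicates the guide word elsewhere in the genome.
    """

    mh_len: int
    mh_dist: int
    config: FlankConfig = FlankConfig.OUTER_RIGHT
    pam: bool = False
    nested: Optional[Tuple[int, int]] = None
    offtarget_copies: int = 0

    def __post_init__(self):
        if self.mh_len < 1 or self.mh_dist < 0:
            raise ValueError("mh_len >= 1 and mh_dist >= 0 required")
        if self.nested is not None:
            q, gp = self.nested
            if q < 3 or gp < 0 or gp >= self.mh_dist or 2 * q + gp > self.mh_dist:
                raise ValueError("nested repeat does not fit the heterology")


@dataclass(frozen=True)
class PlantTruth:
    """What the planted locus must yield when analyzed in exact-match mode."""

    spec: PlantSpec
    variant: DeletionVariant
    canonical_start: int
    canonical_config: FlankConfig
    guide_cut: Optional[int] = None       # planted valid cut, if pam
    guide_word: Optional[str] = None      # protospacer+PAM of the planted guide
    expect_unique: Optional[bool] = None
    nested_cut: Optional[int] = None      # cut at which a nested pair must appear
    expect_nested: Optional[bool] = None
    nested_spans: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None


def _exact_run(a: str, b: str) -> int:
    k = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        k += 1
    return k


def _naive_word_count(genome: GenomeSequence, word: str) -> int:
    total = 0
    for chrom, clen in genome.contigs.items():
        seq = genome.fetch(chrom, 0, clen)
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - len(word) + 1):
                if s[i:i + len(word)] == word:
                    total += 1
    return total


def _has_competing_repeat(het: str, min_len: int = 3) -> bool:
    """Any pair of identical non-overlapping >=min_len words in the heterology."""
    L = len(het)
    for q in range(min_len, L // 2 + 1):
        seen: Dict[str, int] = {}
        for i in range(L - q + 1):
            w = het[i:i + q]
            if w in seen and i >= seen[w] + q:
                return True
            if w not in seen:
                seen[w] = i
    return False


def plant_variant(
    genome: GenomeSequence,
    spec: PlantSpec,
    seed=0,
    chrom: Optional[str] = None,
    start: Optional[int] = None,
    max_tries: int = 300,
) -> Tuple[GenomeSequence, DeletionVariant, PlantTruth]:
    """Write a planted deletion locus into a copy of the genome.

    Returns the edited genome, the deletion at its planted representation,
    and the machine-checkable truth record.  Raises if a satisfying draw is
    not found (essentially impossible at the supported sizes).
    """
    rng = _rng(seed)
    m, d = spec.mh_len, spec.mh_dist
    n = m + d
    if chrom is None:
        chrom = next(iter(genome.contigs))
    clen = genome.length(chrom)
    margin = n + m + 40  # room for flank constraints, PAM and protospacer

    for _ in range(max_tries):
        s = start if start is not None else int(rng.integers(margin, clen - margin - n))
        g2, var, truth = _plant_once(genome, spec, rng, chrom, s)
        if g2 is not None and _verify_plant(g2, spec, var, truth):
            return g2, var, truth
    raise RuntimeError(f"could not plant {spec} after {max_tries} tries")


def _plant_once(genome, spec: PlantSpec, rng, chrom, s):
    m, d = spec.mh_len, spec.mh_dist
    n = m + d
    copy = list(random_bases(rng, m))

    edits: Dict[int, str] = {}
    if spec.config is FlankConfig.OUTER_RIGHT:
        outer_start = s + n
        guide_cut = s + n
        het_start = s + m
    else:
        outer_start = s - m
        guide_cut = s
        het_start = s

    # PAM bases are fixed first so later heterology draws respect them
    het_forced: Dict[int, str] = {}
    if spec.pam:
        # plus-strand NGG with its cut at guide_cut: GG at guide_cut+4, +5
        for gpos in (guide_cut + 4, guide_cut + 5):
            if 0 <= gpos - outer_start < m:
                copy[gpos - outer_start] = "G"   # in the outer copy: bake into both
            elif spec.config is FlankConfig.OUTER_LEFT and 0 <= gpos - (s + d) < m:
                copy[gpos - (s + d)] = "G"       # in the inner copy (mirrors outer)
            elif 0 <= gpos - het_start < d:
                het_forced[gpos - het_start] = "G"
            else:
                edits[gpos] = "G"

    def draw_het():
        h = list(random_bases(rng, d))
        for off, b in het_forced.items():
            h[off] = b
        return h

    het = draw_het()
    nested_off = None
    if spec.nested is not None:
        q, gp = spec.nested
        rep = random_bases(rng, q)
        # end-align when PAM bases occupy the heterology start
        nested_off = d - (2 * q + gp) if het_forced else 0
        if any(nested_off <= off < nested_off + 2 * q + gp for off in het_forced):
            return None, None, None          # PAM and repeat cannot coexist here
        het[nested_off:nested_off + q] = list(rep)
        het[nested_off + q + gp:nested_off + 2 * q + gp] = list(rep)
        if gp >= 1:
            # pin the gap's edge bases so the planted pair stays maximal
            # (an extended pair would no longer straddle the planted cut)
            after_right = nested_off + 2 * q + gp
            forbid_first = [het[after_right]] if after_right < d else []
            forbid_last = [het[nested_off - 1]] if nested_off >= 1 else []
            if gp == 1:
                het[nested_off + q] = _base_not(rng, *forbid_first, *forbid_last)
            else:
                if forbid_first:
                    het[nested_off + q] = _base_not(rng, *forbid_first)
                if forbid_last:
                    het[nested_off + q + gp - 1] = _base_not(rng, *forbid_last)
    elif d > 0:
        # competing repeats must be absent when none was asked for
        for _ in range(200):
            if not _has_competing_repeat("".join(het)):
                break
            het = draw_het()
        else:
            return None, None, None

    if spec.config is FlankConfig.OUTER_RIGHT:
        seg = copy + het + copy
        seg_start = s
        deleted = "".join(copy + het)
        # block left shift / other configuration
        edits[s - 1] = _base_not(rng, deleted[-1])
        if d > 0:
            # stop µH extension exactly at m
            stop = edits.get(s + n + m, None)
            edits[s + n + m] = _base_not(rng, het[0]) if stop is None else stop
            if edits[s + n + m] == het[0]:
                het[0] = _base_not(rng, edits[s + n + m], het[0])
                deleted = "".join(copy + het)
                seg = copy + het + copy
        canonical_start, canonical_config = s, FlankConfig.OUTER_RIGHT
    else:
        seg = copy + het + copy
        seg_start = s - m
        deleted = "".join(het + copy)
        # block right shift / other configuration
        edits[s + n] = _base_not(rng, deleted[0])
        if d > 0:
            stop = edits.get(s - m - 1, None)
            edits[s - m - 1] = _base_not(rng, het[-1]) if stop is None else stop
            if edits[s - m - 1] == het[-1]:
                het[-1] = _base_not(rng, edits[s - m - 1], het[-1])
                deleted = "".join(het + copy)
                seg = copy + het + copy
        else:
            edits[s - m - 1] = _base_not(rng, copy[-1])
        canonical_start, canonical_config = s - m, FlankConfig.OUTER_RIGHT

    g2 = genome.with_edit(chrom, seg_start, "".join(seg))
    for pos, base in edits.items():
        g2 = g2.with_edit(chrom, pos, base)

    var = DeletionVariant(
        id=f"plant_{chrom}_{s}_{n}", chrom=chrom, start=s, deleted_seq=deleted)

    guide_word = None
    expect_unique = None
    if spec.pam:
        pam_start = guide_cut + 3
        guide_word = g2.fetch(chrom, pam_start - 20, pam_start + 3)
        expect_unique = spec.offtarget_copies == 0
        if spec.offtarget_copies:
            placed = 0
            while placed < spec.offtarget_copies:
                p = int(rng.integers(0, g2.length(chrom) - len(guide_word)))
                if abs(p - s) < margin_guard(n, m):
                    continue
                g2 = g2.with_edit(chrom, p, guide_word)
                placed += 1

    nested_cut = None
    nested_spans = None
    if spec.nested is not None:
        q, gp = spec.nested
        het_start = s + m if spec.config is FlankConfig.OUTER_RIGHT else s
        a1 = het_start + nested_off
        nested_spans = ((a1, a1 + q), (a1 + q + gp, a1 + 2 * q + gp))
        nested_cut = a1 + q + gp // 2  # between the two planted copies

    truth = PlantTruth(
        spec=spec, variant=var,
        canonical_start=canonical_start, canonical_config=canonical_config,
        guide_cut=guide_cut if spec.pam else None,
        guide_word=guide_word, expect_unique=expect_unique,
        nested_cut=nested_cut,
        expect_nested=(spec.nested is not None) if d > 0 else False,
        nested_spans=nested_spans,
    )
    return g2, var, truth


def margin_guard(n: int, m: int) -> int:
    return n + m + 40


def _verify_plant(g2: GenomeSequence, spec: PlantSpec, var: DeletionVariant,
                  truth: PlantTruth) -> bool:
    """Independent slice-comparison check that the planted truth holds."""
    m, d = spec.mh_len, spec.mh_dist
    n = m + d
    chrom, s = var.chrom, var.start
    deleted = g2.fetch(chrom, s, s + n)
    if deleted != var.deleted_seq or "N" in deleted:
        return False
    right = _exact_run(deleted, g2.fetch(chrom, s + n, s + n + n))
    left = _exact_run(deleted[::-1], g2.fetch(chrom, s - n if s >= n else 0, s)[::-1])
    if spec.config is FlankConfig.OUTER_RIGHT:
        if right != m or left != 0:
            return False
    else:
        if left != m or right != 0:
            return False
    if spec.pam and truth.guide_word is not None:
        if truth.guide_cut is not None and \
                g2.fetch(chrom, truth.guide_cut + 4, truth.guide_cut + 6) != "GG":
            return False
        want = 1 + spec.offtarget_copies
        if _naive_word_count(g2, truth.guide_word) != want:
            return False
    if truth.nested_spans is not None:
        (a1, b1), (a2, b2) = truth.nested_spans
        if g2.fetch(chrom, a1, b1) != g2.fetch(chrom, a2, b2):
            return False
        # the planted pair must be maximal within the heterology region,
        # otherwise only its extension (which may miss the cut) is reported
        het_start = s + m if spec.config is FlankConfig.OUTER_RIGHT else s
        het_end = het_start + d
        gap = a2 - b1
        if gap >= 1 and a2 >= b1 + 1:
            if b2 < het_end and a2 > b1 and \
                    g2.fetch(chrom, b1, b1 + 1) == g2.fetch(chrom, b2, b2 + 1):
                return False
            if a1 - 1 >= het_start and \
                    g2.fetch(chrom, a1 - 1, a1) == g2.fetch(chrom, a2 - 1, a2):
                return False
    return True


# ---------------------------------------------------------------------------
# Background µH frequencies
# ---------------------------------------------------------------------------

BACKGROUND_MODES = ("single_config_exact", "both_config_exact", "with_mismatch")


def background_fraction(
    n_loci: int,
    del_len: int,
    min_mh: int,
    mode: str = "single_config_exact",
    seed=0,
) -> Tuple[float, Tuple[float, float]]:
    """Monte Carlo background rate of µH-flanked calls at random loci.

    Samples ``n_loci`` loci of length ``del_len`` with uniform i.i.d.
    flanks, runs the µH extension, and returns the fraction of loci whose
    µH reaches ``min_mh`` together with a 95% binomial confidence interval.
    In ``single_config_exact`` mode one flanking configuration is tested
    with exact matching, for which the closed-form expectation is
    ``0.25 ** min_mh``; ``both_config_exact`` tests both configurations;
    ``with_mismatch`` allows the standard single absorbed mismatch.
    """
    from .microhomology import extend_microhomology

    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(seed)
    hits = 0
    # one draw = left flank, deleted segment, right flank
    block = 3 * del_len
    chunk = 20_000
    remaining = n_loci
    while remaining > 0:
        k = min(chunk, remaining)
        idx = rng.integers(0, 4, size=(k, block))
        arr = _BASES[idx]
        for row in arr:
            locus = row.tobytes().decode()
            left, deleted, right_fl = (locus[:del_len], locus[del_len:2 * del_len],
                                       locus[2 * del_len:])
            mm = 1 if mode == "with_mismatch" else 0
            mhL, _, _ = extend_microhomology(deleted, right_fl, max_mismatch=mm)
            ok = mhL >= min_mh
            if not ok and mode == "both_config_exact":
                mhL2, _, _ = extend_microhomology(deleted[::-1], left[::-1], max_mismatch=0)
                ok = mhL2 >= min_mh
            hits += ok
        remaining -= k
    frac = hits / n_loci
    ci = binomtest(hits, n_loci).proportion_ci(confidence_level=0.95, method="wilson")
    return frac, (ci.low, ci.high)


# ---------------------------------------------------------------------------
# PAM availability for abutted µHs
# ---------------------------------------------------------------------------

def pam_availability_per_side() -> float:
    """Probability of 'GG' at the two fixed positions flanking one side: (1/4)^2."""
    return 0.25 ** 2


def pam_availability_additive() -> float:
    """Two-side additive approximation of SpCas9 PAM availability (12.5%).

    For an abutted 3-bp µH on a 3-bp deletion only one cut position is
    permitted, so a usable PAM requires 'GG' at fixed dinucleotide
    positions on one strand or 'CC' at mirrored positions on the other;
    adding the two per-side probabilities gives 2 x (1/4)^2.
    """
    return 2 * pam_availability_per_side()


def pam_availability_exact() -> float:
    """Inclusion-exclusion probability that at least one side carries a PAM."""
    p = pam_availability_per_side()
    return 1 - (1 - p) ** 2


def pam_availability_mc(n_loci: int = 5000, seed=0) -> float:
    """Monte Carlo fraction of abutted 3-bp-µH deletions with a valid NGG guide.

    Plants ``n_loci`` independent (m=3, d=0) loci in random backgrounds and
    runs the guide enumeration; converges to the inclusion-exclusion value
    of :func:`pam_availability_exact`.
    """
    from .microhomology import CanonicalVariant, find_flanking_mh, select_configuration
    from .guides import PamMotif, enumerate_guides

    rng = _rng(seed)
    motifs = [PamMotif("NGG")]
    spec = PlantSpec(mh_len=3, mh_dist=0, config=FlankConfig.OUTER_RIGHT)
    hits = 0
    genome = make_genome(120, seed=rng)
    for _ in range(n_loci):
        g2, var, _ = plant_variant(genome, spec, seed=rng, start=50)
        left, right = find_flanking_mh(g2, var, max_mismatch=0)
        sel = select_configuration(left, right)
        canon = CanonicalVariant(var, 0, sel, left, right)
        guides = enumerate_guides(g2, canon, motifs)
        hits += any(g.valid for g in guides)
        genome = make_genome(120, seed=rng)
    return hits / n_loci
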