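"""Microhomology extension, configuration selection and canonicalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhguide import (DeletionVariant, FlankConfig, GenomeSequence,
                     canonicalize, extend_microhomology, find_flanking_mh,
                     select_configuration, shift_range)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


# ---------------------------------------------------------------------------
# independent oracle: longest valid prefix with <= max_mismatch mismatches
# ---------------------------------------------------------------------------

def oracle_extend(inner, flank, max_mismatch=1, anchor=1):
    """Best alignment prefix ending in a match, mismatches gated by an anchor."""
    limit = min(len(inner), len(flank))
    best = (0, 0, 0)
    for L in range(1, limit + 1):
        flags = [inner[i] == flank[i] and inner[i] != "N" for i in range(L)]
        if not flags[-1]:
            continue
        mm = flags.count(False)
        if mm > max_mismatch:
            continue
        ok = True
        for i, f in enumerate(flags):
            if f:
                continue
            run = 0
            j = i - 1
            while j >= 0 and flags[j]:
                run += 1
                j -= 1
            if run < anchor or i + 1 >= L or not any(flags[i + 1:]):
                ok = False
                break
        if not ok:
            continue
        mh1 = flags.index(False) if False in flags else L
        best = max(best, (L, mh1, sum(flags)))
    return best


@pytest.mark.parametrize("inner,flank,expected", [
    ("AAA", "AAATGC", (3, 3, 3)),        # perfect 3-bp match capped at n
    ("TAGCA", "TAGTACC", (5, 3, 4)),     # one absorbed internal mismatch
    ("GGGG", "TTTT", (0, 0, 0)),         # first-base mismatch
    ("", "ACGT", (0, 0, 0)),             # empty inner sequence
    ("TAGC", "TAGT", (3, 3, 3)),         # trailing mismatch trimmed
    ("ATCGG", "ATCGG", (5, 5, 5)),       # full-length match
])
def test_extension_examples(inner, flank, expected):
    assert extend_microhomology(inner, flank) == expected


def test_extension_score_identity():
    mhL, mh1L, matches = extend_microhomology("TAGCA", "TAGTACC")
    assert matches + mh1L == 7


@pytest.mark.parametrize("anchor", [1, 3])
@settings(max_examples=300, derandomize=True)
@given(inner=DNA, flank=DNA)
def test_extension_matches_bruteforce(inner, flank, anchor):
    """The greedy walk equals an exhaustive search over valid prefixes."""
    got = extend_microhomology(inner, flank, max_mismatch=1,
                               anchor_before_mismatch=anchor)
    assert got == oracle_extend(inner, flank, 1, anchor)


@settings(max_examples=200, derandomize=True)
@given(inner=DNA, flank=DNA)
def test_extension_exact_mode_is_common_prefix(inner, flank):
    k = 0
    while k < min(len(inner), len(flank)) and inner[k] == flank[k]:
        k += 1
    assert extend_microhomology(inner, flank, max_mismatch=0) == (k, k, k)


def test_strict_anchor_requires_three_matches():
    # mismatch after only 2 matches: absorbed with anchor=1, not with anchor=3
    assert extend_microhomology("TACAA", "TAGAACC", anchor_before_mismatch=1)[0] == 5
    assert extend_microhomology("TACAA", "TAGAACC", anchor_before_mismatch=3)[0] == 2


# ---------------------------------------------------------------------------
# flanking configurations
# ---------------------------------------------------------------------------

def test_flanking_configurations_on_repeat_locus():
    #        0123456789...
    g = GenomeSequence({"c1": "TTACAGCAGGTTAA"})
    v = DeletionVariant("v", "c1", 3, "CAG")
    left, right = find_flanking_mh(g, v, max_mismatch=0)
    assert right.config is FlankConfig.OUTER_RIGHT
    assert (right.mhL, right.dist) == (3, 0)
    assert right.mh_seq == "CAG"
    assert left.mhL == 0
    assert select_configuration(left, right) is right


def test_full_length_mh_capped_at_deletion():
    g = GenomeSequence({"c1": "T" * 10 + "ATCGGATCGGCATT"})
    v = DeletionVariant("v", "c1", 10, "ATCGG")
    _, right = find_flanking_mh(g, v, max_mismatch=0)
    assert (right.mhL, right.dist) == (5, 0)


def test_result_invariants_on_planted_loci(planted_set):
    genome, loci = planted_set
    for var, truth in loci:
        left, right = find_flanking_mh(genome, var)
        for r in (left, right):
            assert 0 <= r.mh1L <= r.mhL <= var.n
            assert r.score == r.matches + r.mh1L
            assert r.dist == var.n - r.mhL
            if r.mhL:
                assert 0.0 <= r.gc <= 1.0
                assert len(r.mh_seq) == r.mhL


def test_select_configuration_tie_breaks():
    left, right = find_flanking_mh(
        GenomeSequence({"c": "TTACAGCAGGTTAA"}),
        DeletionVariant("v", "c", 3, "CAG"), max_mismatch=0)
    # same score: larger mh1L wins; equal everything: OUTER_LEFT wins
    assert select_configuration(right, right).config is FlankConfig.OUTER_RIGHT
    from dataclasses import replace
    lo = replace(right, config=FlankConfig.OUTER_LEFT)
    assert select_configuration(lo, right) is lo


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _post_deletion(g, chrom, start, n):
    full = g.fetch(chrom, 0, g.length(chrom))
    return full[:start] + full[start + n:]


def oracle_canonical(g, var):
    """Exhaustive scan of all equivalent representations by string equality."""
    target = _post_deletion(g, var.chrom, var.start, var.n)
    best = None
    for s in range(max(0, var.start - var.n - 40),
                   min(g.length(var.chrom) - var.n, var.start + var.n + 40) + 1):
        if _post_deletion(g, var.chrom, s, var.n) != target:
            continue
        rep = DeletionVariant(var.id, var.chrom, s, g.fetch(var.chrom, s, s + var.n))
        sel = select_configuration(*find_flanking_mh(g, rep))
        if best is None or sel.score > best[0]:
            best = (sel.score, s)
    return best[1]


def test_canonicalize_repeat_example():
    g = GenomeSequence({"c1": "TTACAGCAGGTT"})
    v = DeletionVariant("v", "c1", 3, "CAG")
    assert shift_range(g, v) == (3, 6)
    c = canonicalize(g, v, max_mismatch=0)
    assert c.variant.start == 3           # max µH at 3 and 6; leftmost wins
    assert (c.best_mh.mhL, c.best_mh.dist) == (3, 0)
    assert c.shift_offset == 0


def test_canonicalize_nonrepetitive_is_identity(base_genome):
    v = DeletionVariant("v", "chrS", 1001, base_genome.fetch("chrS", 1001, 1004))
    lo, hi = shift_range(base_genome, v)
    c = canonicalize(base_genome, v)
    assert lo <= c.variant.start <= hi
    if lo == hi:
        assert c.shift_offset == 0


def test_canonicalize_matches_exhaustive_oracle():
    rng = np.random.default_rng(77)
    g = GenomeSequence({"c": "".join(rng.choice(list("ACGT"), size=400))})
    # low-entropy contig to force plenty of shifts
    g2 = GenomeSequence({"c": "".join(rng.choice(list("AC"), size=400))})
    for genome in (g, g2):
        for _ in range(60):
            n = int(rng.integers(1, 7))
            s = int(rng.integers(20, 380 - n))
            v = DeletionVariant("v", "c", s, genome.fetch("c", s, s + n))
            assert canonicalize(genome, v).variant.start == oracle_canonical(genome, v)


def test_shift_invariance_over_equivalent_representations():
    """Every equivalent input representation canonicalizes identically."""
    rng = np.random.default_rng(123)
    g = GenomeSequence({"c": "".join(rng.choice(list("ACGT"), size=300))})
    for _ in range(40):
        n = int(rng.integers(1, 6))
        s = int(rng.integers(20, 280 - n))
        v = DeletionVariant("v", "c", s, g.fetch("c", s, s + n))
        lo, hi = shift_range(g, v)
        ref = canonicalize(g, v)
        for s2 in range(lo, hi + 1):
            v2 = DeletionVariant("v", "c", s2, g.fetch("c", s2, s2 + n))
            c2 = canonicalize(g, v2)
            assert c2.variant == ref.variant
            assert c2.best_mh == ref.best_mh


def test_post_deletion_sequence_identical_across_shift_range(base_genome):
    rng = np.random.default_rng(5)
    for _ in range(30):
        n = int(rng.integers(1, 6))
        s = int(rng.integers(100, 7000))
        v = DeletionVariant("v", "chrS", s, base_genome.fetch("chrS", s, s + n))
        lo, hi = shift_range(base_genome, v)
        target = _post_deletion(base_genome, "chrS", s, n)
        for s2 in range(lo, hi + 1):
            assert _post_deletion(base_genome, "chrS", s2, n) == target


# ---------------------------------------------------------------------------
# strand symmetry
# ---------------------------------------------------------------------------

def test_strand_symmetry_of_flanking_metrics(planted_set):
    """Reverse-complementing the genome swaps the configurations and
    preserves every µH metric; the retained copy reverse-complements."""
    from mhguide import revcomp

    genome, loci = planted_set
    L = genome.length("chrS")
    rc = genome.reverse_complement()
    for var, _ in loci:
        mirrored = DeletionVariant(var.id, var.chrom, L - var.end,
                                   revcomp(var.deleted_seq))
        left, right = find_flanking_mh(genome, var)
        m_left, m_right = find_flanking_mh(rc, mirrored)
        for a, b in ((left, m_right), (right, m_left)):
            assert (a.mhL, a.mh1L, a.matches, a.score, a.dist) == \
                   (b.mhL, b.mh1L, b.matches, b.score, b.dist)
            assert a.gc == pytest.approx(b.gc)
            assert b.mh_seq == revcomp(a.mh_seq)
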