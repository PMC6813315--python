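# Methods

This note records the model, the conventions and the deliberate design
choices behind `mhguide`, in the order the pipeline runs.

## Coordinates and sequence model

All internal coordinates are 0-based, half-open; conversion from the
1-based conventions of VCF and GFF3 happens once, at the parser boundary.
Genomes are held in memory, uppercased, with any non-ACGTN symbol mapped to
N. N never matches anything, including another N; variants whose deleted
segment or µH search window (± one deletion length) contains N are excluded
and counted, because a µH match is undefined there.

VCF records are reduced to pure deletions by stripping the longest common
prefix of REF/ALT and then the longest common suffix of the remainder; a
record survives only if what is left of ALT is empty and of REF non-empty.
Multi-allelic records are decomposed and only deletion ALTs kept. Every
accepted record is verified against the reference slice; mismatches are
rejected and counted rather than repaired.

## Microhomology detection and scoring

For a deletion of length *n*, both flanking configurations are evaluated:

* `outer_right` — deletion prefix vs right-flank prefix, walking rightward
  (inner µH copy at the deletion's 5′ end, outer copy immediately
  downstream);
* `outer_left` — deletion suffix vs left-flank suffix, walking leftward.

The walk absorbs at most `max_mismatch` mismatches (default 1). A mismatch
is absorbed only when at least `anchor_before_mismatch` consecutive matches
immediately precede it and at least one match follows; a trailing mismatch
is trimmed. The default anchor is 1; `anchor_before_mismatch=3` gives the
strict variant in which a mismatch must follow a perfect stretch of ≥ 3 bp.
The full µH length is capped at *n* so the two copies never overlap — an
overlapping pair does not describe a realizable MMEJ junction.

Reported metrics: full length `mhL`, first exact stretch `mh1L`, `matches`,
`score = matches + mh1L`, homology fraction, GC content of the
retained-flank copy (the copy that survives repair; with zero mismatches
both copies are identical anyway), `dist = n − mhL`, and the auxiliary
`dist_exact = n − mh1L` (the heterology a purely exact anneal would resect).

The configuration with the higher score is selected; ties break to the
larger `mh1L` and then to `outer_left`. The tie-break is an arbitrary but
fixed rule chosen for determinism.

## Canonicalization

A deletion inside a repeat has several coordinate representations that
remove the same sequence. The reachable set is enumerated by shifting left
while the base before the deletion equals the last deleted base, and right
symmetrically; the representation whose selected µH scores highest is kept,
leftmost on ties. Deduplication keys on (contig, canonical start, length).

A consequence worth knowing: any deletion with an *exact* flanking µH of
length *m* in `outer_left` configuration can be left-shifted *m* times into
an equivalent `outer_right` representation with identical score, so after
canonicalization exact µHs are always reported as `outer_right` at the
leftmost start. The `outer_left` configuration still matters when analyzing
a fixed input representation and in mismatch mode, where shifts can be
blocked.

## Guide enumeration

PAM motifs are IUPAC strings scanned on both strands (minus-strand hits via
the reverse-complement motif at plus coordinates). The blunt cut sits 3 bp
upstream of the PAM: `cut = pam_start − 3` on the plus strand,
`cut = pam_start + |motif| + 3` on the minus strand. The protospacer is
fixed at 20 nt (the SpCas9 standard; configurable). xCas9 PAMs (NGN, GAA,
GAT) reuse the same cut geometry.

A candidate's cut must lie within the deleted segment, boundaries included;
it is *valid* when it additionally avoids the first `min(3, mhL)` bp of the
inner µH copy (so ≥ 3 bp of µH is retained on each side of the break) and
lies within `max_cut_dist` (default 50) intervening bases of the nearer µH
copy. Measuring to the nearer copy deliberately keeps one candidate near
each copy of a very long deletion, from which a two-cut experiment can be
assembled; `require_both_within` switches to the stricter reading.
Candidates are emitted with their validity flag so the funnel counts
(`n_pam_candidates ≥ n_valid ≥ n_unique ≥ n_no_nested`) are visible per
variant. For deletions longer than `max_del_len` (default 10,000 bp) only
the neighbourhoods of the two µH copies are scanned; interior candidates
could never be valid.

## Off-target uniqueness

Exact, 0-mismatch counting only: an index of all `protospacer+PAM`-length
words over both genome strands (words containing N skipped; a palindromic
word counts once per strand occurrence). By default, counts are summed over
every concrete realization of the motif's ambiguous positions (any NGG
licenses cleavage); literal counting of the observed word is available. A
guide is unique iff its total count is 1 — its own site. Mismatch-tolerant
scoring (MIT/CFD) is out of scope.

## Nested microhomologies

Within the heterology between the two target µH copies (the search stops at
the copies' proximal edges), all *maximal* exact repeat pairs ≥ 3 bp are
enumerated: a pair is maximal when neither a one-base left- nor
right-extension yields another identical, non-overlapping, in-bounds pair.
Copies abutted inside a tandem run are therefore still reported. For a
given cut, a pair qualifies as nested when one copy ends at or before the
cut, the other starts at or after it, and its gap is strictly smaller than
the target µH distance; abutted targets (distance 0) can have no nested µH.
Each pair gets the pattern score `100·exp(−(gap+len)/20)·(2·n_GC + n_AT)`
(exponential decay with the deletion the competitor would create, GC pairs
weighted double; decay constant and GC weight configurable). Per guide, the
summary is the pair count and the *maximum* score ("strength"); the sum is
emitted as an auxiliary column. Max was chosen over sum because the
strongest competitor dominates the repair competition. The variant-level
summary takes the guide with the fewest nested pairs (ties to the lowest
cut coordinate, then strand, for determinism).

## Annotation, classification, filters

Genic context uses any-overlap with precedence CDS → UTR → exon → gene
(exon without CDS/UTR still counts as exonic, covering non-coding exons);
no annotation means intergenic. A deletion is frameshifting iff exonic and
its length is not a multiple of 3. Clinical significance collapses to
pathogenic / benign / VUS-other / none by case-insensitive *word-boundary*
match of "pathogenic" (so "Likely pathogenic" counts but "…pathogenicity"
does not); a substring mode reproduces plain containment. Pathogenic
outranks benign when both appear. Filters are conjunctive and applied in a
fixed order, emitting per-stage survivor counts (the funnel). Output rows
are deterministically ordered (variants by contig/start/id; guides by
variant, cut, strand), making reruns byte-identical.

Repair-outcome prevalences (e.g. from inDelphi) are accepted as a
precomputed per-guide table and passed through as a column; they are never
computed here.

## Synthetic data

`make_genome` draws i.i.d. bases at a given GC fraction. `plant_variant`
writes a locus with exact ground truth: two identical µH copies of length
*m* separated by *d* heterologous bases, optionally a plus-strand NGG whose
cut is the deletion boundary adjacent to the outer copy, optionally a
maximal nested repeat pair inside the heterology, optionally extra
genome-wide copies of the guide word. Single bases adjacent to the locus
are constrained so the µH cannot extend past *m*, the unplanted
configuration scores zero, and the representation cannot shift further than
intended; when no nested pair is requested the heterology is redrawn until
it contains no competing repeat, and the bases flanking a planted pair are
pinned so the pair stays maximal. A final slice-comparison check (simple
string operations, independent of the analysis code) re-verifies the truth
and redraws on the rare failure. Planted truths hold in exact-match mode;
mismatch-mode analysis may legitimately extend a µH into random flank.

What the generator does *not* emulate: human base composition, repeat
families, SNP density, sequencing error. Passing recovery tests therefore
demonstrates algorithmic correctness on known structure, not performance on
genomic sequence context.

## Background statistics

`background_fraction` measures how often random, structureless loci look
µH-flanked: for deletion length *k* and µH threshold *k* under exact
matching in a single configuration, the closed-form expectation is
`0.25^k` (25%, 6.25%, 1.56% for k = 1, 2, 3); both-configuration and
one-mismatch modes are reported separately since their rates are higher.
Estimates use 2×10⁵ loci with Wilson 95% confidence intervals — enough for
three-digit agreement at interactive runtimes.

PAM availability for the abutted 3-bp µH case: only one cut position is
permitted, requiring 'GG' at fixed dinucleotide positions on one strand or
'CC' at the mirrored positions on the other. Per side (1/4)² = 6.25%; the
additive two-side approximation gives 12.5%; the exact inclusion–exclusion
value is 1 − (15/16)² ≈ 12.11%. A guide-level Monte Carlo (planting abutted
loci and running the actual enumeration) converges to the exact value and
ties the closed form to the implementation.

## Numerical and scale choices

Default thresholds: deletions ≥ 3 bp, µH ≥ 3 bp, one absorbed mismatch,
NGG, 20-nt protospacer, 50 bp cut distance, nested minimum 3 bp. Test and
acceptance problem sizes (8–12 kb genomes, 500 planted loci, 2×10⁵
background draws, ≥ 1000 fuzzed oracle instances) were chosen so the whole
suite runs in well under a minute of CPU while keeping binomial standard
errors small relative to the quantities asserted. The k-mer index is a
plain hash-map count over both strands — adequate for the fixture scale
this package targets; genome-scale runs would stream variants and may swap
in an external exact counter behind the same interface.

## Known limitations

* Off-target uniqueness is exact-match only; a guide unique at 0 mismatches
  may still cleave 1-mismatch sites.
* No on-target efficiency model; guide ranking beyond validity/uniqueness/
  nested competition is left to downstream tools.
* Two-cut designs for long deletions are supported only as single-cut
  candidates near each µH copy; pairing is left to the user.
* The nested-µH search stops at the target copies' proximal edges; repeats
  partially overlapping the target copies are not considered competitors.
* Liftover, alt contigs and multi-allelic decomposition beyond deletion
  extraction are out of scope.
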