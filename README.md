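# mhguide

Microhomology-aware CRISPR guide design for recreating naturally occurring
deletion variants through microhomology-mediated end joining (MMEJ).

## The problem

MMEJ repairs a double-strand break (DSB) by resecting the broken ends,
annealing a short identical sequence — a *microhomology* (µH) — present on
both sides of the break, and removing the intervening sequence. The outcome
is a deletion of predictable size and identity. A deletion variant annotated
in a database (dbSNP/ClinVar-style VCF) is therefore a candidate for precise,
template-free recreation by CRISPR-Cas9 if:

1. the deletion is flanked by a µH: one copy inside the deleted segment and
   one in the retained flank, so MMEJ can regenerate exactly the annotated
   allele;
2. a PAM places a blunt Cas9 cut between the two µH copies, keeping at least
   3 bp of µH on either side of the break and staying within 50 bp of a copy;
3. the protospacer+PAM word is unique in the genome (no perfect off-target);
4. no *nested* µH — an exact repeat pair ≥ 3 bp inside the deletion with a
   smaller inter-copy gap — competes for the repair outcome.

`mhguide` implements this analysis end to end: µH detection and scoring,
coordinate canonicalization, guide enumeration, exact off-target counting,
nested-µH scoring, genic/clinical annotation, a filter funnel, and
deterministic variant- and guide-level reports. A synthetic-data module
plants loci with known ground truth so every stage is testable without any
external download.

## Model in brief

For a deletion of length *n* at `[s, s+n)`, both flank alignments are
scored: the 3′ flank against the deletion's 5′ end (`outer_right`) and the
5′ flank against the deletion's 3′ end (`outer_left`). The µH is extended
junction-outward, absorbing at most one mismatch (which must be preceded by
a configurable run of exact matches and followed by a match):

```
score = matches in full µH + length of first exact stretch (mh1L)
dist  = n − mhL            (heterology between the two copies; 0 = abutted)
```

The configuration with the higher score wins. Deletions in repeats are
shifted through every equivalent representation and the coordinates
maximizing the score are kept (leftmost on ties). SpCas9 cuts bluntly 3 bp
upstream of its NGG PAM; xCas9 (`NGN`, `GAA`, `GAT`) is supported with the
same cut geometry. Off-target testing counts exact occurrences of the
23-mer protospacer+PAM over both genome strands — a guide is unique iff the
count is 1. Nested µHs are maximal exact repeat pairs straddling the cut
within the heterology, ranked by the pattern score
`100·exp(−del_len/20)·(2·n_GC + n_AT)`.

## Worked example

Generate a small fixture (9 kb genome, five deletions of 6 bp planted with a
4 bp µH at distance 2 and a valid PAM), then analyze it:

```bash
mhguide simulate --out fix --genome-length 9000 --n-variants 5 \
                 --mh-len 4 --mh-dist 2 --seed 7
mhguide run --ref fix.fa --variants fix.vcf --out demo
```

`demo-variants.tsv` (columns abridged):

```
id                 del_len mhL mh1L dist_exact mh_seq n_unique_guides n_guides_no_nested
plant_chrS_1500_6  6       4   4    2          CCGT   5               5
plant_chrS_3000_6  6       4   4    2          CGTC   1               1
plant_chrS_4500_6  6       4   4    2          GTTG   2               2
```

Every variant is recovered with the planted µH length 4 and heterology 2,
and each has at least one unique guide. `demo-guides.tsv` lists the guides:

```
guide_id                protospacer          pam strand cut_pos dist_left dist_right is_unique
plant_chrS_1500_6:1503- TGACGGCACCACGGAAACGG GGG -      1503    0         3          True
plant_chrS_1500_6:1506+ GCCCCCTACCCCCGTTTCCG TGG +      1506    2         0          True
```

A cut at 1503 on the minus strand sits directly at the edge of the left µH
copy (`dist_left 0`) and 3 bp from the right copy: MMEJ annealing of the two
copies removes exactly the annotated 6 bp. `demo-summary.json` echoes the
parameters and the per-filter survivor counts.

Real data run the same way: `--ref GRCh38.fa --variants clinvar.vcf
--annotation gencode.gff3`, with filters such as `--filter-unique-guide`,
`--filter-no-nested`, or `--pam NGN --pam GAA --pam GAT` for xCas9.

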