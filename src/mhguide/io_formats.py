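"""Reading and writing of genomic file formats.

All internal coordinates are 0-based, half-open.  Conversion from the
1-based conventions of VCF and GFF3 happens here, at the format boundary,
and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("mhguide")

# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean(seq: str) -> str:
    """Uppercase and map any non-ACGTN symbol to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(b if b in _VALID else "N" for b in seq)


class GenomeSequence:
    """In-memory reference genome with 0-based half-open interval access.

    Sequences are stored uppercase over {A,C,G,T,N}.  ``fetch(c, i, j)``
    returns exactly ``j - i`` bases and raises on out-of-bounds requests,
    so downstream code never silently works on truncated windows.
    """

    def __init__(self, contigs: Dict[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self._seqs = {name: _clean(seq) for name, seq in contigs.items()}

    @property
    def contigs(self) -> Dict[str, int]:
        """Contig name -> length registry."""
        return {name: len(s) for name, s in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or start > end:
            raise IndexError(
                f"interval [{start},{end}) out of bounds for contig "
                f"{chrom!r} of length {len(self._seqs[chrom])}"
            )
        return self._seqs[chrom][start:end]

    def fetch_clipped(self, chrom: str, start: int, end: int) -> Tuple[str, int]:
        """Fetch with the interval clipped to the contig; returns (seq, clipped_start)."""
        n = len(self._seqs[chrom])
        s, e = max(0, start), min(n, end)
        if s >= e:
            return "", s
        return self._seqs[chrom][s:e], s

    def reverse_complement(self) -> "GenomeSequence":
        """Genome with every contig reverse-complemented (for strand-symmetry checks)."""
        return GenomeSequence({name: revcomp(s) for name, s in self._seqs.items()})

    def with_edit(self, chrom: str, start: int, seq: str) -> "GenomeSequence":
        """Copy of the genome with ``seq`` written over [start, start+len(seq))."""
        s = self._seqs[chrom]
        if start < 0 or start + len(seq) > len(s):
            raise IndexError("edit out of bounds")
        new = dict(self._seqs)
        new[chrom] = s[:start] + seq.upper() + s[start + len(seq):]
        return GenomeSequence(new)


def load_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file eagerly into a :class:`GenomeSequence`.

    Lowercase is uppercased; non-ACGTN symbols become N.  Duplicate contig
    names and empty files are errors.
    """
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            seq = genome.fetch(name, 0, genome.length(name))
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Deletion variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeletionVariant:
    """A pure deletion: ``deleted_seq`` is removed from the reference.

    ``start`` is the 0-based position of the first deleted base; the
    deletion spans ``[start, start + len(deleted_seq))``.
    """

    id: str
    chrom: str
    start: int
    deleted_seq: str
    source: str = "synthetic"  # dbSNP | ClinVar | merged | synthetic
    clin_sig: Tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.deleted_seq)

    @property
    def end(self) -> int:
        return self.start + len(self.deleted_seq)


def trim_indel(ref: str, alt: str) -> Optional[Tuple[int, str]]:
    """Reduce a VCF REF/ALT pair to a pure deletion, if it is one.

    Strips the longest shared prefix, then the longest shared suffix of the
    remainder.  Returns ``(offset, deleted_seq)`` where ``offset`` is the
    number of prefix bases stripped, or ``None`` when the pair is not a pure
    deletion (insertion, substitution, or complex allele).
    """
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    s = 0
    while s < len(r) and s < len(a) and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
        s += 1
    if s:
        r, a = r[:-s], a[:-s]
    if a or not r:
        return None
    return p, r


def _split_clnsig(value) -> Tuple[str, ...]:
    # ClinVar CLNSIG may be a tuple and uses ',' / '|' / '/' separators
    if value is None:
        return ()
    parts: List[str] = []
    items = value if isinstance(value, (tuple, list)) else [value]
    for item in items:
        text = str(item).replace("|", ",")
        parts.extend(t.strip().replace("_", " ") for t in text.split(",") if t.strip())
    return tuple(parts)


def variant_has_n(genome: GenomeSequence, var: DeletionVariant) -> bool:
    """True when the deletion or its microhomology search window contains N."""
    n = var.n
    window, _ = genome.fetch_clipped(var.chrom, var.start - n, var.end + n)
    return "N" in window


def parse_deletions_vcf(
    path: str | Path,
    genome: GenomeSequence,
    stats: Optional[Dict[str, int]] = None,
) -> Iterator[DeletionVariant]:
    """Stream pure-deletion records from a VCF.

    Multi-allelic records are decomposed and only deletion ALTs are kept.
    Records are verified against the genome: a REF that does not match the
    reference slice is rejected and counted, as are deletions containing N
    in or around the deleted segment.
    """
    import pysam

    if stats is None:
        stats = {}
    for key in ("records", "emitted", "skipped_non_deletion", "skipped_symbolic",
                "rejected_ref_mismatch", "rejected_n"):
        stats.setdefault(key, 0)

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            stats["records"] += 1
            clin = _split_clnsig(rec.info.get("CLNSIG")) if "CLNSIG" in rec.info else ()
            source = str(rec.info.get("MHSOURCE", "dbSNP")) if "MHSOURCE" in rec.info else "dbSNP"
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or set(alt) - _VALID - set("acgtn"):
                    stats["skipped_symbolic"] += 1
                    logger.debug("skipping symbolic/invalid ALT at %s:%s", rec.chrom, rec.pos)
                    continue
                trimmed = trim_indel(rec.ref.upper(), alt.upper())
                if trimmed is None:
                    stats["skipped_non_deletion"] += 1
                    continue
                offset, deleted = trimmed
                start = rec.pos - 1 + offset  # VCF POS is 1-based
                var = DeletionVariant(
                    id=rec.id or f"{rec.chrom}_{rec.pos}_{len(deleted)}",
                    chrom=rec.chrom,
                    start=start,
                    deleted_seq=deleted,
                    source=source,
                    clin_sig=clin,
                )
                try:
                    ref_slice = genome.fetch(var.chrom, var.start, var.end)
                except (KeyError, IndexError):
                    stats["rejected_ref_mismatch"] += 1
                    logger.warning("variant %s out of genome bounds; rejected", var.id)
                    continue
                if ref_slice != var.deleted_seq:
                    stats["rejected_ref_mismatch"] += 1
                    logger.warning("REF mismatch for %s at %s:%d; rejected",
                                   var.id, var.chrom, var.start)
                    continue
                if variant_has_n(genome, var):
                    stats["rejected_n"] += 1
                    continue
                stats["emitted"] += 1
                yield var


def parse_deletions_table(
    path: str | Path,
    genome: GenomeSequence,
    stats: Optional[Dict[str, int]] = None,
) -> Iterator[DeletionVariant]:
    """Read deletions from a plain tab-delimited table.

    Columns: chrom, start (0-based), deleted sequence, id, clinical
    significance (comma-separated, may be empty).  A header line is
    detected and skipped.
    """
    if stats is None:
        stats = {}
    stats.setdefault("records", 0)
    stats.setdefault("emitted", 0)
    stats.setdefault("rejected_ref_mismatch", 0)
    stats.setdefault("rejected_n", 0)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # header
                continue
            stats["records"] += 1
            chrom, start, seq = fields[0], int(fields[1]), fields[2].upper()
            vid = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}_{start}_{len(seq)}"
            clin = tuple(t.strip() for t in fields[4].split(",") if t.strip()) if len(fields) > 4 else ()
            source = fields[5] if len(fields) > 5 else "synthetic"
            var = DeletionVariant(vid, chrom, start, seq, source, clin)
            try:
                ref_slice = genome.fetch(chrom, var.start, var.end)
            except (KeyError, IndexError):
                stats["rejected_ref_mismatch"] += 1
                continue
            if ref_slice != seq:
                stats["rejected_ref_mismatch"] += 1
                logger.warning("sequence mismatch for %s; rejected", vid)
                continue
            if variant_has_n(genome, var):
                stats["rejected_n"] += 1
                continue
            stats["emitted"] += 1
            yield var


def write_variant_table(variants: Iterable[DeletionVariant], path: str | Path) -> None:
    """Write the internal variant table; round-trips through :func:`parse_deletions_table`."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tdeleted_seq\tid\tclin_sig\tsource\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.start}\t{v.deleted_seq}\t{v.id}\t"
                     f"{','.join(v.clin_sig)}\t{v.source}\n")


def write_deletions_vcf(
    genome: GenomeSequence,
    variants: Iterable[DeletionVariant],
    path: str | Path,
) -> None:
    """Write deletions as VCF 4.2 with the shared anchor base convention.

    Each record carries the base before the deletion as REF[0]/ALT, so a
    variant must not start at position 0 of its contig.  Clinical labels go
    to CLNSIG (spaces encoded as underscores), the source to MHSOURCE;
    :func:`parse_deletions_vcf` round-trips both.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLNSIG,Number=.,Type=String,'
                 'Description="Clinical significance">\n')
        fh.write('##INFO=<ID=MHSOURCE,Number=1,Type=String,'
                 'Description="Variant source database">\n')
        for name, length in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.start, v.id)):
            if v.start < 1:
                raise ValueError(f"variant {v.id} starts at contig position 0; "
                                 "cannot write anchored VCF record")
            anchor = genome.fetch(v.chrom, v.start - 1, v.start)
            info = [f"MHSOURCE={v.source}"]
            if v.clin_sig:
                info.append("CLNSIG=" + ",".join(
                    c.replace(" ", "_") for c in v.clin_sig))
            fh.write(f"{v.chrom}\t{v.start}\t{v.id}\t{anchor + v.deleted_seq}\t"
                     f"{anchor}\t.\t.\t{';'.join(sorted(info))}\n")


def deduplicate(
    variants: Iterable[DeletionVariant],
    genome: GenomeSequence,
    **canon_kwargs,
) -> List[DeletionVariant]:
    """Collapse records describing the same deletion.

    Two records are duplicates when they share (contig, canonical start
    after shifting, deletion length).  The survivor keeps the richest
    clinical-significance annotation; records merged across sources are
    marked ``source="merged"``.
    """
    from .microhomology import canonicalize  # deferred: avoids import cycle

    best: Dict[Tuple[str, int, int], DeletionVariant] = {}
    for var in variants:
        canon = canonicalize(genome, var, **canon_kwargs)
        key = (var.chrom, canon.variant.start, var.n)
        prev = best.get(key)
        if prev is None:
            best[key] = var
            continue
        keep, drop = (prev, var) if len(prev.clin_sig) >= len(var.clin_sig) else (var, prev)
        merged_clin = keep.clin_sig + tuple(c for c in drop.clin_sig if c not in keep.clin_sig)
        source = keep.source if keep.source == drop.source else "merged"
        best[key] = replace(keep, clin_sig=merged_clin, source=source)
    return list(best.values())


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_FEATURE_MAP = {
    "CDS": "CDS",
    "UTR": "UTR",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "5UTR": "UTR",
    "3UTR": "UTR",
    "exon": "exon",
    "gene": "gene",
}


@dataclass
class AnnotationIndex:
    """Interval store of {CDS, UTR, exon, gene} features per contig."""

    trees: Dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, feature: str) -> None:
        if end <= start:
            return
        self.trees.setdefault(chrom, IntervalTree())[start:end] = feature

    def overlapping_types(self, chrom: str, start: int, end: int) -> set:
        """Feature types overlapping [start, end); exact half-open semantics."""
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def load_annotation(path: str | Path) -> AnnotationIndex:
    """Load a GFF3 file or a typed BED file into an :class:`AnnotationIndex`.

    GFF3 uses 1-based closed coordinates; BED is already 0-based half-open.
    The BED dialect expected here carries the feature type in column 7
    (chrom, start, end, name, score, strand, type).  Unknown feature types
    are ignored with a warning.
    """
    path = Path(path)
    index = AnnotationIndex()
    unknown: set = set()
    if path.suffix.lower() in {".bed"}:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 7:
                    raise ValueError("typed BED requires 7 columns (feature type in column 7)")
                ftype = _FEATURE_MAP.get(fields[6])
                if ftype is None:
                    unknown.add(fields[6])
                    continue
                index.add(fields[0], int(fields[1]), int(fields[2]), ftype)
    else:
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
        for feat in db.all_features():
            ftype = _FEATURE_MAP.get(feat.featuretype)
            if ftype is None:
                unknown.add(feat.featuretype)
                continue
            # GFF3 closed 1-based [start, end] -> half-open 0-based [start-1, end)
            index.add(feat.seqid, feat.start - 1, feat.end, ftype)
    for ftype in sorted(unknown):
        logger.warning("ignoring unknown feature type %r in %s", ftype, path.name)
    return index


# ---------------------------------------------------------------------------
# Small tabular helpers
# ---------------------------------------------------------------------------

def variants_to_frame(variants: Iterable[DeletionVariant]) -> pd.DataFrame:
    rows = [
        {"id": v.id, "chrom": v.chrom, "start": v.start, "end": v.end,
         "del_len": v.n, "deleted_seq": v.deleted_seq, "source": v.source,
         "clin_sig": ",".join(v.clin_sig)}
        for v in variants
    ]
    return pd.DataFrame(rows)
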