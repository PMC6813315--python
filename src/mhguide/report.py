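"""Genic annotation, clinical classification, filtering and report output.

This module assembles the full analysis: canonicalize each deletion, pick
its flanking microhomology, enumerate and vet guides, and emit a
variant-level table, a guide-level table and a JSON run summary.  Filters
mirror the selection funnel used when screening deletion databases:
deletion length, µH length, guide availability/uniqueness, absence of
nested µHs, genomic context and clinical significance.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_formats import AnnotationIndex, DeletionVariant, GenomeSequence
from .microhomology import CanonicalVariant, canonicalize
from .guides import GuideCandidate, PamMotif, enumerate_guides
from .offtarget import annotate_offtargets, build_index, index_length, KmerIndex
from .nested import annotate_nested, variant_nested_summary


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the analysis, echoed into the run summary."""

    min_del_len: int = 3
    min_mh_len: int = 3
    max_mismatch: int = 1
    anchor_before_mismatch: int = 1
    pams: Tuple[str, ...] = ("NGG",)
    protospacer_len: int = 20
    max_cut_dist: int = 50
    require_both_within: bool = False
    expand_pam: bool = True
    nested_min_len: int = 3
    max_del_len: int = 10_000

    def motifs(self) -> List[PamMotif]:
        return [PamMotif(p, protospacer_len=self.protospacer_len) for p in self.pams]


@dataclass
class VariantReport:
    """One row of the variant-level output."""

    id: str
    chrom: str
    start: int
    end: int
    del_len: int
    source: str
    clin_sig_raw: str
    clin_category: str        # pathogenic | benign | VUS/other | none
    gene_context: str         # exonic | UTR | intronic | intergenic
    frameshift: bool
    shift_offset: int
    flank_config: str
    mhL: int
    mh1L: int
    matches: int
    hom: float
    gc: float
    dist: int
    dist_exact: int
    mh_seq: str
    n_pam_candidates: int = 0
    n_valid_guides: int = 0
    n_unique_guides: int = 0
    n_guides_no_nested: int = 0
    nested_count: int = -1
    nested_strength: float = 0.0
    best_guide_id: str = ""


def classify_context(variant: DeletionVariant, annotation: Optional[AnnotationIndex]) -> str:
    """Genic context by any-overlap with precedence CDS > UTR > exon > gene."""
    if annotation is None:
        return "intergenic"
    types = annotation.overlapping_types(variant.chrom, variant.start, variant.end)
    if "CDS" in types:
        return "exonic"
    if "UTR" in types:
        return "UTR"
    if "exon" in types:
        return "exonic"
    if "gene" in types:
        return "intronic"
    return "intergenic"


def is_frameshift(variant: DeletionVariant, gene_context: str) -> bool:
    """A coding deletion shifts the reading frame unless its length is a multiple of 3."""
    return gene_context == "exonic" and variant.n % 3 != 0


_WORD = re.compile(r"[a-z]+")


def clin_category(labels: Sequence[str], substring: bool = False) -> str:
    """Collapse clinical-significance labels into one category.

    By default the token ``pathogenic`` must appear as a whole word
    (``"Likely pathogenic"`` counts, ``"...pathogenicity"`` does not);
    ``substring=True`` switches to plain substring containment.  Pathogenic
    outranks benign when both appear.
    """
    if not labels or all(not l.strip() for l in labels):
        return "none"
    text = " ".join(labels).lower()
    if substring:
        has_path = "pathogenic" in text
        has_benign = "benign" in text
    else:
        tokens = set(_WORD.findall(text))
        has_path = "pathogenic" in tokens
        has_benign = "benign" in tokens
    if has_path:
        return "pathogenic"
    if has_benign:
        return "benign"
    return "VUS/other"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def analyze_variant(
    genome: GenomeSequence,
    variant: DeletionVariant,
    params: PipelineParams,
    annotation: Optional[AnnotationIndex] = None,
    kmer_index: Optional[KmerIndex] = None,
) -> Tuple[VariantReport, CanonicalVariant, List[GuideCandidate]]:
    """Run the full per-variant analysis; guides require an off-target index."""
    canon = canonicalize(genome, variant, params.max_mismatch,
                         params.anchor_before_mismatch)
    var = canon.variant
    mh = canon.best_mh
    context = classify_context(var, annotation)
    report = VariantReport(
        id=var.id, chrom=var.chrom, start=var.start, end=var.end,
        del_len=var.n, source=var.source,
        clin_sig_raw=",".join(var.clin_sig),
        clin_category=clin_category(var.clin_sig),
        gene_context=context,
        frameshift=is_frameshift(var, context),
        shift_offset=canon.shift_offset,
        flank_config=mh.config.value,
        mhL=mh.mhL, mh1L=mh.mh1L, matches=mh.matches,
        hom=round(mh.hom, 4), gc=round(mh.gc, 4),
        dist=mh.dist, dist_exact=mh.dist_exact, mh_seq=mh.mh_seq,
    )

    guides: List[GuideCandidate] = []
    if mh.mhL >= params.min_mh_len and var.n >= params.min_del_len:
        guides = enumerate_guides(
            genome, canon, params.motifs(),
            max_cut_dist=params.max_cut_dist,
            require_both_within=params.require_both_within,
            restrict_near_mh=var.n > params.max_del_len,
        )
        if kmer_index is not None:
            guides = annotate_offtargets(guides, kmer_index, params.expand_pam)
        guides = annotate_nested(genome, canon, guides, params.nested_min_len)

        report.n_pam_candidates = len(guides)
        report.n_valid_guides = sum(g.valid for g in guides)
        report.n_unique_guides = sum(g.valid and g.is_unique for g in guides)
        report.n_guides_no_nested = sum(
            g.valid and g.is_unique and g.nested_count == 0 for g in guides)
        n_count, n_strength, best = variant_nested_summary(guides)
        report.nested_count = n_count
        report.nested_strength = round(n_strength, 2)
        report.best_guide_id = best.guide_id if best is not None else ""
    return report, canon, guides


def run_pipeline(
    genome: GenomeSequence,
    variants: Iterable[DeletionVariant],
    params: PipelineParams = PipelineParams(),
    annotation: Optional[AnnotationIndex] = None,
) -> Tuple[List[VariantReport], List[GuideCandidate]]:
    """Analyze a collection of deletions against one genome."""
    index = build_index(genome, index_length(params.motifs()))
    reports: List[VariantReport] = []
    guides: List[GuideCandidate] = []
    for variant in variants:
        rep, _, g = analyze_variant(genome, variant, params, annotation, index)
        reports.append(rep)
        guides.extend(gg for gg in g if gg.valid)
    return reports, guides


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterCriteria:
    """Conjunctive variant-level filters; ``None`` disables a criterion."""

    min_del_len: Optional[int] = None
    min_mh_len: Optional[int] = None
    require_unique_guide: bool = False
    require_no_nested: bool = False
    gene_contexts: Optional[Tuple[str, ...]] = None
    clin_categories: Optional[Tuple[str, ...]] = None
    max_dist: Optional[int] = None


def apply_filters(
    reports: Sequence[VariantReport],
    criteria: FilterCriteria,
) -> Tuple[List[VariantReport], Dict[str, int]]:
    """Apply the selection funnel; returns survivors and per-stage counts.

    Stages are applied in a fixed order and each count reflects the
    survivors after that stage, so the funnel is non-increasing.
    """
    funnel: Dict[str, int] = {"input": len(reports)}
    current = list(reports)

    def stage(name: str, pred) -> None:
        nonlocal current
        current = [r for r in current if pred(r)]
        funnel[name] = len(current)

    if criteria.min_del_len is not None:
        stage("min_del_len", lambda r: r.del_len >= criteria.min_del_len)
    if criteria.min_mh_len is not None:
        stage("min_mh_len", lambda r: r.mhL >= criteria.min_mh_len)
    if criteria.require_unique_guide:
        stage("unique_guide", lambda r: r.n_unique_guides > 0)
    if criteria.require_no_nested:
        stage("no_nested", lambda r: r.n_guides_no_nested > 0)
    if criteria.gene_contexts is not None:
        stage("gene_context", lambda r: r.gene_context in criteria.gene_contexts)
    if criteria.clin_categories is not None:
        stage("clin_category", lambda r: r.clin_category in criteria.clin_categories)
    if criteria.max_dist is not None:
        stage("max_dist", lambda r: r.dist <= criteria.max_dist)
    return current, funnel


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_GUIDE_COLUMNS = [
    "variant_id", "guide_id", "chrom", "protospacer", "pam", "motif", "strand",
    "pam_start", "cut_pos", "dist_left", "dist_right", "valid",
    "offtarget_count", "is_unique", "nested_count", "nested_strength",
    "nested_strength_sum",
]


def write_reports(
    reports: Sequence[VariantReport],
    guides: Sequence[GuideCandidate],
    prefix: str | Path,
    params: Optional[PipelineParams] = None,
    funnel: Optional[Dict[str, int]] = None,
    input_stats: Optional[Dict[str, int]] = None,
    indelphi: Optional[Dict[str, float]] = None,
) -> Dict[str, Path]:
    """Write ``<prefix>-variants.tsv``, ``<prefix>-guides.tsv`` and
    ``<prefix>-summary.json`` with deterministic row order.

    ``indelphi`` optionally maps guide ids to precomputed repair-outcome
    prevalences; the values are passed through as an extra column, never
    computed here.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": prefix.parent / (prefix.name + "-variants.tsv"),
        "guides": prefix.parent / (prefix.name + "-guides.tsv"),
        "summary": prefix.parent / (prefix.name + "-summary.json"),
    }

    var_order = {r.id: (r.chrom, r.start, r.id) for r in reports}
    sorted_reports = sorted(reports, key=lambda r: (r.chrom, r.start, r.id))
    var_cols = [f.name for f in dataclasses.fields(VariantReport)]
    with open(paths["variants"], "w") as fh:
        fh.write("\t".join(var_cols) + "\n")
        for r in sorted_reports:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in var_cols) + "\n")

    known_ids = set(var_order)
    guide_rows = [g for g in guides if g.variant_id in known_ids]
    guide_rows.sort(key=lambda g: (var_order[g.variant_id], g.cut_pos, g.strand))
    cols = list(_GUIDE_COLUMNS) + (["indelphi_prevalence"] if indelphi else [])
    with open(paths["guides"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in guide_rows:
            row = [_fmt(getattr(g, c)) if c != "guide_id" else g.guide_id
                   for c in _GUIDE_COLUMNS]
            if indelphi:
                row.append(_fmt(indelphi.get(g.guide_id, "")))
            fh.write("\t".join(row) + "\n")

    summary = {
        "n_variants": len(reports),
        "n_guides": len(guide_rows),
        "params": dataclasses.asdict(params) if params else None,
        "funnel": funnel,
        "input_stats": input_stats,
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.4f}".rstrip("0").rstrip(".") if value == value else "nan"
    return str(value)
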