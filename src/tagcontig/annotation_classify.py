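"""Classification of tag-contigs against genome annotation.

A TC is attributed to an annotation class when at least 20% of the TC's
length overlaps features of that class (the denominator is the TC, not the
feature).  Context resolution is prioritised: annotated ncRNA > exon >
repeat > intron (sense/antisense by host-gene strand) > intergenic; a TC is
intergenic only when its overlap with gene spans is below 20%.

The module also produces the ncRNA coverage report (how many annotated
ncRNAs of each class are touched by TCs, covered >= 70% by the TC union, or
covered >= 70% by a single TC) and the conservation flag (>= 15 bp overlap
with a single conserved element).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .contig_assembly import TagContig
from .io_formats import (
    NCRNA_CLASSES,
    REPEAT_CLASSES,
    AnnotationFeature,
    FeatureClass,
)

#: Minimum fraction of a TC's length that must overlap a feature class for the
#: TC to be classified as derived from it.
OVERLAP_FRACTION_MIN = 0.20

#: Minimum single-element overlap (bp) for a tag or TC to count as conserved.
CONSERVED_OVERLAP_MIN = 15


class TcContext(str, Enum):
    EXONIC = "exonic"
    INTRONIC_SENSE = "intronic_sense"
    INTRONIC_ANTISENSE = "intronic_antisense"
    INTERGENIC = "intergenic"
    REPEAT = "repeat"
    NCRNA_ANNOTATED = "ncRNA_annotated"


@dataclass
class TcClassification:
    tc: TagContig
    overlap_fractions: dict[FeatureClass, float]
    context: TcContext
    host_gene: Optional[str] = None
    conserved: bool = False


class AnnotationIndex:
    """Interval index over annotation features, per chromosome."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[AnnotationFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.end, f.feature_class.value, f.name))
        return hits


def union_overlap_bases(
    start: int, end: int, intervals: Iterable[tuple[int, int]]
) -> int:
    """Bases of ``[start, end)`` covered by the union of ``intervals``."""
    clipped = sorted(
        (max(start, s), min(end, e)) for s, e in intervals if s < end and e > start
    )
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def classify_tc(
    tc: TagContig,
    features: Union[AnnotationIndex, Sequence[AnnotationFeature]],
    conserved_elements: Sequence[AnnotationFeature] = (),
) -> TcClassification:
    """Classify one TC against annotation (20% rule, prioritised context)."""
    index = features if isinstance(features, AnnotationIndex) else AnnotationIndex(features)
    hits = index.overlapping(tc.chrom, tc.start, tc.end)

    by_class: dict[FeatureClass, list[tuple[int, int]]] = {}
    for f in hits:
        by_class.setdefault(f.feature_class, []).append((f.start, f.end))
    fractions = {
        fc: union_overlap_bases(tc.start, tc.end, ivs) / tc.length
        for fc, ivs in by_class.items()
    }

    def class_union(classes: Iterable[FeatureClass]) -> float:
        ivs = [iv for fc in classes for iv in by_class.get(fc, [])]
        return union_overlap_bases(tc.start, tc.end, ivs) / tc.length

    ncrna_frac = class_union(NCRNA_CLASSES)
    exon_frac = fractions.get(FeatureClass.EXON, 0.0)
    repeat_frac = class_union(REPEAT_CLASSES)
    intron_frac = fractions.get(FeatureClass.INTRON, 0.0)
    gene_frac = fractions.get(FeatureClass.GENE, 0.0)

    host_gene: Optional[str] = None
    genes = [f for f in hits if f.feature_class is FeatureClass.GENE]
    if genes:
        host = max(genes, key=lambda g: (g.overlap(tc.start, tc.end), g.name))
        host_gene = host.name

    if ncrna_frac >= OVERLAP_FRACTION_MIN:
        context = TcContext.NCRNA_ANNOTATED
    elif exon_frac >= OVERLAP_FRACTION_MIN:
        context = TcContext.EXONIC
    elif repeat_frac >= OVERLAP_FRACTION_MIN:
        context = TcContext.REPEAT
    elif intron_frac >= OVERLAP_FRACTION_MIN or gene_frac >= OVERLAP_FRACTION_MIN:
        # genic but not exonic: intronic; sense requires matching host strand
        strand_src = None
        introns = [f for f in hits if f.feature_class is FeatureClass.INTRON]
        if introns:
            best = max(introns, key=lambda f: (f.overlap(tc.start, tc.end), f.name))
            strand_src = best.strand
            if host_gene is None:
                host_gene = best.name.rsplit("_intron", 1)[0]
        elif genes:
            strand_src = max(
                genes, key=lambda g: (g.overlap(tc.start, tc.end), g.name)
            ).strand
        if strand_src == tc.strand:
            context = TcContext.INTRONIC_SENSE
        else:
            context = TcContext.INTRONIC_ANTISENSE
    else:
        context = TcContext.INTERGENIC
        host_gene = None

    conserved = flag_conserved((tc.chrom, tc.start, tc.end), conserved_elements)
    return TcClassification(tc, fractions, context, host_gene, conserved)


def classify_all(
    tcs: Sequence[TagContig],
    features: Sequence[AnnotationFeature],
    conserved_elements: Sequence[AnnotationFeature] = (),
) -> dict[TagContig, TcClassification]:
    index = AnnotationIndex(features)
    cons_index = AnnotationIndex(conserved_elements) if conserved_elements else None
    out: dict[TagContig, TcClassification] = {}
    for tc in tcs:
        cons = (
            cons_index.overlapping(tc.chrom, tc.start, tc.end)
            if cons_index is not None else ()
        )
        out[tc] = classify_tc(tc, index, cons)
    return out


def flag_conserved(
    tc_or_tag: Union[TagContig, tuple[str, int, int]],
    elements: Sequence[AnnotationFeature],
    min_overlap: int = CONSERVED_OVERLAP_MIN,
) -> bool:
    """True iff a *single* conserved element overlaps the interval >= ``min_overlap`` bp."""
    if isinstance(tc_or_tag, tuple):
        chrom, start, end = tc_or_tag
    else:
        chrom, start, end = tc_or_tag.chrom, tc_or_tag.start, tc_or_tag.end
    for el in elements:
        if el.chrom == chrom and el.overlap(start, end) >= min_overlap:
            return True
    return False


# ---------------------------------------------------------------------------
# ncRNA coverage report
# ---------------------------------------------------------------------------

def format_percent(numerator: int, denominator: int) -> str:
    """Percentage rendered to 1 decimal with half-up rounding; N/A when empty."""
    if denominator == 0:
        return "N/A"
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ClassCoverage:
    n_annotated: int
    n_overlapped: int = 0
    n_cov70: int = 0
    n_cov70_single: int = 0

    def as_row(self) -> dict:
        return {
            "annotated": self.n_annotated,
            "overlapped": self.n_overlapped,
            "overlapped_pct": format_percent(self.n_overlapped, self.n_annotated),
            "cov70": self.n_cov70,
            "cov70_pct": format_percent(self.n_cov70, self.n_annotated),
            "cov70_single": self.n_cov70_single,
            "cov70_single_pct": format_percent(self.n_cov70_single, self.n_annotated),
        }


@dataclass
class CoverageReport:
    """Per-ncRNA-class TC coverage counts with rendered percentages."""

    classes: dict[FeatureClass, ClassCoverage] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {fc.value: cov.as_row() for fc, cov in self.classes.items()}
        return pd.DataFrame.from_dict(rows, orient="index")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ncRNA_class")


#: Coverage threshold (fraction of the ncRNA's length) for the "well covered"
#: report columns.
COVERAGE_THRESHOLD = 0.70


def _strand_compatible(feature_strand: str, tc_strand: str) -> bool:
    return feature_strand == "." or feature_strand == tc_strand


def coverage_report(
    features: Sequence[AnnotationFeature],
    tcs: Sequence[TagContig],
    classes: Iterable[FeatureClass] = tuple(sorted(NCRNA_CLASSES, key=lambda c: c.value)),
) -> CoverageReport:
    """Coverage of annotated ncRNAs by same-strand TCs.

    An ncRNA counts as overlapped when at least one same-strand TC intersects
    it by >= 1 base; the >= 70% columns use the per-base union of same-strand
    TCs, and the single-TC column requires one TC alone to reach 70%.
    """
    wanted = set(classes)
    tc_index: dict[str, IntervalTree] = {}
    for tc in tcs:
        tc_index.setdefault(tc.chrom, IntervalTree()).addi(tc.start, tc.end, tc)

    report = CoverageReport({fc: ClassCoverage(0) for fc in sorted(wanted, key=lambda c: c.value)})
    for f in features:
        if f.feature_class not in wanted:
            continue
        cov = report.classes[f.feature_class]
        cov.n_annotated += 1
        tree = tc_index.get(f.chrom)
        if tree is None:
            continue
        same = [
            iv.data for iv in tree.overlap(f.start, f.end)
            if _strand_compatible(f.strand, iv.data.strand)
        ]
        if not same:
            continue
        cov.n_overlapped += 1
        union = union_overlap_bases(f.start, f.end, ((t.start, t.end) for t in same))
        if union >= COVERAGE_THRESHOLD * f.length:
            cov.n_cov70 += 1
        if any(t.overlap(f.start, f.end) >= COVERAGE_THRESHOLD * f.length for t in same):
            cov.n_cov70_single += 1
    return report
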