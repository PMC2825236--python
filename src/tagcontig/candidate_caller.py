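"""End-to-end orchestration of the tag-contig discovery cascade.

The pipeline composes the stages deterministically:

    map -> distribute -> assemble -> classify -> exclude annotated
        -> strand-competition filter
        -> { H/ACA window + motifs, C/D window + motifs, group banding }

Every TC receives at most one candidate class.  snoRNA calls take precedence
over group banding, and the C/D window runs on TCs not already consumed by
the H/ACA window (sequential exclusion).  H/ACA-windowed TCs that fail the
motif checks are emitted as an "snRNA_like / unresolved" sidecar list for
manual follow-up, since snRNA identification proper requires external
homology evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .annotation_classify import (
    CoverageReport,
    TcClassification,
    TcContext,
    classify_all,
    coverage_report,
)
from .contig_assembly import TagContig, build_tag_contigs_with_members
from .filters import (
    CD_CONTEXTS,
    HACA_CONTEXTS,
    UNANNOTATED_CONTEXTS,
    FilterConfig,
    assign_group,
    strand_competition_filter,
    window_filter,
)
from .io_formats import (
    AnnotationFeature,
    Genome,
    TagRecord,
    merge_tag_records,
    write_tc_bed,
)
from .mapping import MappedTag, distribute_reads, map_tags_exact
from .motif_search import MotifHit, call_box_cd, call_box_haca, genome_kmer_scan

logger = logging.getLogger("tagcontig")


class CallClass(str, Enum):
    SNORNA_HACA = "snoRNA_HACA"
    SNORNA_CD = "snoRNA_CD"
    SNRNA_LIKE = "snRNA_like"
    GROUP1 = "group1"
    GROUP2 = "group2"
    GROUP3 = "group3"


@dataclass
class CandidateCall:
    """A TC promoted to a candidate ncRNA with its motif evidence."""

    tc: TagContig
    call_class: CallClass
    motif_evidence: tuple[MotifHit, ...] = ()
    host_gene: Optional[str] = None
    dominant_tag: Optional[tuple[str, float]] = None
    conserved: bool = False


@dataclass
class PipelineResult:
    tcs: list[TagContig]
    calls: list[CandidateCall]
    coverage: CoverageReport
    classifications: dict[TagContig, TcClassification]
    members: dict[TagContig, list[MappedTag]]
    tags: list[TagRecord]
    placements: list[MappedTag]
    stage_counts: dict[str, float] = field(default_factory=dict)

    def calls_of(self, call_class: CallClass) -> list[CandidateCall]:
        return [c for c in self.calls if c.call_class is call_class]


def dominant_tag_analysis(
    call: CandidateCall,
    members: Sequence[MappedTag],
    tags: Sequence[TagRecord],
) -> tuple[str, float]:
    """Most abundant member sequence of a TC and its fraction of TC weight.

    Abundance is the summed placement weight per distinct member sequence;
    ties break lexicographically (smallest sequence wins).
    """
    if not members:
        raise ValueError("dominant_tag_analysis: call has no member tags")
    seq_of = {t.tag_id: t.sequence for t in tags}
    weight_by_seq: dict[str, float] = {}
    total = 0.0
    for m in members:
        seq = seq_of[m.tag_id]
        weight_by_seq[seq] = weight_by_seq.get(seq, 0.0) + m.weight
        total += m.weight
    best_seq = max(sorted(weight_by_seq), key=lambda s: weight_by_seq[s])
    return best_seq, weight_by_seq[best_seq] / total


def _candidate_table(calls: Sequence[CandidateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "name": c.tc.name,
            "class": c.call_class.value,
            "chrom": c.tc.chrom,
            "start": c.tc.start,
            "end": c.tc.end,
            "strand": c.tc.strand,
            "length": c.tc.length,
            "tag_depth": c.tc.tag_depth,
            "host_gene": c.host_gene or "",
            "conserved": c.conserved,
            "motifs": ";".join(
                f"{h.motif}@{h.tc_offset}mm{h.mismatches}" for h in c.motif_evidence
            ),
            "dominant_tag": c.dominant_tag[0] if c.dominant_tag else "",
            "dominant_tag_fraction": (
                round(c.dominant_tag[1], 6) if c.dominant_tag else ""
            ),
        })
    return pd.DataFrame(
        rows,
        columns=[
            "name", "class", "chrom", "start", "end", "strand", "length",
            "tag_depth", "host_gene", "conserved", "motifs", "dominant_tag",
            "dominant_tag_fraction",
        ],
    )


def _classification_table(
    classifications: Mapping[TagContig, TcClassification]
) -> pd.DataFrame:
    rows = []
    for tc, cls in classifications.items():
        rows.append({
            "name": tc.name,
            "chrom": tc.chrom,
            "start": tc.start,
            "end": tc.end,
            "strand": tc.strand,
            "length": tc.length,
            "tag_depth": tc.tag_depth,
            "context": cls.context.value,
            "host_gene": cls.host_gene or "",
            "conserved": cls.conserved,
        })
    df = pd.DataFrame(
        rows,
        columns=[
            "name", "chrom", "start", "end", "strand", "length", "tag_depth",
            "context", "host_gene", "conserved",
        ],
    )
    return df.sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)


def run_pipeline(
    genome: Genome,
    tag_libraries: Union[Sequence[TagRecord], Sequence[Sequence[TagRecord]]],
    annotation: Sequence[AnnotationFeature],
    conserved_elements: Sequence[AnnotationFeature] = (),
    config: Optional[FilterConfig] = None,
    premapped: Optional[Sequence[MappedTag]] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full discovery cascade and return TCs, calls and the
    ncRNA coverage report.

    ``tag_libraries`` may be one tag list or several (merged by summing read
    counts of identical sequences).  ``premapped`` placements, when given,
    bypass the built-in exact matcher.  With ``out_dir`` all intermediate
    tables are persisted (TC BED, classification TSV, coverage TSV,
    candidate TSV, stage-count funnel).
    """
    config = config or FilterConfig()

    if tag_libraries and isinstance(tag_libraries[0], TagRecord):
        tags = merge_tag_records(tag_libraries)  # type: ignore[arg-type]
    else:
        tags = merge_tag_records(
            rec for lib in tag_libraries for rec in lib  # type: ignore[union-attr]
        )
    counts: dict[str, float] = {"tags": len(tags)}
    logger.info("stage tags: %d distinct tag sequences", len(tags))

    try:
        raw = list(premapped) if premapped is not None else map_tags_exact(genome, tags)
    except Exception as exc:
        raise RuntimeError(f"stage mapping failed: {exc}") from exc
    counts["placements"] = len(raw)

    placements = distribute_reads(raw, tags)
    counts["placements_weighted"] = len(placements)
    counts["read_mass"] = sum(p.weight for p in placements)
    logger.info(
        "stage mapping: %d placements, %d after discard rule",
        len(raw), len(placements),
    )

    tcs, members = build_tag_contigs_with_members(placements)
    counts["tag_contigs"] = len(tcs)
    logger.info("stage assembly: %d tag-contigs", len(tcs))

    classifications = classify_all(tcs, annotation, conserved_elements)
    coverage = coverage_report(annotation, tcs)

    unannotated = [
        tc for tc in tcs if classifications[tc].context in UNANNOTATED_CONTEXTS
    ]
    counts["unannotated"] = len(unannotated)

    selected = strand_competition_filter(unannotated, config, competitors=tcs)
    counts["strand_filtered"] = len(selected)
    logger.info(
        "stage selection: %d unannotated, %d after %gx strand filter",
        len(unannotated), len(selected), config.strand_ratio_min,
    )

    calls: list[CandidateCall] = []
    called: set[TagContig] = set()

    def _mk_call(tc: TagContig, cls: CallClass, evidence=()) -> CandidateCall:
        c = classifications[tc]
        call = CandidateCall(
            tc=tc, call_class=cls, motif_evidence=tuple(evidence),
            host_gene=c.host_gene, conserved=c.conserved,
        )
        if tc.length < config.short_len_max and members.get(tc):
            call.dominant_tag = dominant_tag_analysis(call, members[tc], tags)
        return call

    # box H/ACA window, then motif checks; failures go to the snRNA-like sidecar
    haca_windowed = window_filter(
        selected, classifications, config.haca_len, config.haca_depth_min,
        HACA_CONTEXTS,
    )
    for tc in haca_windowed:
        pair = call_box_haca(tc, genome)
        if pair is not None:
            calls.append(_mk_call(tc, CallClass.SNORNA_HACA, pair))
        else:
            calls.append(_mk_call(tc, CallClass.SNRNA_LIKE))
        called.add(tc)
    counts["haca_windowed"] = len(haca_windowed)

    # box C/D window on TCs not consumed above (sequential exclusion)
    cd_windowed = window_filter(
        [tc for tc in selected if tc not in called],
        classifications, config.cd_len, config.cd_depth_min, CD_CONTEXTS,
    )
    for tc in cd_windowed:
        pair = call_box_cd(tc, genome)
        if pair is not None:
            calls.append(_mk_call(tc, CallClass.SNORNA_CD, pair))
            called.add(tc)
    counts["cd_windowed"] = len(cd_windowed)

    # group banding of the remaining highly expressed TCs
    group_class = {
        "group1": CallClass.GROUP1,
        "group2": CallClass.GROUP2,
        "group3": CallClass.GROUP3,
    }
    for tc in selected:
        if tc in called or tc.name in config.exclusion_ids:
            continue
        if tc.tag_depth < config.group_depth_min:
            continue
        group = assign_group(tc, config)
        if group in group_class:
            calls.append(_mk_call(tc, group_class[group]))
            called.add(tc)

    # rank within each class by tag-depth, descending
    order = {cls: i for i, cls in enumerate(CallClass)}
    calls.sort(key=lambda c: (order[c.call_class], -c.tc.tag_depth, c.tc.name))
    for cls in CallClass:
        counts[f"calls_{cls.value}"] = sum(1 for c in calls if c.call_class is cls)
    logger.info(
        "stage calling: %s",
        ", ".join(f"{cls.value}={int(counts[f'calls_{cls.value}'])}" for cls in CallClass),
    )

    result = PipelineResult(
        tcs=tcs, calls=calls, coverage=coverage,
        classifications=classifications, members=members,
        tags=tags, placements=placements, stage_counts=counts,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tc_bed(tcs, out / "tag_contigs.bed")
        _classification_table(classifications).to_csv(
            out / "tc_classification.tsv", sep="\t", index=False
        )
        coverage.write_tsv(out / "coverage_report.tsv")
        _candidate_table(calls).to_csv(out / "candidates.tsv", sep="\t", index=False)
        pd.Series(counts, name="count").to_csv(
            out / "stage_counts.tsv", sep="\t", index_label="stage"
        )
    return result


def motif_site_census(
    genome: Genome,
    kmer: str,
    max_mismatches: int,
    annotation: Sequence[AnnotationFeature],
) -> pd.DataFrame:
    """Cross-tabulate genome-wide k-mer sites by mismatch stratum and
    annotation context.

    Each site interval is classified with the same 20% rules used for TCs
    (a site is a short interval, so in practice it lands wholly in one
    context).  Returns a tidy table (mismatches, context, count) whose count
    total equals the number of scan hits.
    """
    from .annotation_classify import AnnotationIndex, classify_tc

    hits = genome_kmer_scan(genome, kmer, max_mismatches)
    index = AnnotationIndex(annotation)
    tallies: dict[tuple[int, str], int] = {}
    for h in hits:
        pseudo = TagContig(
            chrom=h.chrom, start=h.start, end=h.start + len(h.matched_sequence),
            strand=h.strand, tag_depth=0.0, n_tags=0, n_reads=0.0,
        )
        ctx = classify_tc(pseudo, index).context.value
        tallies[(h.mismatches, ctx)] = tallies.get((h.mismatches, ctx), 0) + 1
    rows = [
        {"mismatches": mm, "context": ctx, "count": n}
        for (mm, ctx), n in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["mismatches", "context", "count"])
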