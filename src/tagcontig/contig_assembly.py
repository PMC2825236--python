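"""Strand-specific tag-contig assembly and tag-depth scoring.

A tag-contig (TC) is a maximal genomic interval, on one strand, covered by
placements that contiguously overlap each other by at least 1 nt.  Abutting
placements (one ending exactly where the next starts) do NOT merge.  Each
TC's tag-depth is the maximum over its bases of the summed read weights of
the placements covering that base — the expression score used by every
downstream filter.

Depth is computed on coordinate-compressed segments between placement
endpoints; within a segment the covering members' weights are summed in a
fixed (start, end, tag_id) order so the result is bit-identical to a literal
per-base accumulation that sums members in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .mapping import MappedTag


@dataclass(frozen=True)
class TagContig:
    """A strand-specific genomic interval with tag-depth and composition stats."""

    chrom: str
    start: int
    end: int
    strand: str
    tag_depth: float
    n_tags: int
    n_reads: float
    member_tag_ids: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def _member_order(members: Iterable[MappedTag]) -> list[MappedTag]:
    return sorted(members, key=lambda m: (m.start, m.end, m.tag_id))


def _depth_of(members: Sequence[MappedTag]) -> float:
    """Max per-base weight sum over compressed segments, in fixed member order."""
    ordered = _member_order(members)
    breaks = sorted({m.start for m in ordered} | {m.end for m in ordered})
    best = 0.0
    for b in breaks[:-1]:
        cov = 0.0
        for m in ordered:
            if m.start <= b < m.end:
                cov += m.weight
        if cov > best:
            best = cov
    return best


def compute_tag_depth(tc: TagContig, members: Sequence[MappedTag]) -> float:
    """Tag-depth of ``tc``: max over bases of summed member weights.

    Members must lie within the TC interval on the TC's strand.
    """
    if not members:
        raise ValueError("compute_tag_depth: empty member list")
    for m in members:
        if m.chrom != tc.chrom or m.strand != tc.strand:
            raise ValueError(f"member {m.tag_id} not on TC chrom/strand")
        if m.start < tc.start or m.end > tc.end:
            raise ValueError(f"member {m.tag_id} outside TC interval")
    return _depth_of(members)


def build_tag_contigs_with_members(
    placements: Sequence[MappedTag],
) -> tuple[list[TagContig], dict[TagContig, list[MappedTag]]]:
    """Assemble TCs and return them with their member placements.

    Per (chrom, strand), TCs are the connected components of the >= 1-nt
    overlap graph — equivalently, maximal runs under a start-sorted sweep
    where a placement with ``start < current_end`` extends the run.
    """
    by_group: dict[tuple[str, str], list[MappedTag]] = {}
    for p in placements:
        by_group.setdefault((p.chrom, p.strand), []).append(p)

    tcs: list[TagContig] = []
    members_of: dict[TagContig, list[MappedTag]] = {}
    for (chrom, strand) in sorted(by_group):
        run: list[MappedTag] = []
        run_end = -1

        def _flush() -> None:
            if not run:
                return
            ordered = _member_order(run)
            start = ordered[0].start
            end = max(m.end for m in ordered)
            n_reads = 0.0
            for m in ordered:
                n_reads += m.weight
            tc = TagContig(
                chrom=chrom, start=start, end=end, strand=strand,
                tag_depth=_depth_of(ordered), n_tags=len(ordered),
                n_reads=n_reads,
                member_tag_ids=tuple(m.tag_id for m in ordered),
            )
            tcs.append(tc)
            members_of[tc] = ordered

        for p in sorted(by_group[(chrom, strand)], key=lambda m: (m.start, m.end, m.tag_id)):
            if run and p.start < run_end:
                run.append(p)
                run_end = max(run_end, p.end)
            else:
                _flush()
                run = [p]
                run_end = p.end
        _flush()

    tcs.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand))
    return tcs, members_of


def build_tag_contigs(placements: Sequence[MappedTag]) -> list[TagContig]:
    """Assemble strand-specific tag-contigs from weighted placements."""
    tcs, _ = build_tag_contigs_with_members(placements)
    return tcs
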