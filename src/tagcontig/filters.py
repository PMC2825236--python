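"""Selection cascade for unannotated tag-contigs.

Stages, in pipeline order: annotation exclusion (handled by the caller via
TC context), the 10x opposite-strand depth filter that removes
transposon-like double-stranded signal, size/tag-depth windows matched to
the box H/ACA and box C/D snoRNA classes, and the depth banding of the
remaining highly expressed TCs into groups 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from intervaltree import IntervalTree

from .annotation_classify import TcClassification, TcContext
from .contig_assembly import TagContig


@dataclass
class FilterConfig:
    """Thresholds of the candidate-selection cascade.

    Defaults are the study conditions: snoRNA windows from the size and
    tag-depth ranges of TCs covering full-length annotated snoRNAs, the 10x
    strand-bias ratio, and the >= 100 depth floor for unclassified groups.
    """

    strand_ratio_min: float = 10.0
    haca_len: tuple[int, int] = (120, 180)
    haca_depth_min: float = 15.0
    cd_len: tuple[int, int] = (60, 100)
    cd_depth_min: float = 6.0
    group_depth_min: float = 100.0
    group1_depth_min: float = 1000.0
    short_len_max: int = 40
    #: TC locus names excluded from group banding (e.g. a user-supplied list
    #: of transposon-homologous TCs).
    exclusion_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.exclusion_ids = frozenset(self.exclusion_ids)
        for lo, hi in (self.haca_len, self.cd_len):
            if lo > hi:
                raise ValueError(f"empty length window [{lo}, {hi}]")
        if self.strand_ratio_min <= 1:
            raise ValueError("strand_ratio_min must be > 1")

    # flat key=value serialization -------------------------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = f"{v[0]},{v[1]}"
                elif isinstance(v, frozenset):
                    v = ",".join(sorted(v))
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FilterConfig":
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("haca_len", "cd_len"):
                    lo, hi = val.split(",")
                    kwargs[key] = (int(lo), int(hi))
                elif key == "exclusion_ids":
                    kwargs[key] = frozenset(v for v in val.split(",") if v)
                elif key == "short_len_max":
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


def strand_competition_filter(
    tcs: Sequence[TagContig],
    config: Optional[FilterConfig] = None,
    competitors: Optional[Sequence[TagContig]] = None,
) -> list[TagContig]:
    """Keep TCs with no opposite-strand overlap or a >= 10x depth advantage.

    A TC is retained iff no competitor on the opposite strand overlaps it by
    >= 1 base, or its tag-depth is at least ``strand_ratio_min`` times the
    deepest overlapping opposite-strand competitor (inclusive boundary).
    ``competitors`` defaults to ``tcs`` itself; pass the full TC set when
    filtering a subset.
    """
    config = config or FilterConfig()
    pool = tcs if competitors is None else competitors
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in pool:
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(t.start, t.end, t)

    other = {"+": "-", "-": "+"}
    retained = []
    for tc in tcs:
        tree = trees.get((tc.chrom, other[tc.strand]))
        opposing = [iv.data for iv in tree.overlap(tc.start, tc.end)] if tree else []
        if not opposing:
            retained.append(tc)
            continue
        max_opp = max(o.tag_depth for o in opposing)
        if tc.tag_depth >= config.strand_ratio_min * max_opp:
            retained.append(tc)
    return retained


def window_filter(
    tcs: Sequence[TagContig],
    classifications: Mapping[TagContig, TcClassification],
    len_range: tuple[int, int],
    depth_min: float,
    contexts: Iterable[TcContext],
) -> list[TagContig]:
    """Retain TCs inside a length window (inclusive both ends), above a
    tag-depth floor and in one of the given genomic contexts."""
    lo, hi = len_range
    ctx = set(contexts)
    return [
        tc for tc in tcs
        if lo <= tc.length <= hi
        and tc.tag_depth >= depth_min
        and classifications[tc].context in ctx
    ]


#: Contexts eligible for each snoRNA window: box H/ACA snoRNAs are almost all
#: intronic and sense to their host gene; box C/D snoRNAs are intronic (sense)
#: or intergenic.
HACA_CONTEXTS = frozenset({TcContext.INTRONIC_SENSE})
CD_CONTEXTS = frozenset({TcContext.INTRONIC_SENSE, TcContext.INTERGENIC})

#: Contexts regarded as unannotated (survive the annotation-exclusion step).
UNANNOTATED_CONTEXTS = frozenset({
    TcContext.INTRONIC_SENSE, TcContext.INTRONIC_ANTISENSE, TcContext.INTERGENIC,
})


def assign_group(tc: TagContig, config: Optional[FilterConfig] = None) -> str:
    """Band a highly expressed unannotated TC into group1/group2/group3.

    group1: shorter than 40 nt, depth >= 1000; group2: shorter than 40 nt,
    depth in [100, 1000); group3: >= 40 nt, depth >= 100.  The group2 upper
    bound is exclusive so that fractional depths cannot fall between bands.
    """
    config = config or FilterConfig()
    short = tc.length < config.short_len_max
    if short and tc.tag_depth >= config.group1_depth_min:
        return "group1"
    if short and config.group_depth_min <= tc.tag_depth < config.group1_depth_min:
        return "group2"
    if not short and tc.tag_depth >= config.group_depth_min:
        return "group3"
    return "below_threshold"
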