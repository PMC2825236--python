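"""Exact full-length tag placement and multi-mapping read-weight distribution.

Tags are placed on both strands by exact full-length match.  A tag observed
``r`` times (its read count) that maps to ``n`` loci contributes weight
``r / n`` to each locus; tags with more loci than reads are discarded
entirely, since their per-locus evidence is weaker than a single read.
Placements on excluded chromosomes (chrM, chrU, chrUextra by default) are
dropped *before* ``n`` is counted, so they never dilute the retained loci.

The built-in matcher is a hash index over fixed-length windows per distinct
tag length, intended for desk-scale genomes (<= ~100 Mb).  For larger
genomes, import pre-mapped placements from BED with
:func:`read_premapped_bed`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from .io_formats import Genome, TagRecord, reverse_complement

logger = logging.getLogger("tagcontig")


@dataclass(frozen=True)
class MappedTag:
    """One genomic placement of a tag with its fractional read weight.

    ``n_loci`` is the tag's total number of placements genome-wide after
    chromosome exclusion; ``weight`` is ``read_count / n_loci`` (0 until
    :func:`distribute_reads` runs).
    """

    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_loci: int = 1
    weight: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def _placement_sort_key(p: MappedTag):
    return (p.chrom, p.start, p.strand, p.tag_id)


def map_tags_exact(genome: Genome, tags: Sequence[TagRecord]) -> list[MappedTag]:
    """All full-length exact placements of ``tags`` on both genome strands.

    A minus-strand placement means the reverse complement of the tag matches
    the forward genome string over ``[start, end)``.  Excluded chromosomes are
    never scanned, so ``n_loci`` reflects only retained placements.
    """
    if not any(genome.sequences[c] for c in genome.active_chroms):
        raise ValueError("genome has no indexable sequence outside excluded chromosomes")

    fwd: dict[str, str] = {}
    rev: dict[str, str] = {}
    for t in tags:
        fwd[t.sequence] = t.tag_id
        rev[reverse_complement(t.sequence)] = t.tag_id
    lengths = sorted({len(s) for s in fwd})

    placements: list[MappedTag] = []
    for chrom in genome.active_chroms:
        seq = genome.sequences[chrom]
        n = len(seq)
        for L in lengths:
            if L > n:
                continue
            for i in range(n - L + 1):
                window = seq[i:i + L]
                tid = fwd.get(window)
                if tid is not None:
                    placements.append(MappedTag(tid, chrom, i, i + L, "+"))
                tid = rev.get(window)
                if tid is not None:
                    placements.append(MappedTag(tid, chrom, i, i + L, "-"))

    counts = Counter(p.tag_id for p in placements)
    placements = [replace(p, n_loci=counts[p.tag_id]) for p in placements]
    placements.sort(key=_placement_sort_key)
    return placements


def distribute_reads(
    placements: Sequence[MappedTag], tags: Sequence[TagRecord]
) -> list[MappedTag]:
    """Assign even per-locus weights; discard tags with more loci than reads.

    For each surviving placement, ``weight = read_count / n_loci``; the sum of
    weights over retained placements equals the sum of read counts of retained
    tags (mass conservation).
    """
    read_count = {t.tag_id: t.read_count for t in tags}
    out: list[MappedTag] = []
    dropped: set[str] = set()
    for p in placements:
        r = read_count.get(p.tag_id)
        if r is None:
            logger.warning("placement for unknown tag %s skipped", p.tag_id)
            continue
        if p.n_loci > r:
            dropped.add(p.tag_id)
            continue
        out.append(replace(p, weight=r / p.n_loci))
    if dropped:
        logger.info(
            "discarded %d tags with more mapped loci than reads", len(dropped)
        )
    return out


def read_premapped_bed(
    path: Union[str, Path],
    tags: Sequence[TagRecord],
    genome: Genome,
) -> list[MappedTag]:
    """Import pre-mapped tags from BED6 (name column = tag_id).

    Placements on excluded chromosomes are dropped before ``n_loci`` is
    counted, matching the built-in matcher.  Interval lengths are validated
    against the tag sequences.
    """
    seq_len = {t.tag_id: len(t.sequence) for t in tags}
    raw: list[MappedTag] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{i}: not a BED6 line")
            chrom, start, end, tag_id, _, strand = parts[:6]
            start, end = int(start), int(end)
            if chrom in genome.excluded_chroms:
                continue
            if tag_id not in seq_len:
                logger.warning("%s:%d: unknown tag_id %s skipped", path, i, tag_id)
                continue
            if end - start != seq_len[tag_id]:
                raise ValueError(
                    f"{path}:{i}: interval length {end - start} != tag length "
                    f"{seq_len[tag_id]} for {tag_id}"
                )
            raw.append(MappedTag(tag_id, chrom, start, end, strand))
    counts = Counter(p.tag_id for p in raw)
    out = [replace(p, n_loci=counts[p.tag_id]) for p in raw]
    out.sort(key=_placement_sort_key)
    return out
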