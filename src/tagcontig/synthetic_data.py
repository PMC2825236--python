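"""Desk-scale synthetic fixtures for every pipeline stage.

The generator builds a toy genome with gene/intron/intergenic architecture,
plants ncRNA loci with the correct motif grammar (box C/D, box H/ACA, a
short high-depth 18mer-motif locus, transposon-like double-stranded
regions), and samples a tag library the way a size-fractionated small-RNA
sequencing experiment would see it: each planted locus is tiled by
overlapping 18-32 nt windows (guaranteeing >= 1-nt chaining into a single
tag-contig spanning exactly the planted interval) with read counts scaled to
reach a target tag-depth, on top of uniform depth-1 background tags.

Everything derives from a single integer seed; identical seeds give
byte-identical fixture files.  A truth table records every planted feature
with its expected pipeline call, so recovery tests can join calls to truth
by interval overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationFeature,
    FeatureClass,
    Genome,
    TagRecord,
    merge_tag_records,
    reverse_complement,
    synthesize_introns,
    write_annotation_gff3,
    write_conserved_bed,
    write_genome_fasta,
    write_tag_library,
)

#: The consensus 18mer dominating the short highly expressed unannotated loci.
KMER_18 = "GTCCACCCGGGGGCGCCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Planted:
    """One feature to plant: its class, length, genomic context and the
    tag-depth its sampled tags should reach."""

    kind: str  # snoRNA_CD | snoRNA_HACA | tRNA_like | mirna_like | kmer_site | transposon_like
    length: int
    context: str  # intronic | intergenic
    target_depth: float


def _default_planted() -> tuple[Planted, ...]:
    # Lengths and depths mirror validated candidates of each class: three
    # box C/D loci (74/566, 81/42, 69/993), two box H/ACA loci (145/105,
    # 143/234), one 21-nt locus at depth 5027 carrying the 18mer motif, one
    # transposon-like double-stranded decoy, and two annotated ncRNAs
    # (tRNA-like and miRNA-like) to exercise the coverage report.
    return (
        Planted("snoRNA_CD", 74, "intronic", 566.0),
        Planted("snoRNA_CD", 81, "intronic", 42.0),
        Planted("snoRNA_CD", 69, "intergenic", 993.0),
        Planted("snoRNA_HACA", 145, "intronic", 105.0),
        Planted("snoRNA_HACA", 143, "intronic", 234.0),
        Planted("kmer_site", 21, "intronic", 5027.0),
        Planted("transposon_like", 200, "intergenic", 120.0),
        Planted("tRNA_like", 72, "intergenic", 300.0),
        Planted("mirna_like", 22, "intronic", 400.0),
    )


@dataclass
class FixtureSpec:
    seed: int = 1
    genome_length: int = 200_000
    n_genes: int = 8
    planted: tuple[Planted, ...] = field(default_factory=_default_planted)
    tag_length_range: tuple[int, int] = (18, 32)
    #: probability that a planted ncRNA also emits one full-length tag
    #: (an uncollapsed precursor read).
    full_length_fraction: float = 0.5
    n_background_tags: int = 300

    exon_length: int = 300
    intron_length: int = 600
    chrm_length: int = 2000


@dataclass
class FixtureResult:
    spec: FixtureSpec
    genome: Genome
    features: list[AnnotationFeature]
    conserved: list[AnnotationFeature]
    tags: list[TagRecord]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _cd_body(rng: np.random.Generator, length: int) -> str:
    """Random sequence with box C (RTGATGA) near the 5' end and box D (CTGA)
    ending 5 nt before the 3' end."""
    body = list(_random_dna(rng, length))
    box_c = ("A" if rng.integers(0, 2) == 0 else "G") + "TGATGA"
    body[4:11] = box_c
    body[length - 9:length - 5] = "CTGA"
    return "".join(body)


def _haca_body(rng: np.random.Generator, length: int) -> str:
    """Random sequence with box H (ANANNA) at the midpoint and ACA ending
    2 nt before the 3' end."""
    body = list(_random_dna(rng, length))
    mid = (length - 6) // 2
    n = lambda: "ACGT"[rng.integers(0, 4)]
    body[mid:mid + 6] = "A" + n() + "A" + n() + n() + "A"
    body[length - 5:length - 2] = "ACA"
    return "".join(body)


def _kmer_body(rng: np.random.Generator, length: int) -> str:
    if length < len(KMER_18):
        raise ValueError("kmer_site locus shorter than the 18mer motif")
    pad = length - len(KMER_18)
    left = int(rng.integers(0, pad + 1))
    return _random_dna(rng, left) + KMER_18 + _random_dna(rng, pad - left)


def _planted_body(rng: np.random.Generator, item: Planted) -> str:
    if item.kind == "snoRNA_CD":
        return _cd_body(rng, item.length)
    if item.kind == "snoRNA_HACA":
        return _haca_body(rng, item.length)
    if item.kind == "kmer_site":
        return _kmer_body(rng, item.length)
    return _random_dna(rng, item.length)


# ---------------------------------------------------------------------------
# tag sampling
# ---------------------------------------------------------------------------

def _tile_windows(start: int, end: int, window: int, step: int) -> list[tuple[int, int]]:
    """Windows tiling [start, end) exactly: first starts at ``start``, last
    ends at ``end``, consecutive windows overlap by ``window - step`` >= 1."""
    length = end - start
    if length <= window:
        return [(start, end)]
    starts = list(range(start, end - window, step))
    if starts[-1] != end - window:
        starts.append(end - window)
    return [(s, s + window) for s in starts]


def _max_multiplicity(windows: Sequence[tuple[int, int]], start: int, end: int) -> int:
    cov = np.zeros(end - start, dtype=np.int64)
    for s, e in windows:
        cov[s - start:e - start] += 1
    return int(cov.max())


def _locus_tags(
    name: str,
    chrom_seq: str,
    start: int,
    end: int,
    strand: str,
    target_depth: float,
    rng: np.random.Generator,
    tag_length_range: tuple[int, int],
    full_length: bool,
) -> list[TagRecord]:
    """Tags tiling a planted locus so its TC spans exactly [start, end) with
    tag-depth >= target_depth."""
    w = min(tag_length_range[1] - 6, end - start)
    w = max(w, tag_length_range[0]) if end - start >= tag_length_range[0] else end - start
    step = max(1, w // 2)
    windows = _tile_windows(start, end, w, step)
    mult = _max_multiplicity(windows, start, end)
    count = max(1, math.ceil(target_depth / mult))
    tags = []
    for i, (s, e) in enumerate(windows):
        seq = chrom_seq[s:e]
        if strand == "-":
            seq = reverse_complement(seq)
        tags.append(TagRecord(f"{name}_w{i}", seq, count))
    if full_length and end - start <= 400:
        seq = chrom_seq[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        tags.append(TagRecord(
            f"{name}_full", seq, max(1, round(0.05 * target_depth))
        ))
    return tags


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def generate_fixture(
    spec: FixtureSpec,
    out_dir: Optional[Union[str, Path]] = None,
) -> FixtureResult:
    """Build the fixture; optionally write FASTA/GFF3/BED/TSV files.

    Raises ``ValueError`` when the planted features cannot be packed into the
    gene architecture (too many intronic/intergenic items, or an item longer
    than its slot).
    """
    rng = np.random.default_rng(spec.seed)
    glen = spec.genome_length

    # gene architecture: n_genes of exon-intron-exon-intron-exon, alternating
    # strand, evenly spaced with intergenic gaps on both sides
    gene_span = 3 * spec.exon_length + 2 * spec.intron_length
    gap = (glen - spec.n_genes * gene_span) // (spec.n_genes + 1)
    if gap < 1000:
        raise ValueError("genome too short for the requested gene architecture")

    features: list[AnnotationFeature] = []
    introns: list[AnnotationFeature] = []
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for i in range(spec.n_genes):
        gstart = gap + i * (gene_span + gap)
        gaps.append((cursor + 200, gstart - 200))
        cursor = gstart + gene_span
        strand = "+" if i % 2 == 0 else "-"
        gname = f"gene{i + 1}"
        features.append(AnnotationFeature(
            "chr2R", gstart, gstart + gene_span, strand, FeatureClass.GENE, gname
        ))
        pos = gstart
        for j in range(3):
            features.append(AnnotationFeature(
                "chr2R", pos, pos + spec.exon_length, strand,
                FeatureClass.EXON, f"{gname}_exon{j + 1}",
            ))
            pos += spec.exon_length + spec.intron_length
    gaps.append((cursor + 200, glen - 200))
    introns = synthesize_introns(features)
    features.extend(introns)

    # assign planted items to slots
    margin = 50
    intronic = [p for p in spec.planted if p.context == "intronic"]
    intergenic = [p for p in spec.planted if p.context == "intergenic"]
    if len(intronic) > len(introns):
        raise ValueError(
            f"cannot pack {len(intronic)} intronic features into "
            f"{len(introns)} introns"
        )
    chrom = bytearray(_random_dna(rng, glen).encode())
    occupied: list[tuple[int, int]] = []
    placements: list[tuple[Planted, str, int, int, str, Optional[str]]] = []

    for item, intron in zip(intronic, introns):
        if item.length + 2 * margin > intron.length:
            raise ValueError(
                f"{item.kind} of length {item.length} does not fit intron "
                f"{intron.name}"
            )
        s = intron.start + (intron.length - item.length) // 2
        host = intron.name.rsplit("_intron", 1)[0]
        placements.append((item, "chr2R", s, s + item.length, intron.strand, host))

    gap_cursor = {k: gaps[k][0] + 300 for k in range(len(gaps))}
    for k, item in enumerate(intergenic):
        gi = k % len(gaps)
        s = gap_cursor[gi]
        if s + item.length + 300 > gaps[gi][1]:
            raise ValueError(f"intergenic slot {gi} cannot fit {item.kind}")
        gap_cursor[gi] = s + item.length + 600
        strand = "+" if k % 2 == 0 else "-"
        placements.append((item, "chr2R", s, s + item.length, strand, None))

    # write planted bodies into the genome (reverse-complemented for minus-
    # strand placements: the body reads 5'->3' on its own strand)
    truth_rows = []
    tag_lists: list[list[TagRecord]] = []
    expected_call = {
        "snoRNA_CD": "snoRNA_CD",
        "snoRNA_HACA": "snoRNA_HACA",
        "kmer_site": "group1",
        "transposon_like": "rejected_strand_filter",
        "tRNA_like": "annotated",
        "mirna_like": "annotated",
    }
    ncrna_class = {"tRNA_like": FeatureClass.TRNA, "mirna_like": FeatureClass.MIRNA}
    counters: dict[str, int] = {}
    chrom_str = None  # rebuilt after all bodies are written

    for item, _, s, e, strand, host in placements:
        counters[item.kind] = counters.get(item.kind, 0) + 1
        name = f"{item.kind}_{counters[item.kind]}"
        body = _planted_body(rng, item)
        genomic = body if strand == "+" else reverse_complement(body)
        chrom[s:e] = genomic.encode()
        occupied.append((s, e))
        if item.kind in ncrna_class:
            features.append(AnnotationFeature(
                "chr2R", s, e, strand, ncrna_class[item.kind], name
            ))
        truth_rows.append({
            "name": name, "kind": item.kind, "chrom": "chr2R",
            "start": s, "end": e, "strand": strand,
            "context": item.context, "host_gene": host or "",
            "target_depth": item.target_depth,
            "expected_call": expected_call[item.kind],
        })

    chrom_str = chrom.decode()
    full_length_draws = rng.random(len(placements))
    for k, (item, _, s, e, strand, _) in enumerate(placements):
        name = truth_rows[k]["name"]
        if item.kind == "transposon_like":
            # double-stranded decoy: sense tags at the target depth plus
            # antisense tags at half depth (well inside the 10x ratio)
            tag_lists.append(_locus_tags(
                f"{name}_s", chrom_str, s, e, strand, item.target_depth,
                rng, spec.tag_length_range, full_length=False,
            ))
            anti = "-" if strand == "+" else "+"
            tag_lists.append(_locus_tags(
                f"{name}_a", chrom_str, s + 5, e - 5, anti,
                item.target_depth / 2, rng, spec.tag_length_range,
                full_length=False,
            ))
        else:
            tag_lists.append(_locus_tags(
                name, chrom_str, s, e, strand, item.target_depth,
                rng, spec.tag_length_range,
                full_length=full_length_draws[k] < spec.full_length_fraction,
            ))

    # uniform depth-1 background tags outside planted regions
    forbidden = sorted((max(0, s - 35), e + 35) for s, e in occupied)

    def _is_free(s: int, e: int) -> bool:
        return all(e <= fs or s >= fe for fs, fe in forbidden)

    background: list[TagRecord] = []
    attempts = 0
    while len(background) < spec.n_background_tags and attempts < 50 * spec.n_background_tags:
        attempts += 1
        L = int(rng.integers(spec.tag_length_range[0], spec.tag_length_range[1] + 1))
        s = int(rng.integers(0, glen - L))
        if not _is_free(s, s + L):
            continue
        seq = chrom_str[s:s + L]
        if rng.integers(0, 2) == 1:
            seq = reverse_complement(seq)
        background.append(TagRecord(f"bg{len(background)}", seq, 1))
    tag_lists.append(background)

    # chrM decoy: carries an exact copy of the planted 18mer locus, so its
    # tags also hit an excluded chromosome (which must not affect weights)
    chrm = bytearray(_random_dna(rng, spec.chrm_length).encode())
    kmer_rows = [r for r in truth_rows if r["kind"] == "kmer_site"]
    if kmer_rows:
        r = kmer_rows[0]
        copy = chrom_str[r["start"]:r["end"]]
        chrm[1000:1000 + len(copy)] = copy.encode()

    genome = Genome(["chr2R", "chrM"], {"chr2R": chrom_str, "chrM": chrm.decode()})

    # conserved elements: one spanning each planted snoRNA, plus background
    conserved: list[AnnotationFeature] = []
    for r in truth_rows:
        if r["kind"] in ("snoRNA_CD", "snoRNA_HACA"):
            conserved.append(AnnotationFeature(
                "chr2R", max(0, r["start"] - 5), min(glen, r["end"] + 5), ".",
                FeatureClass.CONSERVED_ELEMENT, f"cons_{r['name']}",
            ))
    for i in range(3):
        s = int(rng.integers(0, glen - 200))
        conserved.append(AnnotationFeature(
            "chr2R", s, s + 200, ".", FeatureClass.CONSERVED_ELEMENT, f"cons_bg{i}"
        ))

    tags = merge_tag_records(t for lst in tag_lists for t in lst)
    features.sort(key=lambda f: (f.chrom, f.start, f.end, f.feature_class.value))
    truth = pd.DataFrame(truth_rows, columns=[
        "name", "kind", "chrom", "start", "end", "strand", "context",
        "host_gene", "target_depth", "expected_call",
    ])

    result = FixtureResult(spec, genome, features, conserved, tags, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(genome, out / "genome.fa")
        write_annotation_gff3(
            [f for f in features if f.feature_class is not FeatureClass.INTRON],
            out / "annotation.gff3",
        )
        write_conserved_bed(conserved, out / "conserved.bed")
        write_tag_library(tags, out / "tags.fa")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------

def match_calls_to_truth(calls: Sequence, truth: pd.DataFrame) -> pd.DataFrame:
    """Join pipeline calls to the truth table by >= 50% interval overlap on
    the same strand; adds ``called_class`` (empty when nothing matched)."""
    called = []
    for _, row in truth.iterrows():
        match = ""
        for c in calls:
            tc = c.tc
            if tc.chrom != row["chrom"] or tc.strand != row["strand"]:
                continue
            ov = max(0, min(tc.end, row["end"]) - max(tc.start, row["start"]))
            if ov >= 0.5 * (row["end"] - row["start"]):
                match = c.call_class.value
                break
        called.append(match)
    out = truth.copy()
    out["called_class"] = called
    return out


def recovery_stats(calls: Sequence, truth: pd.DataFrame) -> dict[str, float]:
    """Recall over planted candidates and precision of candidate calls.

    Recall: fraction of truth rows expecting a candidate call whose expected
    class was called at >= 50% overlap.  Precision: fraction of candidate
    calls (snoRNA/group classes) matching such a truth row.
    """
    candidate_classes = {"snoRNA_CD", "snoRNA_HACA", "group1", "group2", "group3"}
    joined = match_calls_to_truth(calls, truth)
    expected = joined[joined["expected_call"].isin(candidate_classes)]
    n_expected = len(expected)
    n_recovered = int((expected["expected_call"] == expected["called_class"]).sum())

    truth_hits = 0
    cand_calls = [c for c in calls if c.call_class.value in candidate_classes]
    for c in cand_calls:
        tc = c.tc
        for _, row in truth.iterrows():
            if (
                tc.chrom == row["chrom"] and tc.strand == row["strand"]
                and row["expected_call"] == c.call_class.value
                and max(0, min(tc.end, row["end"]) - max(tc.start, row["start"]))
                >= 0.5 * (row["end"] - row["start"])
            ):
                truth_hits += 1
                break
    return {
        "n_expected": float(n_expected),
        "n_recovered": float(n_recovered),
        "recall": n_recovered / n_expected if n_expected else float("nan"),
        "n_candidate_calls": float(len(cand_calls)),
        "precision": truth_hits / len(cand_calls) if cand_calls else float("nan"),
    }
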