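"""Genome, tag-library and annotation I/O plus the shared genomic data model.

All coordinates are 0-based, half-open ``[start, end)`` internally, so a locus
string ``chr3R_1020733_1020883`` names an interval of length ``end - start``
(here 150 nt).  GFF3 input (1-based, inclusive) is converted on read; BED input
is taken as-is.  Every nucleotide sequence is normalised to the uppercase DNA
alphabet at the I/O boundary (``U`` -> ``T``), so motifs stated in RNA (e.g.
RUGAUGA) are matched as DNA (RTGATGA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tagcontig")

#: Chromosomes excluded from mapping and scanning by default: the mitochondrial
#: genome and the bins of un-assembled / un-mapped scaffolds.
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrM", "chrU", "chrUextra"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA_BASES = frozenset("ACGT")

MIN_TAG_LEN = 12
MAX_TAG_LEN = 400


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of a sequence as a percentage (0-100)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    return 100.0 * sum(1 for b in s if b in "GC") / len(s)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A reference genome held in memory.

    Excluded chromosomes stay in ``sequences`` but are flagged; no mapping or
    scanning output may reference them.
    """

    chrom_names: list[str]
    sequences: dict[str, str]
    excluded_chroms: frozenset[str] = DEFAULT_EXCLUDED_CHROMS

    def __post_init__(self) -> None:
        self.excluded_chroms = frozenset(self.excluded_chroms)
        norm = {}
        for name in self.chrom_names:
            seq = self.sequences[name].upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            norm[name] = seq
        self.sequences = norm

    @property
    def active_chroms(self) -> list[str]:
        return [c for c in self.chrom_names if c not in self.excluded_chroms]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence of ``[start, end)``, clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]


def read_genome_fasta(
    path: Union[str, Path],
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> Genome:
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise ValueError(f"no sequences in genome FASTA {path}")
    return Genome(names, seqs, frozenset(excluded_chroms))


def write_genome_fasta(genome: Genome, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tag libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagRecord:
    """One distinct short RNA sequence with its sequencing read count.

    The read count is the number of times the tag was cloned and sequenced;
    identical sequences from different libraries are merged by summing counts.
    """

    tag_id: str
    sequence: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"tag {self.tag_id}: read_count must be >= 1")
        if not set(self.sequence) <= _DNA_BASES:
            raise ValueError(f"tag {self.tag_id}: sequence must be ACGT only")


def merge_tag_records(records: Iterable[TagRecord]) -> list[TagRecord]:
    """Merge duplicate sequences by summing read counts.

    The surviving ``tag_id`` is the lexicographically smallest of the merged
    ids; output is sorted lexicographically by sequence (deterministic).
    """
    by_seq: dict[str, tuple[str, int]] = {}
    for rec in records:
        if rec.sequence in by_seq:
            tid, cnt = by_seq[rec.sequence]
            by_seq[rec.sequence] = (min(tid, rec.tag_id), cnt + rec.read_count)
        else:
            by_seq[rec.sequence] = (rec.tag_id, rec.read_count)
    return [
        TagRecord(tid, seq, cnt)
        for seq, (tid, cnt) in sorted(by_seq.items())
    ]


def _parse_count_header(header: str) -> Optional[tuple[str, int]]:
    """Parse ``id_count`` or ``id count`` headers; None if no count found."""
    if " " in header or "\t" in header:
        parts = header.split()
        if len(parts) >= 2:
            try:
                return parts[0], int(parts[-1])
            except ValueError:
                return None
    if "_" in header:
        stem, _, tail = header.rpartition("_")
        try:
            return stem, int(tail)
        except ValueError:
            return None
    return None


def read_tag_library(
    path: Union[str, Path],
    format: str = "fasta_with_counts",
) -> list[TagRecord]:
    """Read a tag library; one TagRecord per distinct sequence.

    ``fasta_with_counts``: the read count is encoded in the FASTA header as
    ``id_count`` or ``id count``.  ``two_column_table``: tab/space separated
    ``sequence count`` (or ``id sequence count``) lines; ``#`` comments allowed.
    Records with unparsable counts, non-ACGT sequences or out-of-range lengths
    are rejected with a logged warning; zero usable records is a hard error.
    """
    raw: list[TagRecord] = []

    def _add(tag_id: str, seq: str, count: Optional[int], what: str) -> None:
        if count is None or count < 1:
            logger.warning("skipping %s: no parsable read count", what)
            return
        seq = normalize_sequence(seq)
        if not set(seq) <= _DNA_BASES:
            logger.warning("skipping %s: non-ACGT sequence", what)
            return
        if not (MIN_TAG_LEN <= len(seq) <= MAX_TAG_LEN):
            logger.warning(
                "skipping %s: length %d outside [%d, %d]",
                what, len(seq), MIN_TAG_LEN, MAX_TAG_LEN,
            )
            return
        raw.append(TagRecord(tag_id, seq, count))

    if format == "fasta_with_counts":
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description if rec.description else rec.id
            parsed = _parse_count_header(header)
            if parsed is None:
                logger.warning("skipping record %r: malformed count header", header)
                continue
            tag_id, count = parsed
            _add(tag_id, str(rec.seq), count, f"record {header!r}")
    elif format == "two_column_table":
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    if len(parts) == 2:
                        tag_id, seq, count = f"t{i}", parts[0], int(parts[1])
                    elif len(parts) >= 3:
                        tag_id, seq, count = parts[0], parts[1], int(parts[2])
                    else:
                        raise ValueError
                except ValueError:
                    logger.warning("skipping line %d of %s: malformed", i, path)
                    continue
                _add(tag_id, seq, count, f"line {i}")
    else:
        raise ValueError(f"unknown tag library format {format!r}")

    merged = merge_tag_records(raw)
    if not merged:
        raise ValueError(f"no parsable tag records in {path}")
    return merged


def write_tag_library(tags: Sequence[TagRecord], path: Union[str, Path]) -> None:
    """Write tags as FASTA with ``id_count`` headers (round-trips with read)."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.tag_id}_{t.read_count}\n{t.sequence}\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

class FeatureClass(str, Enum):
    EXON = "exon"
    INTRON = "intron"
    GENE = "gene"
    REPEAT = "repeat"
    TRANSPOSON = "transposon"
    MIRNA = "miRNA"
    PRE_MIRNA = "pre_miRNA"
    SNORNA_CD = "snoRNA_CD"
    SNORNA_HACA = "snoRNA_HACA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    OTHER_NCRNA = "other_ncRNA"
    CONSERVED_ELEMENT = "conserved_element"


#: Annotated ncRNA classes (used for the annotation-exclusion step and for the
#: ncRNA coverage report).
NCRNA_CLASSES = frozenset({
    FeatureClass.MIRNA, FeatureClass.PRE_MIRNA, FeatureClass.SNORNA_CD,
    FeatureClass.SNORNA_HACA, FeatureClass.TRNA, FeatureClass.SNRNA,
    FeatureClass.OTHER_NCRNA,
})

REPEAT_CLASSES = frozenset({FeatureClass.REPEAT, FeatureClass.TRANSPOSON})

#: GFF3 ``type`` column -> FeatureClass.  snoRNA entries are refined by a
#: ``snoRNA_type`` attribute (CD / HACA) when present.
DEFAULT_CLASS_MAP: dict[str, FeatureClass] = {
    "gene": FeatureClass.GENE,
    "exon": FeatureClass.EXON,
    "intron": FeatureClass.INTRON,
    "repeat_region": FeatureClass.REPEAT,
    "repeat": FeatureClass.REPEAT,
    "transposable_element": FeatureClass.TRANSPOSON,
    "transposon": FeatureClass.TRANSPOSON,
    "miRNA": FeatureClass.MIRNA,
    "pre_miRNA": FeatureClass.PRE_MIRNA,
    "miRNA_primary_transcript": FeatureClass.PRE_MIRNA,
    "snoRNA": FeatureClass.OTHER_NCRNA,
    "snoRNA_CD": FeatureClass.SNORNA_CD,
    "snoRNA_HACA": FeatureClass.SNORNA_HACA,
    "tRNA": FeatureClass.TRNA,
    "snRNA": FeatureClass.SNRNA,
    "ncRNA": FeatureClass.OTHER_NCRNA,
    "conserved_element": FeatureClass.CONSERVED_ELEMENT,
}


@dataclass(frozen=True)
class AnnotationFeature:
    """A typed genomic interval (exon / intron / gene / repeat / ncRNA / ...)."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    feature_class: FeatureClass
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of bases shared with ``[start, end)``."""
        return max(0, min(self.end, end) - max(self.start, start))


def _resolve_class(
    ftype: str,
    attributes: Mapping[str, Sequence[str]],
    class_map: Mapping[str, FeatureClass],
) -> Optional[FeatureClass]:
    if ftype == "snoRNA":
        sub = attributes.get("snoRNA_type", [""])[0].upper()
        if sub in ("CD", "C/D"):
            return FeatureClass.SNORNA_CD
        if sub in ("HACA", "H/ACA"):
            return FeatureClass.SNORNA_HACA
    return class_map.get(ftype)


def synthesize_introns(features: Sequence[AnnotationFeature]) -> list[AnnotationFeature]:
    """Derive intron features from gene/exon structure.

    For every gene, the introns are the gaps between its exons within the gene
    span.  Exons are attached to the gene that contains them on the same
    strand (matching by containment; names are ``<gene>_intron<i>``).
    """
    genes = [f for f in features if f.feature_class is FeatureClass.GENE]
    exons = [f for f in features if f.feature_class is FeatureClass.EXON]
    introns: list[AnnotationFeature] = []
    for gene in genes:
        mine = sorted(
            (e for e in exons
             if e.chrom == gene.chrom and e.strand == gene.strand
             and e.start >= gene.start and e.end <= gene.end),
            key=lambda e: (e.start, e.end),
        )
        cursor = None
        i = 0
        for e in mine:
            if cursor is not None and e.start > cursor:
                i += 1
                introns.append(AnnotationFeature(
                    gene.chrom, cursor, e.start, gene.strand,
                    FeatureClass.INTRON, f"{gene.name}_intron{i}",
                ))
            cursor = e.end if cursor is None else max(cursor, e.end)
    return introns


def _validate_against_genome(
    features: Sequence[AnnotationFeature], genome: Optional[Genome]
) -> None:
    if genome is None:
        return
    for f in features:
        if f.chrom not in genome.sequences:
            raise ValueError(f"feature {f.name}: unknown chromosome {f.chrom}")
        if f.end > genome.length(f.chrom):
            raise ValueError(
                f"feature {f.name}: end {f.end} beyond {f.chrom} length "
                f"{genome.length(f.chrom)}"
            )


def read_annotation(
    path: Union[str, Path],
    format: str = "gff3",
    genome: Optional[Genome] = None,
    class_map: Optional[Mapping[str, FeatureClass]] = None,
    bed_class: FeatureClass = FeatureClass.OTHER_NCRNA,
) -> list[AnnotationFeature]:
    """Read annotation as a flat feature list.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    When the file carries genes and exons but no introns, introns are
    synthesized from the gene/exon structure.  Unmapped feature types are
    skipped with a debug message.  For BED6 every line becomes a feature of
    ``bed_class``.
    """
    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    features: list[AnnotationFeature] = []

    if format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.all_features(order_by=("seqid", "start", "end")):
            fclass = _resolve_class(feat.featuretype, dict(feat.attributes), cmap)
            if fclass is None:
                logger.debug("skipping unmapped feature type %r", feat.featuretype)
                continue
            name = (
                feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or feat.id
            )
            features.append(AnnotationFeature(
                feat.seqid, feat.start - 1, feat.end,
                feat.strand if feat.strand in "+-" else ".",
                fclass, name,
            ))
        if not any(f.feature_class is FeatureClass.INTRON for f in features):
            features.extend(synthesize_introns(features))
    elif format == "bed6":
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{i}: not a BED line")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"feature{i}"
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                features.append(AnnotationFeature(
                    chrom, start, end, strand, bed_class, name,
                ))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    features.sort(key=lambda f: (f.chrom, f.start, f.end, f.feature_class.value))
    _validate_against_genome(features, genome)
    return features


def write_annotation_gff3(
    features: Sequence[AnnotationFeature], path: Union[str, Path]
) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    type_of = {
        FeatureClass.SNORNA_CD: ("snoRNA", "snoRNA_type=CD"),
        FeatureClass.SNORNA_HACA: ("snoRNA", "snoRNA_type=HACA"),
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype, extra = type_of.get(f.feature_class, (f.feature_class.value, ""))
            attrs = f"ID={f.name};Name={f.name}"
            if extra:
                attrs += ";" + extra
            fh.write(
                f"{f.chrom}\ttagcontig\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_conserved_bed(
    elements: Sequence[AnnotationFeature], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for f in elements:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# Tag-contig BED I/O
# ---------------------------------------------------------------------------

def tc_locus_name(chrom: str, start: int, end: int) -> str:
    """Canonical locus name, e.g. ``chr3R_1020733_1020883``."""
    return f"{chrom}_{start}_{end}"


def parse_locus_name(name: str) -> tuple[str, int, int]:
    """Inverse of :func:`tc_locus_name`; chromosome names may contain ``_``."""
    chrom, start, end = name.rsplit("_", 2)
    return chrom, int(start), int(end)


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def write_tc_bed(tcs: Sequence, path: Union[str, Path]) -> None:
    """Write tag-contigs as BED6+1.

    Column 5 is the tag-depth rounded half-up and capped at 1000 (BED score
    range); column 7 repeats the full-precision depth.  Rows are sorted by
    (chrom, start, end, strand).
    """
    rows = sorted(tcs, key=lambda t: (t.chrom, t.start, t.end, t.strand))
    with open(path, "w") as fh:
        for t in rows:
            score = min(1000, _round_half_up(t.tag_depth))
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t"
                f"{tc_locus_name(t.chrom, t.start, t.end)}\t{score}\t{t.strand}\t"
                f"{t.tag_depth!r}\n"
            )


def read_tc_bed(path: Union[str, Path]) -> list:
    """Read tag-contigs from BED6+1 written by :func:`write_tc_bed`.

    Composition statistics (n_tags, n_reads, members) are not stored in BED;
    they come back as placeholders (0, tag_depth, empty).
    """
    from .contig_assembly import TagContig

    tcs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{i}: not a BED6 line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5]
            depth = float(parts[6]) if len(parts) > 6 else float(parts[4])
            tcs.append(TagContig(
                chrom=chrom, start=start, end=end, strand=strand,
                tag_depth=depth, n_tags=0, n_reads=depth, member_tag_ids=(),
            ))
    return tcs
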