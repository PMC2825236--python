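"""Degenerate (IUPAC) motif matching, anchored snoRNA box searches and
genome-wide k-mer scanning with mismatches.

Box C/D snoRNAs carry a box C (RUGAUGA in RNA; RTGATGA here) near their 5'
end and a box D (CUGA) near their 3' end; box H/ACA snoRNAs carry a box H
(ANANNA) in the hinge between their two hairpins — near the TC midpoint —
and an ACA triplet near the 3' end.  Anchored searches run in the TC's
5'->3' frame (for minus-strand TCs the 5' end is the genomic end) and may
extend past the TC boundary into genomic flank, because a TC can slightly
under- or over-run the mature RNA.

Windows are start-based: a motif qualifies when its start position lies
within ``window`` bases of the anchor, where the anchor is the start the
motif would have if flush with the TC end (0 for the 5' end, L - m for the
3' end) or centred on the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .contig_assembly import TagContig
from .io_formats import Genome, normalize_sequence, reverse_complement

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif with mismatch budget and an anchored search window."""

    name: str
    pattern: str  # IUPAC, DNA alphabet
    max_mismatches: int = 0
    anchor: str = "none"  # five_prime | three_prime | midpoint | none
    window: int = 0  # bp each side of the anchor for the motif start

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        if self.window < 0 or self.max_mismatches < 0:
            raise ValueError("window and max_mismatches must be >= 0")
        bad = set(normalize_sequence(self.pattern)) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {sorted(bad)}")


@dataclass(frozen=True)
class MotifHit:
    """One motif match; ``start`` is genomic, ``tc_offset`` is the start in
    the TC's 5'->3' frame (None for genome-wide scans)."""

    motif: str
    chrom: str
    strand: str
    start: int
    mismatches: int
    matched_sequence: str
    tc_offset: Optional[int] = None


# Canonical box specs (RNA motifs stored in DNA alphabet).
BOX_C = MotifSpec("box_C", "RTGATGA", max_mismatches=1, anchor="five_prime", window=10)
BOX_D = MotifSpec("box_D", "CTGA", max_mismatches=1, anchor="three_prime", window=10)
BOX_H = MotifSpec("box_H", "ANANNA", max_mismatches=0, anchor="midpoint", window=20)
BOX_ACA = MotifSpec("box_ACA", "ACA", max_mismatches=0, anchor="three_prime", window=20)


def iupac_mismatch_count(pattern: str, window_seq: str) -> int:
    """Positions of ``window_seq`` outside the IUPAC set of ``pattern``.

    ``N`` in the pattern never mismatches; comparison is per-position set
    membership with no partial credit.
    """
    if len(pattern) != len(window_seq):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window_seq)}"
        )
    pat = normalize_sequence(pattern)
    seq = normalize_sequence(window_seq)
    return sum(1 for p, b in zip(pat, seq) if b not in IUPAC_SETS[p])


def tc_oriented_sequence(
    genome: Genome, tc: TagContig, flank: int = 0
) -> tuple[str, int]:
    """TC sequence in its 5'->3' frame with up to ``flank`` genomic bases on
    each side (truncated at chromosome edges).

    Returns ``(seq, left_pad)`` where ``left_pad`` bases precede TC-frame
    position 0, i.e. TC-frame position ``p`` is ``seq[p + left_pad]``.
    """
    chrom_len = genome.length(tc.chrom)
    lo = max(0, tc.start - flank)
    hi = min(chrom_len, tc.end + flank)
    raw = genome.fetch(tc.chrom, lo, hi)
    if tc.strand == "+":
        return raw, tc.start - lo
    return reverse_complement(raw), hi - tc.end


def _anchor_position(spec: MotifSpec, tc_length: int) -> int:
    m = len(spec.pattern)
    if spec.anchor == "five_prime":
        return 0
    if spec.anchor == "three_prime":
        return tc_length - m
    if spec.anchor == "midpoint":
        return (tc_length - m) // 2
    raise ValueError(f"motif {spec.name}: anchored_search needs an anchor")


def anchored_search(
    tc: TagContig, genome: Genome, spec: MotifSpec
) -> Optional[MotifHit]:
    """Best in-window hit of ``spec`` around its anchor on ``tc``.

    Candidate motif starts ``p`` (TC frame) satisfy ``|p - anchor| <=
    window``; the best hit has the fewest mismatches, ties broken by smallest
    ``|p - anchor|`` then smallest ``p``.  Returns None when no candidate is
    within the mismatch budget.
    """
    m = len(spec.pattern)
    anchor = _anchor_position(spec, tc.length)
    seq, pad = tc_oriented_sequence(genome, tc, flank=spec.window + m)
    best: Optional[tuple[int, int, int]] = None
    best_seq = ""
    for p in range(anchor - spec.window, anchor + spec.window + 1):
        i = p + pad
        if i < 0 or i + m > len(seq):
            continue  # truncated at a chromosome edge
        window_seq = seq[i:i + m]
        mm = iupac_mismatch_count(spec.pattern, window_seq)
        if mm > spec.max_mismatches:
            continue
        key = (mm, abs(p - anchor), p)
        if best is None or key < best:
            best = key
            best_seq = window_seq
    if best is None:
        return None
    mm, _, p = best
    if tc.strand == "+":
        gstart = tc.start + p
    else:
        gstart = tc.end - p - m
    return MotifHit(spec.name, tc.chrom, tc.strand, gstart, mm, best_seq, tc_offset=p)


def call_box_cd(
    tc: TagContig, genome: Genome,
    box_c: MotifSpec = BOX_C, box_d: MotifSpec = BOX_D,
) -> Optional[tuple[MotifHit, MotifHit]]:
    """Paired box C + box D call for a size/depth-windowed TC.

    Requires box C (<= 1 mismatch, within 10 bp of the 5' end) and box D
    (<= 1 mismatch, within 10 bp of the 3' end) with C upstream of D in the
    TC frame.
    """
    c_hit = anchored_search(tc, genome, box_c)
    if c_hit is None:
        return None
    d_hit = anchored_search(tc, genome, box_d)
    if d_hit is None:
        return None
    if not (c_hit.tc_offset < d_hit.tc_offset):
        return None
    return c_hit, d_hit


def call_box_haca(
    tc: TagContig, genome: Genome,
    box_h: MotifSpec = BOX_H, box_aca: MotifSpec = BOX_ACA,
) -> Optional[tuple[MotifHit, MotifHit]]:
    """Paired box H + ACA call: ANANNA (exact) within 20 bp of the TC
    midpoint and ACA (exact) within 20 bp of the 3' end, H upstream of ACA."""
    h_hit = anchored_search(tc, genome, box_h)
    if h_hit is None:
        return None
    aca_hit = anchored_search(tc, genome, box_aca)
    if aca_hit is None:
        return None
    if not (h_hit.tc_offset < aca_hit.tc_offset):
        return None
    return h_hit, aca_hit


# ---------------------------------------------------------------------------
# Genome-wide fixed-kmer scanning
# ---------------------------------------------------------------------------

MAX_SCAN_KMER_LEN = 64


def genome_kmer_scan(
    genome: Genome, kmer: str, max_mismatches: int = 0
) -> list[MotifHit]:
    """All sites on both strands within Hamming distance ``max_mismatches``.

    Excluded chromosomes are skipped.  Each (chrom, start, strand) site is
    reported once with its exact mismatch count; ``matched_sequence`` is the
    site read 5'->3' on the hit strand.  N bases in the genome never match an
    ACGT k-mer, so they count as mismatches.
    """
    kmer = normalize_sequence(kmer)
    if not 0 < len(kmer) <= MAX_SCAN_KMER_LEN:
        raise ValueError(f"kmer length must be in [1, {MAX_SCAN_KMER_LEN}]")
    if set(kmer) - set("ACGT"):
        raise ValueError("kmer must be ACGT only")
    m = len(kmer)
    patterns = {
        "+": np.frombuffer(kmer.encode(), dtype=np.uint8),
        "-": np.frombuffer(reverse_complement(kmer).encode(), dtype=np.uint8),
    }
    hits: list[MotifHit] = []
    for chrom in genome.active_chroms:
        seq = genome.sequences[chrom]
        n = len(seq)
        if n < m:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand in ("+", "-"):
            pat = patterns[strand]
            mm = np.zeros(n - m + 1, dtype=np.int32)
            for j in range(m):
                mm += arr[j:n - m + 1 + j] != pat[j]
            for i in np.nonzero(mm <= max_mismatches)[0]:
                window = seq[i:i + m]
                hits.append(MotifHit(
                    "kmer_scan", chrom, strand, int(i), int(mm[i]),
                    window if strand == "+" else reverse_complement(window),
                ))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def stratify_hits(hits: Sequence[MotifHit]) -> dict[int, list[MotifHit]]:
    """Group scan hits by exact mismatch count (0, 1, ..., max observed)."""
    strata: dict[int, list[MotifHit]] = {}
    for h in hits:
        strata.setdefault(h.mismatches, []).append(h)
    return dict(sorted(strata.items()))


# ---------------------------------------------------------------------------
# Motif spec config files and hit emission
# ---------------------------------------------------------------------------

def load_motif_specs(path: Union[str, Path]) -> dict[str, MotifSpec]:
    """Load motif specs from a flat file: one
    ``name pattern max_mismatches anchor window`` line per motif."""
    specs: dict[str, MotifSpec] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{i}: expected 5 fields")
            name, pattern, mm, anchor, window = parts
            specs[name] = MotifSpec(name, pattern, int(mm), anchor, int(window))
    return specs


def write_hits_bed(hits: Sequence[MotifHit], path: Union[str, Path]) -> None:
    """Emit hits as BED6 plus a mismatch-count column."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.strand)):
            end = h.start + len(h.matched_sequence)
            fh.write(
                f"{h.chrom}\t{h.start}\t{end}\t{h.motif}\t0\t{h.strand}\t"
                f"{h.mismatches}\n"
            )
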