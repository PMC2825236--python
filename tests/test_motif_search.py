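"""IUPAC mismatch counting, anchored box searches and genome k-mer scans."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tagcontig as tg
from tagcontig.contig_assembly import TagContig
from tagcontig.motif_search import (
    BOX_ACA,
    BOX_C,
    BOX_D,
    BOX_H,
    IUPAC_SETS,
    MotifSpec,
    anchored_search,
    call_box_cd,
    call_box_haca,
    genome_kmer_scan,
    iupac_mismatch_count,
    load_motif_specs,
    stratify_hits,
)
from tagcontig.synthetic_data import KMER_18

from conftest import brute_force_scan, random_genome


def TC(start, end, strand="+", chrom="chr1", depth=100.0):
    return TagContig(chrom, start, end, strand, depth, 1, depth, ("t",))


def _expansion_min_hamming(pattern: str, seq: str) -> int:
    """Independent oracle: minimal Hamming distance over all concrete
    expansions of the degenerate pattern."""
    choices = [sorted(IUPAC_SETS[p]) for p in pattern]
    return min(
        sum(1 for a, b in zip(exp, seq) if a != b)
        for exp in itertools.product(*choices)
    )


class TestIupacMismatch:
    def test_r_accepts_a(self):
        assert iupac_mismatch_count("RTGATGA", "ATGATGA") == 0

    def test_c_is_outside_r(self):
        assert iupac_mismatch_count("RTGATGA", "CTGATGA") == 1

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            iupac_mismatch_count("ACGT", "ACG")

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        pattern=st.text(alphabet="ACGTRYNSWKM", min_size=1, max_size=6),
        seq=st.text(alphabet="ACGT", min_size=6, max_size=6),
    )
    def test_matches_expansion_oracle(self, pattern, seq):
        seq = seq[:len(pattern)]
        assert iupac_mismatch_count(pattern, seq) == \
            _expansion_min_hamming(pattern, seq)


def _genome_from(seq: str, name="chr1") -> tg.Genome:
    return tg.Genome([name], {name: seq})


class TestAnchoredSearch:
    def test_planted_box_c_near_five_prime(self):
        rng = np.random.default_rng(0)
        g = random_genome(rng, 400, "chr1")
        seq = list(g.sequences["chr1"])
        seq[104:111] = "ATGATGA"  # 4 nt inside the 5' end of TC [100, 180)
        g = _genome_from("".join(seq))
        hit = anchored_search(TC(100, 180), g, BOX_C)
        assert hit is not None and hit.mismatches == 0
        assert hit.tc_offset == 4
        assert hit.start == 104

    def test_motif_beyond_tc_three_prime_end_is_found(self):
        rng = np.random.default_rng(1)
        g = random_genome(rng, 400, "chr1")
        seq = list(g.sequences["chr1"])
        seq[100:188] = "T" * 88   # wipe accidental ACA in the tail and flank
        seq[188:191] = "ACA"      # 8 nt downstream of the 3' end
        seq[191:203] = "T" * 12
        g = _genome_from("".join(seq))
        hit = anchored_search(TC(100, 180), g, BOX_ACA)
        assert hit is not None
        assert hit.tc_offset == 88  # outside the 80-nt TC

    def test_no_hit_within_budget_returns_none(self):
        g = _genome_from("T" * 300)
        assert anchored_search(TC(100, 180), g, BOX_C) is None

    def test_window_truncated_at_chromosome_edge(self):
        g = _genome_from("ATGATGA" + "T" * 73)
        hit = anchored_search(TC(0, 60), g, BOX_C)
        assert hit is not None and hit.tc_offset == 0

    def test_tie_break_prefers_fewest_mismatches_then_anchor_distance(self):
        g = _genome_from("T" * 100 + "CTGATGA" + "TT" + "ATGATGA" + "T" * 100)
        # 1-mismatch copy at offset 0, exact copy at offset 9
        hit = anchored_search(TC(100, 180), g, BOX_C)
        assert hit.mismatches == 0 and hit.tc_offset == 9


class TestBoxCalls:
    def _cd_genome(self, strand="+"):
        rng = np.random.default_rng(3)
        g = random_genome(rng, 500, "chr1")
        body = list("T" * 74)
        body[5:12] = "ATGATGA"
        body[74 - 10:74 - 6] = "CTGA"
        insert = "".join(body)
        if strand == "-":
            insert = tg.reverse_complement(insert)
        seq = g.sequences["chr1"][:200] + insert + g.sequences["chr1"][274:]
        return _genome_from(seq)

    def test_planted_cd_called_on_plus_strand(self):
        g = self._cd_genome("+")
        pair = call_box_cd(TC(200, 274, "+"), g)
        assert pair is not None
        c_hit, d_hit = pair
        assert c_hit.tc_offset == 5 and d_hit.tc_offset == 74 - 10

    def test_minus_strand_call_mirrors_plus(self):
        plus = call_box_cd(TC(200, 274, "+"), self._cd_genome("+"))
        minus = call_box_cd(TC(200, 274, "-"), self._cd_genome("-"))
        assert minus is not None
        assert [(h.tc_offset, h.mismatches) for h in minus] == \
            [(h.tc_offset, h.mismatches) for h in plus]

    def test_box_c_alone_is_not_called(self):
        g = _genome_from("T" * 200 + "ATGATGA" + "T" * 200)
        assert call_box_cd(TC(195, 269, "+"), g) is None

    def test_planted_haca_called(self):
        body = list("T" * 145)
        mid = (145 - 6) // 2
        body[mid:mid + 6] = "ACACGA"
        body[140:143] = "ACA"
        g = _genome_from("G" * 100 + "".join(body) + "G" * 100)
        pair = call_box_haca(TC(100, 245, "+"), g)
        assert pair is not None
        h_hit, aca_hit = pair
        assert h_hit.tc_offset == mid and aca_hit.tc_offset == 140

    def test_box_h_outside_midpoint_window_not_called(self):
        body = list("T" * 145)
        body[20:26] = "ACACGA"  # 49 nt from the midpoint anchor
        body[140:143] = "ACA"
        g = _genome_from("G" * 100 + "".join(body) + "G" * 100)
        assert call_box_haca(TC(100, 245, "+"), g) is None


class TestGenomeKmerScan:
    def test_planted_exact_and_one_mismatch_copies(self):
        rng = np.random.default_rng(8)
        g = random_genome(rng, 3000, "chr1")
        seq = list(g.sequences["chr1"])
        seq[500:518] = KMER_18
        mutated = list(KMER_18)
        mutated[9] = "A" if mutated[9] != "A" else "C"
        seq[1500:1518] = mutated
        g = _genome_from("".join(seq))
        strata = stratify_hits(genome_kmer_scan(g, KMER_18, 1))
        assert [h.start for h in strata[0]] == [500]
        assert 1500 in [h.start for h in strata.get(1, [])]

    def test_excluded_chromosomes_skipped(self):
        g = tg.Genome(
            ["chr1", "chrU"],
            {"chr1": "T" * 100, "chrU": "A" * 40 + KMER_18 + "A" * 40},
        )
        assert genome_kmer_scan(g, KMER_18, 0) == []

    def test_matches_brute_force_hamming_scan(self):
        rng = np.random.default_rng(12)
        g = random_genome(rng, 8000)
        kmer = g.sequences["chrR"][4000:4018]
        for m in (0, 1, 2):
            got = {(h.chrom, h.start, h.strand, h.mismatches)
                   for h in genome_kmer_scan(g, kmer, m)}
            assert got == brute_force_scan(g, kmer, m)

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(21)
        g = random_genome(rng, 5000)
        kmer = g.sequences["chrR"][100:118]
        sites = [
            {(h.chrom, h.start, h.strand) for h in genome_kmer_scan(g, kmer, m)}
            for m in (0, 1, 2)
        ]
        assert sites[0] <= sites[1] <= sites[2]

    def test_strand_symmetry_under_genome_reversal(self):
        rng = np.random.default_rng(31)
        g = random_genome(rng, 4000)
        n = 4000
        kmer = g.sequences["chrR"][2000:2018]
        g_rc = tg.Genome(["chrR"], {"chrR": tg.reverse_complement(g.sequences["chrR"])})
        fwd = {(h.start, h.strand, h.mismatches) for h in genome_kmer_scan(g, kmer, 1)}
        mirrored = {
            (n - h.start - 18, "-" if h.strand == "+" else "+", h.mismatches)
            for h in genome_kmer_scan(g_rc, kmer, 1)
        }
        assert fwd == mirrored


class TestMotifSpecConfig:
    def test_specs_load_from_flat_file(self, tmp_path):
        p = tmp_path / "motifs.cfg"
        p.write_text(
            "# name pattern max_mismatches anchor window\n"
            "box_C RTGATGA 1 five_prime 10\n"
            "box_ACA ACA 0 three_prime 20\n"
        )
        specs = load_motif_specs(p)
        assert specs["box_C"] == BOX_C
        assert specs["box_ACA"] == BOX_ACA

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifSpec("bad", "ACGX", 0, "none", 0)
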