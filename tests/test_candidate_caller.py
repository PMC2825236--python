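"""End-to-end pipeline behaviour on the synthetic study fixture."""

import numpy as np
import pandas as pd
import pytest

import tagcontig as tg
from tagcontig.candidate_caller import (
    CallClass,
    dominant_tag_analysis,
    motif_site_census,
    run_pipeline,
)
from tagcontig.filters import FilterConfig
from tagcontig.io_formats import AnnotationFeature, FeatureClass
from tagcontig.mapping import MappedTag
from tagcontig.synthetic_data import KMER_18


class TestRunPipeline:
    def test_recovers_all_planted_candidates(self, default_fixture, pipeline_result):
        stats = tg.recovery_stats(pipeline_result.calls, default_fixture.truth)
        assert stats["recall"] == 1.0

    def test_decoy_removed_by_strand_filter(self, default_fixture, pipeline_result):
        joined = tg.match_calls_to_truth(pipeline_result.calls, default_fixture.truth)
        decoys = joined[joined["expected_call"] == "rejected_strand_filter"]
        assert len(decoys) >= 1
        assert (decoys["called_class"] == "").all()

    def test_each_tc_called_at_most_once(self, pipeline_result):
        keys = [(c.tc.name, c.tc.strand) for c in pipeline_result.calls]
        assert len(keys) == len(set(keys))

    def test_calls_ranked_by_depth_within_class(self, pipeline_result):
        for cls in CallClass:
            depths = [c.tc.tag_depth for c in pipeline_result.calls_of(cls)]
            assert depths == sorted(depths, reverse=True)

    def test_group1_candidate_dominant_tag_carries_18mer(self, pipeline_result):
        (g1,) = pipeline_result.calls_of(CallClass.GROUP1)
        seq, fraction = g1.dominant_tag
        assert KMER_18 in seq
        assert 0.0 < fraction <= 1.0

    def test_empty_tag_library_yields_empty_outputs(self, default_fixture):
        fx = default_fixture
        result = run_pipeline(fx.genome, [], fx.features, fx.conserved)
        assert result.tcs == [] and result.calls == []
        assert all(
            cov.n_overlapped == 0 for cov in result.coverage.classes.values()
        )

    def test_read_mass_conservation(self, pipeline_result):
        retained_ids = {p.tag_id for p in pipeline_result.placements}
        expected = sum(
            t.read_count for t in pipeline_result.tags if t.tag_id in retained_ids
        )
        got = sum(p.weight for p in pipeline_result.placements)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_doubling_reads_doubles_depths_and_preserves_calls(self, default_fixture):
        fx = default_fixture
        doubled = [
            tg.TagRecord(t.tag_id, t.sequence, 2 * t.read_count) for t in fx.tags
        ]
        base = run_pipeline(fx.genome, fx.tags, fx.features, fx.conserved)
        scaled_cfg = FilterConfig(
            haca_depth_min=30.0, cd_depth_min=12.0,
            group_depth_min=200.0, group1_depth_min=2000.0,
        )
        scaled = run_pipeline(
            fx.genome, doubled, fx.features, fx.conserved, config=scaled_cfg
        )
        base_depths = {(t.name, t.strand): t.tag_depth for t in base.tcs}
        for t in scaled.tcs:
            assert t.tag_depth == 2 * base_depths[(t.name, t.strand)]
        assert {(c.tc.name, c.call_class) for c in scaled.calls} == \
            {(c.tc.name, c.call_class) for c in base.calls}

    def test_persisted_tables_written(self, default_fixture, tmp_path):
        fx = default_fixture
        run_pipeline(fx.genome, fx.tags, fx.features, fx.conserved,
                     out_dir=tmp_path / "out")
        for fname in ("tag_contigs.bed", "tc_classification.tsv",
                      "coverage_report.tsv", "candidates.tsv", "stage_counts.tsv"):
            assert (tmp_path / "out" / fname).exists()

    def test_byte_identical_reruns(self, default_fixture, tmp_path):
        fx = default_fixture
        for d in ("a", "b"):
            run_pipeline(fx.genome, fx.tags, fx.features, fx.conserved,
                         out_dir=tmp_path / d)
        for fname in ("tag_contigs.bed", "candidates.tsv", "coverage_report.tsv"):
            assert (tmp_path / "a" / fname).read_bytes() == \
                (tmp_path / "b" / fname).read_bytes()


class TestDominantTag:
    def _call(self, tc):
        return tg.CandidateCall(tc=tc, call_class=CallClass.GROUP1)

    def test_weighted_majority_sequence(self):
        tc = tg.TagContig("chr1", 0, 30, "+", 40.0, 2, 40.0, ("a", "b"))
        members = [
            MappedTag("a", "chr1", 0, 20, "+", 1, 30.0),
            MappedTag("b", "chr1", 5, 25, "+", 1, 10.0),
        ]
        tags = [tg.TagRecord("a", "A" * 20, 30), tg.TagRecord("b", "C" * 20, 10)]
        seq, frac = dominant_tag_analysis(self._call(tc), members, tags)
        assert seq == "A" * 20
        assert frac == pytest.approx(0.75)

    def test_single_tag_fraction_is_one(self):
        tc = tg.TagContig("chr1", 0, 20, "+", 7.0, 1, 7.0, ("a",))
        members = [MappedTag("a", "chr1", 0, 20, "+", 1, 7.0)]
        seq, frac = dominant_tag_analysis(
            self._call(tc), members, [tg.TagRecord("a", "G" * 20, 7)]
        )
        assert frac == 1.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(17)
        tags = [tg.TagRecord(f"t{k}", "ACGT" * 5, 1) for k in range(3)] + \
               [tg.TagRecord("u", "TTTT" * 5, 1)]
        members = [
            MappedTag(t.tag_id, "chr1", 0, 20, "+", 1, float(rng.integers(1, 10)))
            for t in tags
        ]
        tc = tg.TagContig("chr1", 0, 20, "+", 1.0, 4, 1.0, tuple(t.tag_id for t in tags))
        seq, frac = dominant_tag_analysis(self._call(tc), members, tags)
        tally = {}
        for m in members:
            s = next(t.sequence for t in tags if t.tag_id == m.tag_id)
            tally[s] = tally.get(s, 0.0) + m.weight
        best = max(sorted(tally), key=tally.get)
        assert seq == best
        assert frac == pytest.approx(tally[best] / sum(m.weight for m in members))


class TestMotifSiteCensus:
    def test_planted_sites_cross_tabulated(self):
        rng = np.random.default_rng(19)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq = list(bases[rng.integers(0, 4, size=5000)].tobytes().decode())
        seq[1000:1018] = KMER_18                 # inside an intron
        mutated = list(KMER_18)
        mutated[5] = "A" if mutated[5] != "A" else "C"
        seq[3000:3018] = mutated                 # intergenic, 1 mismatch
        genome = tg.Genome(["chr1"], {"chr1": "".join(seq)})
        annotation = [
            AnnotationFeature("chr1", 800, 1500, "+", FeatureClass.GENE, "g1"),
            AnnotationFeature("chr1", 900, 1400, "+", FeatureClass.INTRON, "g1_intron1"),
        ]
        table = motif_site_census(genome, KMER_18, 1, annotation)
        exact = table[table["mismatches"] == 0]
        assert exact["count"].sum() == 1
        assert exact["context"].iloc[0] == "intronic_sense"
        one_mm = table[
            (table["mismatches"] == 1) & (table["context"] == "intergenic")
        ]
        assert one_mm["count"].sum() == 1

    def test_totals_equal_scan_hits(self):
        rng = np.random.default_rng(23)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = tg.Genome(
            ["chr1"], {"chr1": bases[rng.integers(0, 4, size=20000)].tobytes().decode()}
        )
        kmer = genome.sequences["chr1"][500:518]
        table = motif_site_census(genome, kmer, 2, [])
        hits = tg.genome_kmer_scan(genome, kmer, 2)
        assert table["count"].sum() == len(hits)

    def test_zero_mismatches_reproduces_exact_count(self):
        genome = tg.Genome(["chr1"], {"chr1": "T" * 200 + KMER_18 + "T" * 200})
        table = motif_site_census(genome, KMER_18, 0, [])
        assert table["count"].sum() == 1
        assert set(table["mismatches"]) == {0}
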