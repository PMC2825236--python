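"""Shared fixtures and brute-force oracles.

The oracles here are deliberately naive (per-base arrays, pairwise graph
connectivity, all-windows Hamming scans) so they stay independent of the
sweep/index implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import tagcontig as tg
from tagcontig.mapping import MappedTag


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def perbase_depth(members) -> float:
    """Literal per-base accumulation; members summed in (start, end, id) order."""
    ordered = sorted(members, key=lambda m: (m.start, m.end, m.tag_id))
    lo = min(m.start for m in ordered)
    hi = max(m.end for m in ordered)
    best = 0.0
    for b in range(lo, hi):
        s = 0.0
        for m in ordered:
            if m.start <= b < m.end:
                s += m.weight
        if s > best:
            best = s
    return best


def connected_components(members) -> list[frozenset]:
    """Components of the >= 1-nt overlap graph by pairwise union-find."""
    ms = list(members)
    parent = list(range(len(ms)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            a, b = ms[i], ms[j]
            if (a.chrom, a.strand) == (b.chrom, b.strand) and \
                    min(a.end, b.end) - max(a.start, b.start) >= 1:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(len(ms)):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def brute_force_map(genome: tg.Genome, tags) -> set:
    """All exact full-length placements by a sliding-window scan."""
    hits = set()
    for chrom in genome.active_chroms:
        seq = genome.sequences[chrom]
        for t in tags:
            L = len(t.sequence)
            rc = tg.reverse_complement(t.sequence)
            for i in range(len(seq) - L + 1):
                w = seq[i:i + L]
                if w == t.sequence:
                    hits.add((t.tag_id, chrom, i, i + L, "+"))
                if w == rc:
                    hits.add((t.tag_id, chrom, i, i + L, "-"))
    return hits


def brute_force_scan(genome: tg.Genome, kmer: str, max_mismatches: int) -> set:
    """All-windows Hamming scan on both strands."""
    hits = set()
    rc = tg.reverse_complement(kmer)
    m = len(kmer)
    for chrom in genome.active_chroms:
        seq = genome.sequences[chrom]
        for strand, pat in (("+", kmer), ("-", rc)):
            for i in range(len(seq) - m + 1):
                mm = sum(1 for a, b in zip(seq[i:i + m], pat) if a != b)
                if mm <= max_mismatches:
                    hits.add((chrom, i, strand, mm))
    return hits


def random_placements(rng, n, span=100, chroms=("chrA",), strands=("+", "-")):
    """Random weighted placements for assembly property tests."""
    out = []
    for k in range(n):
        start = int(rng.integers(0, span - 5))
        length = int(rng.integers(5, 30))
        out.append(MappedTag(
            tag_id=f"t{k}",
            chrom=str(rng.choice(list(chroms))),
            start=start,
            end=min(span, start + length),
            strand=str(rng.choice(list(strands))),
            n_loci=1,
            weight=float(rng.integers(1, 20)) / float(rng.integers(1, 4)),
        ))
    return out


def random_genome(rng, length, name="chrR") -> tg.Genome:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
    return tg.Genome([name], {name: seq})


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_fixture() -> tg.FixtureResult:
    """The default synthetic study fixture (seed 1, 200 kb)."""
    return tg.generate_fixture(tg.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_fixture) -> tg.PipelineResult:
    fx = default_fixture
    return tg.run_pipeline(fx.genome, fx.tags, fx.features, fx.conserved)
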