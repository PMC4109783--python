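"""Shared fixtures: simulated datasets, pipeline runs and oracles."""

from __future__ import annotations

import random

import pytest

from omscaffold.align import score_block
from omscaffold.digest import digest
from omscaffold.scaffolding import scaffold_assembly
from omscaffold.simulate import SimulationConfig, simulate_dataset

BENCHMARK_SEED = 42


def brute_force_best(q, t, params):
    """Exhaustive search over all monotone block decompositions.

    Enumerates every chain of blocks (each side merging at most
    ``max_merge`` fragments) with every admissible start and end,
    including clipped scaffold ends, and returns the best total score.
    Independent of the DP implementation; tractable only for small
    maps.
    """
    m, n = len(q), len(t)
    mm = params.max_merge
    best = [None]

    def extend(i, j, score, n_blocks):
        if n_blocks >= 1:
            end_cost = 0.0 if (i == m or j == n) else -params.clip_penalty * (m - i)
            total = score + end_cost
            if best[0] is None or total > best[0]:
                best[0] = total
        if i == m or j == n:
            return
        for a in range(1, min(mm, m - i) + 1):
            for b in range(1, min(mm, n - j) + 1):
                extend(
                    i + a,
                    j + b,
                    score + score_block(q[i : i + a], t[j : j + b], params),
                    n_blocks + 1,
                )

    for i0 in range(m):
        for j0 in range(n):
            start = 0.0 if (i0 == 0 or j0 == 0) else -params.clip_penalty * i0
            extend(i0, j0, start, 0)
    return best[0]


def naive_site_scan(sequence, site, cut_offset):
    """Character-by-character occurrence scan (overlaps included)."""
    seq = sequence.upper()
    out = []
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            cut = i + cut_offset
            if 0 < cut < len(seq):
                out.append(cut)
    return out


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def noise_dataset():
    """Default-noise benchmark dataset (10 Mb, 8 map contigs)."""
    return simulate_dataset(SimulationConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def noise_result(noise_dataset):
    ds = noise_dataset
    smaps = [digest(rec) for rec in ds.scaffolds]
    lengths = {rec.id: len(rec) for rec in ds.scaffolds}
    return scaffold_assembly(smaps, ds.optical_maps, lengths)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: exact optical maps, no chimeras."""
    config = SimulationConfig(
        seed=7,
        genome_length=5_000_000,
        n_map_contigs=4,
        sizing_cv=0.0,
        missing_cut_prob=0.0,
        false_cut_rate=0.0,
        chimera_rate=0.0,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_result(clean_dataset):
    ds = clean_dataset
    smaps = [digest(rec) for rec in ds.scaffolds]
    lengths = {rec.id: len(rec) for rec in ds.scaffolds}
    return scaffold_assembly(smaps, ds.optical_maps, lengths)
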