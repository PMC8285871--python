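"""Shared fixtures: tiny hand-built genomes, alignments and simulations."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from allosort.io_formats import AlignmentRecord, GenomeSequence
from allosort.simulator import SimConfig, simulate_reads

logging.getLogger("allosort").setLevel(logging.ERROR)


def make_aln(
    bases: str,
    chrom: str = "chr1",
    pos: int = 1,
    quals=None,
    q: int = 20,
    bs_strand: str = "CT",
    cigar: str | None = None,
    genome_label: str = "parent1",
    read_id: str = "r1",
    mate: int = 1,
    flag: int = 0,
) -> AlignmentRecord:
    """Hand-built mapped alignment with constant quality by default."""
    return AlignmentRecord(
        read_id=read_id,
        genome_label=genome_label,
        chrom=chrom,
        pos=pos,
        strand="+",
        cigar=cigar or f"{len(bases)}M",
        bs_strand=bs_strand,
        mapped=True,
        bases=bases,
        quals=quals if quals is not None else [q] * len(bases),
        mate=mate,
        flag=flag,
    )


@pytest.fixture
def tiny_genome() -> GenomeSequence:
    return GenomeSequence("parent1", {"chr1": "ACGTACGTACGTACGTACGT"})


@pytest.fixture(scope="session")
def small_benchmark_sim():
    """500 reads/parent at the default study conditions (shared, read-only)."""
    cfg = SimConfig(genome_length=50_000, n_reads=500, seed=1)
    return simulate_reads(cfg, mode="benchmark")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
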