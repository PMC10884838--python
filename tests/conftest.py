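"""Shared fixtures: a toy genome and one simulated dataset per event type.

The event datasets use a reduced ~200 kb genome so the whole suite stays
fast; the full-scale study conditions are exercised by the acceptance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

import gcrscope as g
from gcrscope.classify import analyze, simulate_cohort_files

SMALL_SIZES = (60_000, 100_000, 40_000)

EXPECTED_MECHANISM = {
    "telomere_addition": "de_novo_telomere_addition",
    "chromosome_fusion": "homology_independent_fusion",
    "homology_translocation": "homology_driven_translocation",
    "inversion_plus_deletion": "complex_inversion_plus_deletion",
}


def small_config(seed: int = 7) -> g.ToyGenomeConfig:
    return g.ToyGenomeConfig(seed=seed, chrom_sizes=SMALL_SIZES,
                             essential_gap=20_000)


@pytest.fixture(scope="session")
def toy_genome() -> g.Genome:
    return g.build_toy_genome(small_config())


@dataclass
class EventDataset:
    genome: g.Genome
    truth: g.RearrangementEvent
    sam: Path
    workdir: Path


@pytest.fixture(scope="session")
def event_datasets(tmp_path_factory) -> dict[str, EventDataset]:
    """One simulated dataset per rearrangement mechanism (error rate 0.005,
    30x, 2x150 bp), with truth SAM against the reference."""
    out = {}
    for i, et in enumerate(sorted(EXPECTED_MECHANISM)):
        wd = tmp_path_factory.mktemp(f"ev_{et}")
        genome, truth, sam = simulate_cohort_files(
            wd, et, seed=50 + i, genome_cfg=small_config(seed=50 + i),
            read_cfg=g.ReadSimConfig(seed=150 + i))
        out[et] = EventDataset(genome=genome, truth=truth, sam=sam, workdir=wd)
    return out


@pytest.fixture(scope="session")
def analyzed(event_datasets):
    """Full pipeline evidence + calls per event dataset."""
    out = {}
    for et, ds in event_datasets.items():
        bundle, profile, calls = analyze(ds.genome, ds.sam)
        out[et] = (bundle, profile, calls)
    return out


@pytest.fixture(scope="session")
def plain_library(tmp_path_factory):
    """A proper (rearrangement-free) library from the toy genome."""
    wd = tmp_path_factory.mktemp("plain")
    genome = g.build_toy_genome(small_config(seed=21))
    reads = g.simulate_reads(genome, g.ReadSimConfig(seed=22, error_rate=0.0))
    sam = wd / "plain.sam"
    reads.write_sam(sam)
    return genome, reads, sam
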