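import numpy as np
import pytest

from tssprofiler.genomic_io import CoverageTrack
from tssprofiler.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset at default (noisy) conditions, shared read-only."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-dispersion dataset: emitted counts equal analytic expectations."""
    return generate_dataset(
        SimulationConfig(seed=7, dispersion=0.0, spikein_noise=0.0)
    )


@pytest.fixture()
def small_genome():
    return {"chrA": 10_000, "chrB": 6_000}


@pytest.fixture()
def flat_track(small_genome):
    track = CoverageTrack(small_genome)
    for c in small_genome:
        track.array(c)[:] = 1.0
    return track


def make_stranded_track(genome, entries):
    """entries: iterable of (chrom, pos, strand, value)."""
    track = CoverageTrack(genome, stranded=True)
    for chrom, pos, strand, value in entries:
        track.array(chrom, strand)[pos] += value
    return track


@pytest.fixture()
def make_stranded(small_genome):
    def _make(entries):
        return make_stranded_track(small_genome, entries)

    return _make
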