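"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from finder.genome_io import FeatureTrack, VariantSet
from finder.simulate import SimConfig, simulate_tracks, simulate_variants

SMALL_GENOME = {"chr1": 2_000_000, "chr2": 2_000_000}


def make_track(name, intervals):
    """Intervals as (chrom, start, end) triples."""
    return FeatureTrack(
        name,
        pd.DataFrame(intervals, columns=["chrom", "start", "end"]),
    )


def make_variants(rows, label="test"):
    """Rows as (id, chrom, pos) triples."""
    return VariantSet(pd.DataFrame(rows, columns=["id", "chrom", "pos"]), label=label)


def random_track(rng, name="t", n_max=100, chroms=("chr1", "chr2"), span=1000):
    n = rng.integers(0, n_max + 1)
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span, size=n)
    length = rng.integers(1, 60, size=n)
    return FeatureTrack(
        name, pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=7, genome=dict(SMALL_GENOME))


@pytest.fixture(scope="session")
def small_tracks(small_cfg):
    return simulate_tracks(small_cfg)


@pytest.fixture(scope="session")
def small_variants(small_cfg, small_tracks):
    return simulate_variants(small_cfg, small_tracks)
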