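import dataclasses

import numpy as np
import pytest

from stresscan.annotations_io import CoverageTrack, GenomeLayout
from stresscan.synthetic_data import SyntheticConfig, generate_annotation, generate_tracks


@pytest.fixture
def layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 8_000))


@pytest.fixture
def tiny_config():
    """A fast single-chromosome study for generator unit tests."""
    return SyntheticConfig(seed=7, n_chroms=1, chrom_length=2_500_000, n_genes=80)


@pytest.fixture(scope="session")
def default_study():
    """The default-condition synthetic study (noisy), shared across tests."""
    cfg = SyntheticConfig(seed=1)
    genes, erfs, truth = generate_annotation(cfg)
    tracks = generate_tracks(cfg, genes, truth)
    return cfg, genes, erfs, truth, tracks


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = SyntheticConfig(seed=3, noise=False)
    genes, erfs, truth = generate_annotation(cfg)
    tracks = generate_tracks(cfg, genes, truth)
    return cfg, genes, erfs, truth, tracks


def make_track(layout, segments, **meta):
    """Helper: CoverageTrack from {chrom: [(start, end, value), ...]}."""
    segs = {
        chrom: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows], dtype=float),
        )
        for chrom, rows in segments.items()
    }
    return CoverageTrack(layout, segs, **meta)
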