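import numpy as np
import pytest

import eboxchip as ec


@pytest.fixture(scope="session")
def tiny_cfg() -> ec.SyntheticConfig:
    """Small but complete synthetic study: 140 kb, 10 genes, 4 planted peaks."""
    return ec.SyntheticConfig(
        seed=11,
        chrom_lengths={"chrA": 140_000},
        n_genes=10,
        n_planted_peaks=4,
        n_bound_sites=12,
        n_unbound_sites=40,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    genome, truth = ec.gen_genome(tiny_cfg)
    genes = ec.gen_annotation(tiny_cfg, genome)
    return genome, truth, genes


@pytest.fixture(scope="session")
def uniform_table() -> ec.ShapeTable:
    return ec.uniform_shape_table(mgw=5.0, prot=-8.0, roll=0.0, helt=34.5)


@pytest.fixture(scope="session")
def shape_table() -> ec.ShapeTable:
    return ec.synthetic_shape_table()


def constant_track(chrom="chr1", n=60, spacing=35, value=0.0, start=0):
    pos = start + np.arange(n) * spacing
    return ec.ProbeTrack(chrom, pos, np.full(n, float(value)))
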