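import numpy as np
import pytest

import vespagen as vg


@pytest.fixture(scope="session")
def fixture_panel():
    """The bundled small fixture: 3 populations, nests, planted autozygosity."""
    cfg = vg.SimConfig(seed=11, autozygosity_targets=(0.05, 0.2, 0.5))
    gm, meta, truth = vg.simulate_panel(cfg)
    return cfg, gm, meta, truth


@pytest.fixture(scope="session")
def filtered_panel(fixture_panel):
    cfg, gm, meta, truth = fixture_panel
    return cfg, vg.filter_genotypes(gm), meta, truth


@pytest.fixture(scope="session")
def mito_panel():
    cfg = vg.SimConfig(seed=11)
    aln, truth = vg.simulate_mito(cfg)
    return cfg, aln, truth


def make_matrix(calls, spacing=1000, chrom=None, pos=None, **kwargs):
    """Small-matrix helper: evenly spaced sites on one chromosome by default."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites = calls.shape[1]
    if pos is None:
        pos = np.arange(1, n_sites + 1) * spacing
    if chrom is None:
        chrom = np.full(n_sites, "chr1")
    return vg.GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(calls.shape[0])],
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        calls=calls,
        **kwargs,
    )
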