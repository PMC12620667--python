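"""Shared fixtures: small synthetic datasets and toy matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonalpop.core import DepthMatrix, GenotypeMatrix
from clonalpop.simulate import SimConfig, simulate_dataset


def make_gm(dosages, ploidy=None, contig="c1", spacing=2000) -> GenotypeMatrix:
    """GenotypeMatrix from a dosage array, loci spaced out on one contig."""
    dosages = np.asarray(dosages)
    n, L = dosages.shape
    loci = pd.DataFrame(
        {
            "contig": [contig] * L,
            "pos": [1 + spacing * j for j in range(L)],
            "ref": ["A"] * L,
            "alt": ["T"] * L,
            "multiallelic": [False] * L,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        loci=loci,
        dosages=dosages,
        ploidy=ploidy,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across read-only tests."""
    cfg = SimConfig(
        n_sites=4, samples_per_site=8, n_loci=400, n_adaptive_loci=10, seed=7
    )
    return simulate_dataset(cfg)
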