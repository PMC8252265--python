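import numpy as np
import pandas as pd
import pytest

from slopescan import (
    GenotypeMatrix,
    HaplotypeSet,
    SimulationConfig,
    VariantTable,
    simulate_population,
)


@pytest.fixture(scope="session")
def neutral_pop():
    """A small neutral founder population shared across tests."""
    cfg = SimulationConfig(seed=11, N_e=100, L=500_000, mu=4e-7, r=2e-7)
    hs, vt, gmap, info = simulate_population(cfg)
    return hs, vt, gmap


def toy_variant_table(positions, chrom="chr1"):
    n = len(positions)
    return VariantTable(
        np.array([chrom] * n, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["T"] * n, dtype=object),
        np.array([f"{chrom}_{p}" for p in positions], dtype=object),
    )


def toy_track(ps, positions=None, chrom="chr1"):
    """A minimal GWAS track from a p-value list."""
    if positions is None:
        positions = [1000 * (i + 1) for i in range(len(ps))]
    return pd.DataFrame({"chrom": chrom, "pos": positions, "p": ps})
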