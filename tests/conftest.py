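import numpy as np
import pandas as pd
import pytest

from tspoly.genomeio import GenotypeMatrix, SampleMap
from tspoly.simulate import (
    DemographicModel,
    Population,
    Split,
    StudyConfig,
    scaled_capsella_model,
    synthetic_study,
)


@pytest.fixture(scope="session")
def one_pop_model():
    """Constant-size single population; theta = 4 N mu L = 10 for L = 10 kb."""
    return DemographicModel(
        [Population("p", [(0.0, 1000.0)], 0.0)], mu=2.5e-7, rho=0.0
    )


@pytest.fixture(scope="session")
def two_pop_model():
    """Small two-population split for quick divergence checks."""
    return DemographicModel(
        [Population("a", [(0.0, 1000.0)], 0.0), Population("b", [(0.0, 1000.0)], 0.0)],
        splits=[Split(2000.0, "b", "a")],
        mu=2.5e-7,
        rho=0.0,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """Small three-species study with two balanced windows."""
    cfg = StudyConfig(n_windows=12, n_balanced=2, balanced_span=3, include_selfer2=True)
    return synthetic_study(cfg, seed=42)


@pytest.fixture(scope="session")
def scan_model():
    return scaled_capsella_model(include_selfer2=True)


def make_gm(genotypes, species, populations=None, pos=None, chrom="chr1"):
    """Small literal genotype matrix: genotypes is (n_sites, n_samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    populations = populations or ["."] * n_samples
    sm = SampleMap(
        pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n_samples)],
                "species": species,
                "population": populations,
            }
        )
    )
    pos = np.arange(n_sites, dtype=np.int64) * 10 if pos is None else np.asarray(pos, np.int64)
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        genotypes=g,
        sample_map=sm,
    )
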