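import numpy as np
import pandas as pd
import pytest

from rohpop.core import GenotypeMatrix


def make_matrix(geno, positions=None, chroms=None, populations=None,
                sample_ids=None, ref="A", alt="G"):
    """Build a GenotypeMatrix from a plain genotype array for tests."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    if positions is None:
        positions = (np.arange(n_sites) + 1) * 1000
    if chroms is None:
        chroms = ["chr1"] * n_sites
    sites = pd.DataFrame({
        "chrom": chroms, "pos": np.asarray(positions, dtype=np.int64),
        "ref": ref, "alt": alt, "id": ".",
    })
    if populations is None:
        populations = ["P1"] * n_samples
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(geno, sites, samples)


@pytest.fixture
def mk():
    return make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
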