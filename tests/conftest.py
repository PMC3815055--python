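import numpy as np
import pytest

from gbspredict import GenotypeMatrix, simulate_study


@pytest.fixture(scope="session")
def study():
    """Small synthetic DH study shared by read-only tests: true genotypes,
    observed (GBS-masked) genotypes, pedigree, plot phenotypes, breeding
    values."""
    return simulate_study(n_lines=60, n_chrom=2, markers_per_chrom=200, seed=3)


@pytest.fixture()
def toy_geno():
    """5 lines x 4 markers with hand-placed missingness and heterozygotes."""
    calls = np.array([
        [0, 2, 1, -1],
        [0, 2, 0, -1],
        [2, 2, 0, -1],
        [2, -1, 0, -1],
        [-1, 0, 2, -1],
    ], dtype=np.int8)
    return GenotypeMatrix(
        calls, [f"L{i}" for i in range(5)], [f"M{j}" for j in range(4)],
        np.array(["1", "1", "2", "2"], object), np.array([10, 20, 10, 20]),
    )
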