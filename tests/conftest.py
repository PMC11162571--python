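import numpy as np
import pandas as pd
import pytest

from milkpred.genomics import GenotypeData
from milkpred.pipeline import HerdDataset
from milkpred.simulate import SimConfig, simulate_herd


def make_genotype_data(matrix, chrom="1", sample_prefix="cow"):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if np.isscalar(chrom) or isinstance(chrom, str):
        chrom = [chrom] * p
    mm = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(p)],
            "chrom": [str(c) for c in chrom],
            "pos": np.arange(1, p + 1) * 100,
            "ref": "A",
            "alt": "B",
        }
    )
    return GenotypeData(
        matrix=matrix,
        marker_map=mm,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_cows=60,
        n_snps=80,
        n_qtl=10,
        heritability=(0.5,),
        batch_variance_fraction=0.1,
        mean_subobs=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simulate_herd(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_herd):
    return HerdDataset.from_herd(small_herd)
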