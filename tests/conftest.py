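import numpy as np
import pytest

from brsvd import GenotypeMatrix, PhenotypeTable, SimulationSpec
from brsvd.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs, fully observed."""
    return GenotypeMatrix(
        dosages=np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]]),
        sample_ids=["s1", "s2", "s3"],
        snp_ids=["snp1", "snp2"],
    )


@pytest.fixture
def tiny_phenotypes():
    return PhenotypeTable(
        sample_ids=["s1", "s2", "s3"],
        trait=np.array([0.5, 1.5, -0.5]),
        covariates=np.array([[1.0], [0.0], [1.0]]),
        covariate_names=["sex"],
    )


@pytest.fixture(scope="session")
def small_study():
    """Seeded n=60, k=150 study with 3 strong causal SNPs, one replicate."""
    spec = SimulationSpec(n=60, k=150, n_causal=3, effect_size=1.5,
                          noise_sd=1.0, n_replicates=2, seed=77,
                          causal_min_maf=0.1)
    return simulate_study(spec)


@pytest.fixture
def geno_tsv(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text(
        "sample_id\tsnp1\tsnp2\n"
        "s1\t0\t1\n"
        "s2\t1\t2\n"
        "s3\t2\t0\n"
    )
    return path


@pytest.fixture
def pheno_tsv(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "sample_id\tQ1\tsex\tage\tsmoke\n"
        "s1\t0.5\t1\t44\t0\n"
        "s2\t1.5\t0\t51\t1\n"
        "s3\t-0.5\t1\t63\t0\n"
        "s4\t0.1\t0\t38\t0\n"
        "s5\t0.9\t1\t55\t1\n"
    )
    return path
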