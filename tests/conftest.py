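import numpy as np
import pytest

import snpblup as sb


@pytest.fixture(scope="session")
def small_sim():
    """A modest LD-structured dataset with a polygenic trait (h2 = 0.4)."""
    cfg = sb.SimulationConfig(
        n_individuals=300, n_snps=600, n_chromosomes=3, n_qtl=60, h2_target=0.4, seed=7
    )
    g, data, truth = sb.simulate_dataset(cfg)
    return g, data, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Identity-weight REML fit of the small dataset."""
    g, data, _ = small_sim
    sg = sb.standardize(g)
    vc = sb.reml_direct(data, sg.Z)
    return sg, vc, data


@pytest.fixture()
def toy_genotypes():
    """Hand-written 4-sample, 3-SNP genotype matrix with one missing call."""
    return sb.GenotypeMatrix(
        dosages=np.array([[0, 2, 1], [1, -1, 1], [2, 1, 0], [2, 2, 1]], dtype=np.int8),
        snp_ids=np.array(["s1", "s2", "s3"], dtype=object),
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos=np.array([100, 200, 50]),
        a1=np.array(["A", "G", "T"], dtype=object),
        a2=np.array(["C", "T", "A"], dtype=object),
        sample_ids=np.array(["i1", "i2", "i3", "i4"], dtype=object),
    )
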