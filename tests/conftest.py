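import numpy as np
import pandas as pd
import pytest

from sociogwas.genoqc import GenotypeMatrix
from sociogwas.relatedness import Pedigree
from sociogwas.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """300-animal study with genotypes; shared across read-only tests."""
    cfg = SimulationConfig(n_animals=300, n_founders=60, n_snps=600, seed=42)
    return simulate_study(cfg)


@pytest.fixture()
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {"id": ["s", "d", "o"], "sire": ["0", "0", "s"], "dam": ["0", "0", "d"]}
        )
    )


def make_genotype_matrix(dosages, samples=None, contigs=None, depths=None):
    """GenotypeMatrix from a raw dosage array with autogenerated loci."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if contigs is None:
        contigs = [str(1 + j % 18) for j in range(m)]
    loci = pd.DataFrame({"contig": contigs, "pos": 0, "ref": "A", "alt": "G"})
    loci["pos"] = loci.groupby("contig").cumcount() * 1000 + 1
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages, loci, samples, depths)
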