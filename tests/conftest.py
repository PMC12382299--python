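import numpy as np
import pandas as pd
import pytest

from testcross_gwas.qc import GenotypeMatrix
from testcross_gwas.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """A compact but structurally complete study: LD blocks, noise markers,
    one planted QTL, two testers, two-year p-rep layout."""
    return SimConfig(
        n_fathers=60, n_chromosomes=2, markers_per_chromosome=40,
        ld_block_length=8, within_block_corr=0.9, noise_marker_fraction=0.1,
        replicated_fraction=0.15, qtl_spec=[(0, 2, 1.5)],
        variance_spec=(0.5, 0.3, 0.2, 0.1, 0.1, 0.8), mother_effect=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    geno, pheno, truth = simulate_all(small_config)
    return {"geno": geno, "pheno": pheno, "truth": truth, "config": small_config}


@pytest.fixture()
def toy_geno():
    """Five lines x four markers with a missing call and a het call."""
    dosages = pd.DataFrame(
        {
            "m1": [0, 0, 2, 2, 0],
            "m2": [0, 1, 2, 2, 2],
            "m3": [0, 2, np.nan, 2, 0],
            "m4": [2, 2, 2, 2, 2],
        },
        index=[f"L{i}" for i in range(5)],
        dtype=float,
    )
    marker_map = pd.DataFrame(
        {"chromosome": ["A01"] * 4, "pos": [100, 200, 300, 400]},
        index=pd.Index(["m1", "m2", "m3", "m4"], name="marker"),
    )
    return GenotypeMatrix(dosages, marker_map)
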