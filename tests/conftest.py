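import numpy as np
import pandas as pd
import pytest

import dosaqtl as dq


@pytest.fixture(scope="session")
def pool():
    """A medium haplotype pool: 2000 haplotypes, 3000 variants, block LD."""
    return dq.simulate_haplotype_pool(2000, 3000, seed=11)


@pytest.fixture(scope="session")
def cohort(pool):
    """450 unrelated individuals drawn from the pool."""
    return dq.sample_cohort(pool, 450, seed=12)


@pytest.fixture(scope="session")
def dosage_matrix(pool, cohort):
    """High-quality dosages (target r2 = 0.95) for the cohort."""
    return dq.degrade_to_dosages(cohort, pool, dq.QualitySpec(target_rsq=0.95), seed=13)


@pytest.fixture()
def toy_matrix():
    """Five hand-built variants x 6 samples with controllable metadata."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 1.0, 0.0, 1.0],
            [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],
            [2.0, 2.0, 1.0, 2.0, 2.0, 1.0],
            [0.0, 1.0, 0.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 1.0, 0.0, 2.0, 0.0],
        ]
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [100, 200, 300, 400, 500],
            "ref": list("ACGTA"),
            "alt": list("GTACC"),
            "rsq": [0.99, 0.8, 0.71, 0.70, 0.5],
            "is_biallelic": [True, True, True, True, False],
            "kind": "snp",
        }
    )
    return dq.DosageMatrix(
        dosages=dosages, variants=variants, samples=[f"S{i}" for i in range(6)]
    )
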