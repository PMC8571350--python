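import numpy as np
import pytest
from hypothesis import settings

import panelqc as pq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Small admixed cohort reused by IO / eval tests."""
    return pq.simulate_panel(
        pq.CohortSpec(n_samples=60, n_variants=2000, chrom_length=2_000_000, seed=1)
    )


@pytest.fixture(scope="session")
def pedigree_sim():
    """Cohort at kinship-resolution (20k sites) with the default pedigree mix."""
    sim = pq.simulate_panel(
        pq.CohortSpec(n_samples=60, n_variants=20_000, chrom_length=20_000_000, seed=1)
    )
    ped = pq.simulate_pedigree(
        sim.panel,
        pq.PedigreeSpec(n_trios=1, n_duos=6, n_sib_pairs=6, n_cousin_pairs=6, seed=2),
    )
    return sim, ped


def toy_genotypes(gt_rows, samples=None, variants=None, gq=None, dp=None):
    """Build a GenotypeMatrix from a variants-x-samples list of lists."""
    gt = np.asarray(gt_rows, dtype=np.int16).T
    n, m = gt.shape
    samples = samples or [f"s{i}" for i in range(n)]
    variants = variants or [
        pq.VariantKey("1", 100 + 10 * j, "A", "G") for j in range(m)
    ]
    gq_arr = None if gq is None else np.asarray(gq, dtype=np.int32).T
    dp_arr = None if dp is None else np.asarray(dp, dtype=np.int32).T
    return pq.GenotypeMatrix(samples, variants, gt, gq_arr, dp_arr)
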