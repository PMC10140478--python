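import numpy as np
import pandas as pd
import pytest

from twinbile.synthetic import AceSpec, CohortDesign, simulate_twin_cohort, simulate_microbiome


@pytest.fixture(scope="session")
def small_cohort():
    """60 MZ + 40 DZ pairs + 20 singletons with one moderately heritable trait."""
    design = CohortDesign(n_mz_pairs=60, n_dz_pairs=40, n_singletons=20, seed=123)
    return simulate_twin_cohort(design, {"trait": AceSpec(0.6, 0.2, 0.2)})


@pytest.fixture(scope="session")
def small_profile():
    """200 samples x 30 species with mixed prevalence."""
    rng = np.random.default_rng(7)
    prev = rng.uniform(0.3, 1.0, 30)
    return simulate_microbiome(200, 30, prev, seed=7)


@pytest.fixture()
def singleton_meta():
    def make(n):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i:05d}" for i in range(n)],
                "family_id": [f"F{i:05d}" for i in range(n)],
                "zygosity": "SINGLETON",
            }
        )

    return make
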