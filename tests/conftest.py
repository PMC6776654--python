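import numpy as np
import pandas as pd
import pytest

from gutmet.pedigree import Pedigree
from gutmet.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    spec = CohortSpec(
        n_mz_pairs=25, n_dz_pairs=25, n_singletons=50,
        n_species=20, n_pathways=10,
        n_faecal_mets=15, n_blood_mets=15,
        n_planted_effects=4, n_planted_trios=2,
        effect_size=0.7, heritability=0.4, missing_rate=0.03,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def toy_pedigree():
    return Pedigree(pd.DataFrame({
        "family_id": ["F1", "F1", "F2", "F2", "F3"],
        "individual_id": ["a", "b", "c", "d", "e"],
        "zygosity": ["MZ", "MZ", "DZ", "DZ", "NA"],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
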