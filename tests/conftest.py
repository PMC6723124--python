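import numpy as np
import pytest

from lifegwas.simcohort import CausalEffect, SimConfig, simulate_study


@pytest.fixture(scope="session")
def null_study():
    """Mid-sized cohort with no causal loci and no record loss."""
    cfg = SimConfig(
        n_offspring=4000,
        n_variants=300,
        missing_death_base_rate=0.0,
        birth_year_range=(1886, 1905),
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def causal_study():
    """Cohort with one strong paternal-lifespan locus (2 yr/allele, p~0.3)."""
    cfg = SimConfig(
        n_offspring=8000,
        n_variants=120,
        maf_spectrum=("uniform", 0.25, 0.35),
        causal_effects=(CausalEffect(0, "paternal_lifespan", 2.0),),
        missing_death_base_rate=0.0,
        birth_year_range=(1886, 1905),
        seed=23,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
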