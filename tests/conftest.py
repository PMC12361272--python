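import numpy as np
import pytest

import grskit as gk


@pytest.fixture(scope="session")
def default_pool():
    return gk.default_haplotype_pool()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with every generator feature switched on."""
    cfg = gk.SimulationConfig(
        n_cases=400,
        n_controls=600,
        haplotype_pool=gk.default_haplotype_pool(),
        interaction_effects=gk.default_interaction_effects(),
        tag_specs={
            gk.default_haplotype_pool()[0].label: 1.0,
            gk.default_haplotype_pool()[1].label: 0.9,
        },
        nonhla_snps=[gk.SnpSpec(*t) for t in gk.T1D_SNP_EFFECTS],
        covariate_effects=(0.2, [0.3]),
        intercept=-2.0,
        missing_rate=0.02,
        seed=123,
    )
    return gk.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
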