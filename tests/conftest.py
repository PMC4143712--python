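import numpy as np
import pytest

from lbltvc import (AnalysisConfig, Cohort, MCMCSettings, SimScenario,
                    generate_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated default-scenario cohort (250 individuals, 4 exams)."""
    geno, pheno, truth = generate_dataset(SimScenario(), seed=42)
    return Cohort(geno, pheno), truth


@pytest.fixture()
def short_config():
    """Shortened chain settings for fast fixture fits."""
    return AnalysisConfig(
        mcmc=MCMCSettings(iterations=2000, burn_in=500, thinning=5, seed=3))


def random_frequency_model(rng, m):
    """Random valid (f, d) pair for property tests."""
    from lbltvc.haplotypes import FrequencyModel, d_lower_bound
    f = rng.dirichlet(np.ones(m))
    lo = d_lower_bound(f)
    d = rng.uniform(lo + 1e-6, 0.999)
    haps = [f"H{i}" for i in range(m)]
    return FrequencyModel(haplotypes=haps, f=f, d=d)
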