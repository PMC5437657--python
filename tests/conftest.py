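import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import seqalloc as sa


@pytest.fixture(scope="session")
def tiny_population():
    """A small 3-generation bred population shared across tests."""
    cfg = sa.SimConfig(
        n_chromosomes=2, n_snps_per_chr=100, n_base_haplotypes=60,
        n_generations=3, n_per_generation=40, n_sires_selected=4,
        n_dams=20, n_qtn=40, seed=11,
    )
    base = sa.simulate_base_haplotypes(cfg)
    ped, panel, trait = sa.simulate_pedigree_population(cfg, base)
    return cfg, base, ped, panel, trait


@pytest.fixture(scope="session")
def tiny_library(tiny_population):
    _cfg, _base, _ped, panel, _trait = tiny_population
    eligible = sa.filter_eligible(panel, 0.9)
    windows = sa.build_windows(100, 25, 2)
    return sa.build_library(panel, windows, eligible)


def random_panel(rng, n_ind, n_snps, missing_rate=0.0):
    """Small fully random phased panel (one chromosome) for oracle tests."""
    alleles = rng.integers(0, 2, size=(n_ind, 2, n_snps)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(alleles.shape) < missing_rate
        alleles[miss] = sa.MISSING
    return sa.PhasedPanel(np.arange(1, n_ind + 1), [alleles])
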