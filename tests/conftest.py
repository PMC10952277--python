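import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ovistep import SimConfig, drop_genotypes, simulate_pedigree, simulate_traits
from ovistep.pedigree import Pedigree, sort_and_validate
from ovistep.varcomp import VarianceComponents

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# confounded-column warnings are expected on small simulated designs
warnings.filterwarnings("ignore", message=".*confounded fixed-effect columns.*")

SCAN_WEIGHT = dict(sigma2_a=8.97, sigma2_e=18.58)  # moderate-heritability truth


def random_pedigree(rng: np.random.Generator, n: int, p_known: float = 0.8) -> Pedigree:
    """Random valid pedigree: parents drawn among earlier animals."""
    records = []
    for i in range(n):
        sire = dam = "0"
        males = [j for j in range(i) if j % 2 == 0]
        females = [j for j in range(i) if j % 2 == 1]
        if males and rng.random() < p_known:
            sire = f"A{rng.choice(males)}"
        if females and rng.random() < p_known:
            dam = f"A{rng.choice(females)}"
        sex = "M" if i % 2 == 0 else "F"
        records.append((f"A{i}", sire, dam, sex, "F1", 2000 + i // 10))
    order = rng.permutation(n)
    return sort_and_validate([records[i] for i in order])


@pytest.fixture(scope="session")
def scan_vc() -> VarianceComponents:
    return VarianceComponents(**SCAN_WEIGHT)


@pytest.fixture(scope="session")
def small_sim(scan_vc):
    """A compact error-free flock shared by several suites."""
    cfg = SimConfig(
        n_founders=120, n_generations=2, n_flocks=2, dams_per_sire=4,
        seed=77, n_snps=500, prop_genotyped=0.4, prop_phenotyped=0.8,
        genotyping_error_rate=0.0, missing_rate=0.0,
        trait_components={"swt": scan_vc},
    )
    ped = simulate_pedigree(cfg)
    panel = drop_genotypes(ped, cfg)
    phen, truth = simulate_traits(ped, cfg)
    return cfg, ped, panel, phen, truth
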