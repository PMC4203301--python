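import numpy as np
import pandas as pd
import pytest

from hfcsurv import simulate as sim
from hfcsurv.genotypes import MISSING, GenotypeTable


def make_table(rows, loci=None):
    """Build a GenotypeTable from {individual: [(a,b) or None, ...]}."""
    individuals = list(rows)
    L = len(next(iter(rows.values())))
    loci = loci or [f"L{j}" for j in range(L)]
    a1 = np.full((len(individuals), L), MISSING, dtype=np.int64)
    a2 = np.full((len(individuals), L), MISSING, dtype=np.int64)
    for i, ind in enumerate(individuals):
        for j, call in enumerate(rows[ind]):
            if call is not None:
                a1[i, j], a2[i, j] = call
    return GenotypeTable(individuals, loci, a1, a2)


def random_table(rng, n=30, L=8, n_alleles=4, missing_rate=0.0):
    a1 = rng.integers(1, n_alleles + 1, (n, L))
    a2 = rng.integers(1, n_alleles + 1, (n, L))
    if missing_rate:
        gone = rng.random((n, L)) < missing_rate
        a1[gone] = MISSING
        a2[gone] = MISSING
        # keep every individual typed somewhere
        for i in range(n):
            if (a1[i] == MISSING).all():
                a1[i, 0], a2[i, 0] = 1, 2
    return GenotypeTable([f"i{k}" for k in range(n)],
                         [f"L{j}" for j in range(L)], a1, a2)


@pytest.fixture(scope="session")
def small_population():
    """One moderately sized simulated population shared across tests."""
    cfg = sim.scenario("paternal_x_rain", seed=11, n_years=10, n_founders=100)
    return sim.simulate_population(cfg)


@pytest.fixture(scope="session")
def null_population():
    cfg = sim.scenario("null", seed=7, n_years=8, n_founders=80)
    return sim.simulate_population(cfg)
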