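import numpy as np
import pytest

from plastinet.datamodel import TimeGrid, compute_plasticity
from plastinet.synthdata import (
    QtlSpec,
    SimConfig,
    gwas_grid,
    sample_stable_system,
    simulate_curve_clusters,
    simulate_population,
)


@pytest.fixture(scope="session")
def grid6() -> TimeGrid:
    return gwas_grid()


@pytest.fixture(scope="session")
def null_population():
    """A population with no planted QTLs (n=100, m=40)."""
    cfg = SimConfig(n=100, m=40, seed=11)
    traj, geno, truth = simulate_population(cfg)
    return traj, geno, truth


@pytest.fixture(scope="session")
def qtl_population():
    """A population with one strong planted QTL at index 7."""
    shift = 2.0 * np.sqrt(2.0)  # 2 sd of plasticity noise per allele
    cfg = SimConfig(n=100, m=40, qtls=[QtlSpec(snp_index=7, stress_shift=shift)],
                    seed=23)
    traj, geno, truth = simulate_population(cfg)
    return traj, geno, truth


@pytest.fixture(scope="session")
def planted_clusters():
    curves, labels = simulate_curve_clusters(150, 3, 5.0, seed=5)
    return curves, labels


@pytest.fixture(scope="session")
def planted_system():
    """A stable random 10-node driven system with 2 regulators per node."""
    return sample_stable_system(10, 2, seed=3)


@pytest.fixture()
def plasticity_null(null_population):
    traj, _, _ = null_population
    return compute_plasticity(traj)
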