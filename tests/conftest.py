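"""Shared fixtures.

The expensive resources — forward simulations and the trained desk-scale
network — are session-scoped and shared across test modules so the whole
suite stays within a CPU budget a laptop can afford.
"""

import warnings

import numpy as np
import pytest

import msprime

warnings.simplefilter("ignore", msprime.TimeUnitsMismatchWarning)
warnings.simplefilter("ignore", msprime.IncompletePopulationMetadataWarning)

from sigmanet.io import GenotypeMatrix, LocationsTable, read_store
from sigmanet.network import NetworkSpec
from sigmanet.simulate import SimParams, generate_training_set, run_simulation
from sigmanet.training import PairwiseDispersalNet, TrainingConfig


def random_dataset(n, m, rng, width=10.0):
    """A random (genotypes, locations) dataset for architecture tests."""
    counts = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    # keep the minor-allele invariant: flip columns with frequency > 0.5
    freq = counts.sum(axis=0) / (2 * n)
    counts[:, freq > 0.5] = 2 - counts[:, freq > 0.5]
    ids = [str(i) for i in range(n)]
    g = GenotypeMatrix(counts, np.arange(1, m + 1), ids)
    loc = LocationsTable(ids, rng.uniform(0, width, n), rng.uniform(0, width, n))
    return g, loc


@pytest.fixture(scope="session")
def desk_template():
    return SimParams.desk(sigma_f=1.0)


@pytest.fixture(scope="session")
def kernel_sim():
    """One simulation with a generous displacement log for kernel checks."""
    return run_simulation(SimParams.desk(sigma_f=0.6, seed=42, min_snps=300))


@pytest.fixture(scope="session")
def train_store(tmp_path_factory):
    """Desk-scale training store: 60 simulations x 10 draws, n=10, m=500."""
    path = tmp_path_factory.mktemp("stores") / "train.store"
    return generate_training_set(60, 10, n=10, m=500,
                                 params_template=SimParams.desk_training(),
                                 rng_seed=11, path=path)


@pytest.fixture(scope="session")
def heldout_store(tmp_path_factory):
    """Held-out simulations (disjoint seeds from the training store)."""
    path = tmp_path_factory.mktemp("stores") / "heldout.store"
    return generate_training_set(15, 4, n=10, m=500,
                                 params_template=SimParams.desk_training(),
                                 rng_seed=99, path=path)


@pytest.fixture(scope="session")
def fitted_results(train_store):
    """The trained desk-scale network (shared by recovery checks).

    Fixed epoch budget (no early stopping): stopping on a small, noisy
    validation split adds run-to-run variance without improving the fit.
    """
    spec = NetworkSpec(n=10, m=500, filters_per_block=(16, 32),
                       pair_feature_width=64)
    cfg = TrainingConfig(learning_rate=1e-3, batch_size=16, max_epochs=130,
                         patience=130, lr_patience=10, k_extract=16, seed=1)
    return PairwiseDispersalNet(spec).fit(train_store, cfg)


@pytest.fixture(scope="session")
def matched_sims():
    """Simulations with census >= 100, for sample-size comparisons."""
    sims = []
    rng = np.random.default_rng(2024)
    for k in range(12):
        sf = float(rng.uniform(0.2, 3.0))
        sims.append(run_simulation(
            SimParams.desk(sigma_f=sf, seed=3000 + k, min_snps=750)
        ))
    return sims


@pytest.fixture(scope="session")
def ibd_sims_small_sigma():
    """Replicate sims at sigma_f = 0.4 (strong isolation by distance)."""
    return [run_simulation(SimParams.desk(sigma_f=0.4, seed=500 + k, min_snps=750))
            for k in range(10)]


@pytest.fixture(scope="session")
def ibd_sims_mid_sigma():
    """Replicate sims at sigma_f = 1.0."""
    return [run_simulation(SimParams.desk(sigma_f=1.0, seed=700 + k, min_snps=750))
            for k in range(10)]


@pytest.fixture(scope="session")
def ibd_sims_large_sigma():
    """Replicate sims at sigma_f = 3.0 (near-panmictic at desk scale)."""
    return [run_simulation(SimParams.desk(sigma_f=3.0, seed=900 + k, min_snps=750))
            for k in range(10)]
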