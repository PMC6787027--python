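"""Shared fixtures: the synthetic 64-variant study and one reference fit.

The study emulates the measured dataset's structure: the full combinatorial
slippery-sequence design, ground-truth per-change free energies inside the
prior box, equilibrium frameshifting (no kinetic damping) and 2-percentage-
point Gaussian replicate noise.  The reference fit (two chains, 30 000
Metropolis steps) is session-scoped because several modules interrogate the
same posterior.
"""

import numpy as np
import pytest

import fsthermo as ft
from fsthermo.synthetic import default_invitro_truth, simulate_fs_dataset

STUDY_SEED = 11
FIT_SEED = 5
STUDY_STEPS = 30_000


@pytest.fixture(scope="session")
def study():
    design, truth = default_invitro_truth(seed=STUDY_SEED)
    data = simulate_fs_dataset(design, truth)
    return {
        "design": design,
        "truth": truth,
        "data": data,
        "fs": data["fs"].to_numpy(),
        "sigma": data["sigma"].to_numpy(),
    }


@pytest.fixture(scope="session")
def study_config():
    return ft.FitConfig(n_steps=STUDY_STEPS, n_chains=2, rng_seed=FIT_SEED)


@pytest.fixture(scope="session")
def study_chains(study, study_config):
    return ft.run_chains(study["fs"], study["sigma"], study["design"], study_config)


@pytest.fixture(scope="session")
def study_summary(study_chains, study_config):
    return ft.summarize(study_chains, study_config)


@pytest.fixture(scope="session")
def study_pooled(study_chains, study_config):
    return ft.pooled_samples(study_chains, study_config.burn_in_fraction)


@pytest.fixture(scope="session")
def study_kinetic_chain(study):
    """Kinetic fit (κ̄ as nuisance) on the equilibrium-truth study data."""
    cfg = ft.FitConfig(
        n_steps=3_000,
        n_chains=1,
        rng_seed=FIT_SEED,
        kinetic_enabled=True,
        kappa_proposal_sigma=0.005,
    )
    chain = ft.metropolis_run_kinetic(
        study["fs"], study["sigma"], study["design"], cfg
    )
    return chain, cfg


def make_design(entries, col_labels, row_labels=None):
    """Small hand-built design matrices for toy problems."""
    entries = np.asarray(entries)
    if row_labels is None:
        row_labels = [f"v{i}" for i in range(entries.shape[0])]
    return ft.DesignMatrix(entries, row_labels, list(col_labels))
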