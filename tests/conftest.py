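"""Shared fixtures.  BLAS threading is pinned to one thread before NumPy
loads: the models' matrices are small and oversubscription dominates
runtime otherwise (it also makes runs bit-reproducible)."""

import os

for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS", "VECLIB_MAXIMUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from gaitphase.synthetic import GaitSimParams, generate_dataset


@pytest.fixture(scope="session")
def clockwork_params() -> GaitSimParams:
    """Zero-variance schedule: 1.0 s cycles, 60% stance, half-cycle offset."""
    return GaitSimParams(
        n_subjects=1,
        trials_per_subject=1,
        trial_duration=10.0,
        fs=200.0,
        cycle_mean=1.0,
        cycle_cv=0.0,
        stance_fraction=0.6,
        contralateral_offset=0.5,
        subject_amp_sd=0.0,
        subject_cadence_sd=0.0,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_params() -> GaitSimParams:
    """A small but non-degenerate multi-subject dataset."""
    return GaitSimParams(
        n_subjects=3,
        trials_per_subject=2,
        trial_duration=12.0,
        fs=200.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return generate_dataset(small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
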