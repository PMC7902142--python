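"""Shared fixtures: small synthetic cohorts, cleaned and cached per session."""

from __future__ import annotations

import numpy as np
import pytest

from gaitanomaly import CohortSpec, generate_cohort
from gaitanomaly.preprocess import clean_sequence


def clean_cohort(spec: CohortSpec):
    """Generate and preprocess a cohort; returns (sequences, manifest)."""
    seqs, manifest = generate_cohort(spec)
    return [clean_sequence(s) for s in seqs], manifest


@pytest.fixture(scope="session")
def small_cohort():
    """20 normal + 8 abnormal walkers, cleaned, unshuffled (normals first)."""
    spec = CohortSpec(n_normal=20, n_abnormal=8, seed=7, shuffle=False)
    return clean_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
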