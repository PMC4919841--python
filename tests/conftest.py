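"""Shared fixtures: small databases, synthetic studies and session-scoped
benchmark results reused by several tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from metaproiq.catalog_store import ProteinDatabase, ProteinRecord
from metaproiq.evaluation import biology_recovery_experiment, fdr_calibration_summary
from metaproiq.synthetic_fixtures import CommunitySpec, make_catalog, make_study

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_protein(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(rng.choice(AA, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def small_db(rng) -> ProteinDatabase:
    db = ProteinDatabase()
    for i in range(20):
        db.add(ProteinRecord(f"P{i:03d}", random_protein(rng, int(rng.integers(40, 120)))))
    return db


@pytest.fixture(scope="session")
def tiny_study():
    """Small clean single-sample study for search smoke tests."""
    spec = CommunitySpec(
        seed=11,
        n_catalog=60,
        n_true=20,
        peptides_per_protein=5,
        n_noise_spectra=0,
        fragment_keep_prob=1.0,
        weak_fraction=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        catalog = make_catalog(spec)
        study = make_study(spec, catalog)
    return spec, catalog, study


@pytest.fixture(scope="session")
def calibration():
    """Ten-seed FDR-calibration / two-step-gain benchmark (reference
    desk-scale conditions: 1000-protein catalog, 100 true proteins,
    ~800 peptide + 400 noise spectra per seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fdr_calibration_summary(20260924, n_seeds=10)


@pytest.fixture(scope="session")
def biology():
    """End-to-end planted-biology benchmark (3:1 Firmicutes shift,
    20 four-fold differential proteins, 4 vs 4 samples)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return biology_recovery_experiment(20260924)
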