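"""Shared fixtures: small hand-built structures and session-scoped synthetic
ensembles (generated programmatically; nothing is read from disk)."""

from __future__ import annotations

import numpy as np
import pytest

from flycast.pipeline import converge_double_well
from flycast.structure_io import Structure
from flycast.synthetic_models import (
    SyntheticEnsembleSpec,
    generate_binding_ensemble,
)


def make_structure(positions, elements=None, names=None, chain="A", model_id=1):
    """Minimal structure builder for geometry tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    elements = elements or ["C"] * n
    names = names or [f"C{i+1}" for i in range(n)]
    return Structure(
        serials=np.arange(1, n + 1),
        names=list(names),
        elements=list(elements),
        res_numbers=np.ones(n, dtype=int),
        res_names=["LIG"] * n,
        chains=[chain] * n,
        positions=positions,
        model_id=model_id,
    )


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from flycast.structure_io import Transform

    quat = rng.standard_normal(4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    return Transform(rotation=rot, translation=rng.normal(0, 5, 3))


@pytest.fixture(scope="session")
def synthetic_20k():
    """Default-condition synthetic binding ensemble, n = 20,000."""
    spec = SyntheticEnsembleSpec(n_snapshots=20_000, seed=11)
    ensemble, truth = generate_binding_ensemble(spec)
    return ensemble.ensure_aligned(), truth


@pytest.fixture(scope="session")
def synthetic_10k():
    """Smaller ensemble for exact oracle-equivalence checks, n = 10,000."""
    spec = SyntheticEnsembleSpec(n_snapshots=10_000, seed=7)
    ensemble, truth = generate_binding_ensemble(spec)
    return ensemble.ensure_aligned(), truth


@pytest.fixture(scope="session")
def double_well_recovery():
    """The full canonical-recovery loop on the 1-D double well (fixed seed)."""
    return converge_double_well(seed=1)
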