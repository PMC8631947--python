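"""Shared fixtures: small synthetic sessions generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from laminabo import synth
from laminabo.border_ownership import BODataset
from laminabo.datamodel import StimulusGeometry


@pytest.fixture(scope="session")
def small_session():
    """A compact BO session: 12 units, 8 trials/condition."""
    params = synth.BOSessionParams(
        n_units={"superficial": 3, "granular": 4, "deep": 5})
    return synth.gen_bo_session(params, seed=101)


@pytest.fixture()
def geometry():
    return StimulusGeometry(
        dataset_id=0, square_side_dva=16.0, edge_orientation_deg=0.0,
        edge_position_dva=(5.0, 5.0), side_a_direction_deg=90.0)


def make_counts_dataset(counts: dict[int, list[float]],
                        geometry: StimulusGeometry | None = None,
                        pretrial: dict[int, list[float]] | None = None) -> BODataset:
    counts_arr = {c: np.asarray(v, dtype=float) for c, v in counts.items()}
    if pretrial is None:
        pretrial = {c: np.zeros_like(v) for c, v in counts_arr.items()}
    else:
        pretrial = {c: np.asarray(v, dtype=float) for c, v in pretrial.items()}
    return BODataset(unit_id="u000", dataset_id=0, edge_orientation_deg=0.0,
                     geometry=geometry, counts=counts_arr,
                     pretrial_counts=pretrial)


@pytest.fixture()
def poisson_null_dataset():
    """Factory: side-symmetric Poisson datasets (no BO modulation)."""

    def make(seed: int, n_trials: int = 8, lam: float = 10.0) -> BODataset:
        rng = np.random.default_rng(seed)
        return make_counts_dataset(
            {c: rng.poisson(lam, n_trials).astype(float) for c in (1, 2, 3, 4)})

    return make
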