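"""Shared fixtures: small phantoms and the full desk-scale training experiment.

The desk experiment (24 simulated cases, 16 train / 8 held out, desk
training profile) is expensive, so it is computed once per session and
shared by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

import srfseg as s
from srfseg.training import desk_network_config, desk_train_config, train_model


@pytest.fixture(scope="session")
def symmetric_case():
    """A mirror-symmetric two-kidney phantom (true LRF% exactly 50)."""
    return s.generate_phantom(s.default_phantom_spec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Six quick 48-cube phantoms spanning variants."""
    mix = {"normal": 0.5, "solitary": 0.2, "hypoplastic": 0.2, "low_asymmetric": 0.1}
    return s.generate_cohort(6, seed=3, variant_mix=mix, shape=(48, 48, 48))


@pytest.fixture(scope="session")
def desk_experiment():
    """The end-to-end desk experiment: simulate 24, train on 16, hold out 8.

    Training uses the desk profile (32-cube patches, 2 levels, 8 base
    channels, 20 epochs x 200 samples, seed 7) on a 24-case cohort
    simulated with seed 7 on the 64-cube grid.
    """
    cohort = s.generate_cohort(24, seed=7, shape=(64, 64, 64))
    train_cases = cohort[:16]
    heldout = cohort[16:]
    result = train_model(
        [(c.ct, c.pet, c.truth) for c in train_cases],
        desk_network_config(),
        desk_train_config(seed=7),
    )
    return {"result": result, "train": train_cases, "heldout": heldout}
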