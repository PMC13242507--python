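"""Shared fixtures: tiny handcrafted datasets and module-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from emoblend.data_model import (
    Dataset,
    ResponseRecord,
    StimulusSpec,
    build_stimuli_index,
)
from emoblend.synthetic_raters import (
    RaterModelParams,
    build_design,
    simulate_study,
)


def make_stimulus(
    sid="s1",
    actor="a1",
    first="anger",
    second="disgust",
    proportion="50:50",
) -> StimulusSpec:
    return StimulusSpec(sid, actor, first, second, proportion)


def make_response(pid, sid, ratings) -> ResponseRecord:
    return ResponseRecord(pid, sid, ratings)


@pytest.fixture
def tiny_forced2() -> Dataset:
    """Two participants x two stimuli, handcrafted forced-two-scale data."""
    stimuli = build_stimuli_index(
        [
            make_stimulus("s1", "a1", "anger", "disgust", "30:70"),
            make_stimulus("s2", "a1", "fear", "sadness", "50:50"),
        ]
    )
    responses = [
        make_response("p1", "s1", {"anger": 3, "disgust": 7}),
        make_response("p1", "s2", {"fear": 5, "sadness": 5}),
        make_response("p2", "s1", {"anger": 6, "fear": 2}),
        make_response("p2", "s2", {"happiness": 1, "sadness": 4}),
    ]
    return Dataset(stimuli=stimuli, responses=responses, mode="forced2")


@pytest.fixture(scope="module")
def sim_forced2_small():
    """Seeded default-parameter forced2 simulation (8 participants, 2 actors)."""
    params = RaterModelParams(seed=42)
    return simulate_study(build_design(2), 8, params, "forced2")


@pytest.fixture(scope="module")
def sim_free_small():
    """Seeded default-parameter free-selection simulation."""
    params = RaterModelParams(seed=43)
    return simulate_study(build_design(2), 8, params, "free")


@pytest.fixture(scope="module")
def sim_noise_free():
    """Deterministic (sigma=0, identity-kernel) forced2 simulation."""
    params = RaterModelParams(sigma=0.0, kernel=np.eye(5), seed=7)
    return simulate_study(build_design(2), 4, params, "forced2")
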