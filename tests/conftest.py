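"""Shared fixtures: the two-member case-study community and the
proof-of-concept tracking scenario (expensive, so session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from chemotrack import (
    ChemostatState,
    CommunityModel,
    OperatingConditions,
    TrackingConfig,
    asre_track,
)
from chemotrack.synth import (
    CASE_STUDY_1_KINETICS,
    make_proof_of_concept,
    sample_observations,
)


@pytest.fixture(scope="session")
def two_member_model() -> CommunityModel:
    """1 AOB + 1 NOB with the case-study kinetics, no interactions."""
    return CommunityModel.build(**CASE_STUDY_1_KINETICS)


@pytest.fixture(scope="session")
def dense_two_member_model(two_member_model) -> CommunityModel:
    """Same community with a generic dense invertible interaction matrix."""
    return two_member_model.with_interactions(np.array([[-0.3, 0.2], [-1.5, -0.4]]))


@pytest.fixture(scope="session")
def poc_scenario():
    """The 300-day regime-change scenario (CN -> PN at day 150)."""
    return make_proof_of_concept(seed=1)


@pytest.fixture(scope="session")
def poc_data(poc_scenario):
    """Dense trajectory plus the sampled (noise-free) reference signal."""
    traj = poc_scenario.simulate(dt=0.5)
    signal, substrates = sample_observations(traj, poc_scenario)
    return traj, signal, substrates


@pytest.fixture(scope="session")
def poc_tracking(poc_scenario, poc_data):
    """ASRE tracking of the proof-of-concept data with default weights."""
    _, signal, _ = poc_data
    return asre_track(
        poc_scenario.model, poc_scenario.operating, signal, TrackingConfig()
    )


@pytest.fixture()
def small_state(two_member_model) -> ChemostatState:
    return ChemostatState(x=np.array([0.05, 0.01]), s=np.array([1.25, 0.0, 0.0]))


@pytest.fixture()
def constant_operating() -> OperatingConditions:
    return OperatingConditions.constant(0.24, 1.25, horizon=400.0)
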