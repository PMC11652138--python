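"""Shared fixtures: synthetic scenes are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from axocalc import (
    CalibrationParams,
    StimulationProtocol,
    correlation_map,
    define_compartment_rois,
    segment_by_correlation,
    subtract_background,
)
from axocalc.synthgen import (
    DynamicsParams,
    GeometryParams,
    contaminated_scene,
    fura_scene,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib() -> CalibrationParams:
    return CalibrationParams()


@pytest.fixture(scope="session")
def protocol_100hz() -> StimulationProtocol:
    return StimulationProtocol(frequency=100.0, duration=2.0, onset=10.0)


@pytest.fixture(scope="session")
def noiseless_scene(protocol_100hz):
    """Noiseless 100 Hz 2 s recording: exact round-trips."""
    return fura_scene(protocol_100hz, seed=1, noiseless=True)


@pytest.fixture(scope="session")
def noisy_scene(protocol_100hz):
    """Default-noise 100 Hz 2 s recording."""
    return fura_scene(protocol_100hz, seed=2)


@pytest.fixture(scope="session")
def hard_scene():
    """Debris + bright non-responsive fiber + dim responsive axon."""
    return contaminated_scene(seed=3)


@pytest.fixture(scope="session")
def repeat_scene():
    """Large dendritic tree, three identical 20 Hz 2 s stimulations, static
    per-pixel dendritic amplitude pattern independent of position."""
    protocols = [
        StimulationProtocol(frequency=20.0, duration=2.0, onset=o)
        for o in (15.0, 45.0, 75.0)
    ]
    geometry = GeometryParams(
        shape=(192, 192), n_dendrites=8, dendrite_length=(55.0, 85.0),
        dendrite_radius=1.5,
    )
    dynamics = DynamicsParams(branch_amp_spread=0.0, pixel_amp_cv=0.3)
    return fura_scene(protocols, geometry=geometry, dynamics=dynamics, seed=4)


def analyze_scene(scene, threshold: float = -0.3):
    """Segment a scene and build compartment ROIs (helper, not a fixture)."""
    corrected = subtract_background(scene.stack, scene.blank)
    corr = correlation_map(corrected)
    mask = segment_by_correlation(corr, threshold=threshold)
    rois = define_compartment_rois(
        mask, scene.phantom.labels, scene.phantom.names
    )
    return corrected, corr, mask, rois


@pytest.fixture(scope="session")
def noisy_analysis(noisy_scene):
    return analyze_scene(noisy_scene)


@pytest.fixture(scope="session")
def repeat_analysis(repeat_scene):
    return analyze_scene(repeat_scene)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum() / (a | b).sum())
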