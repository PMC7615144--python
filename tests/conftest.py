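"""Shared fixtures: the default phantom, desk-scale acquisition, and
cached reconstructions reused across reconstruction/quality tests."""

import numpy as np
import pytest

from mocosim.motion import MotionTrace
from mocosim.phantom import build_default_phantom
from mocosim.recon import AcquisitionSpec, reconstruct_fft, simulate_acquisition
from mocosim.scenarios import ScenarioSpec, generate_scenario_trace

MATRIX = 64
FOV = 200.0


@pytest.fixture(scope="session")
def phantom():
    return build_default_phantom(MATRIX, FOV)


@pytest.fixture(scope="session")
def rigid_phantom():
    """Same geometry but with a rigidly coupled neck (no confound)."""
    return build_default_phantom(MATRIX, FOV, neck_coupling=1.0)


@pytest.fixture(scope="session")
def acq_spec():
    return AcquisitionSpec(matrix=MATRIX, fov_mm=FOV)


@pytest.fixture(scope="session")
def still_trace(acq_spec):
    return MotionTrace(
        times=np.array([0.0, acq_spec.scan_duration_s]), poses=np.zeros((2, 6))
    )


@pytest.fixture(scope="session")
def still_kspace(phantom, still_trace, acq_spec):
    return simulate_acquisition(phantom, still_trace, acq_spec)


@pytest.fixture(scope="session")
def still_recon(still_kspace):
    return reconstruct_fft(still_kspace)


def still_reference_at(phantom, acq_spec, pose_params):
    """FFT reconstruction of a motion-free acquisition at a fixed pose."""
    trace = MotionTrace(
        times=np.array([0.0, acq_spec.scan_duration_s]),
        poses=np.tile(np.asarray(pose_params, float), (2, 1)),
    )
    return reconstruct_fft(simulate_acquisition(phantom, trace, acq_spec))


@pytest.fixture(scope="session")
def stepwise_small_trace(acq_spec):
    sc = ScenarioSpec.named("stepwise-small", scan_duration_s=acq_spec.scan_duration_s)
    return generate_scenario_trace(sc, 30.0)


@pytest.fixture(scope="session")
def stepwise_small_kspace(phantom, stepwise_small_trace, acq_spec):
    return simulate_acquisition(phantom, stepwise_small_trace, acq_spec)
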