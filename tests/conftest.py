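import numpy as np
import pytest
from hypothesis import settings

from ensuq import Ensemble, EnergyTrajectory, SyntheticSpec, generate_ensemble

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def tiny_ensemble() -> Ensemble:
    """Two replicas x 3 frames with hand-checkable values."""
    return Ensemble(
        replicas=(
            EnergyTrajectory("r1", np.array([1.0, 2.0, 3.0]), np.array([-9.0, -9.0, -9.0])),
            EnergyTrajectory("r2", np.array([1.0, 2.0, 3.0]), np.array([-11.0, -11.0, -11.0])),
        ),
        label="tiny",
    )


@pytest.fixture
def gaussian_ensemble() -> Ensemble:
    """50 iid-gaussian replicas x 20 frames (1 ns spacing), ΔG ~ N(-10, 1)."""
    spec = SyntheticSpec(
        family="gaussian", location=-10.0, scale=1.0,
        n_replicas=50, frames_per_replica=20, frame_interval_ns=1.0, seed=42,
    )
    return generate_ensemble(spec)


@pytest.fixture
def scalar_gaussian_ensemble() -> Ensemble:
    """100 single-frame replicas: per-replica ΔG exactly N(-10, 1)."""
    spec = SyntheticSpec(
        family="gaussian", location=-10.0, scale=1.0,
        n_replicas=100, frames_per_replica=1, seed=7,
    )
    return generate_ensemble(spec)
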