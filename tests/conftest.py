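from __future__ import annotations

import numpy as np
import pytest

import actinmachine as am


@pytest.fixture
def line_matrix() -> am.ConductiveMatrix:
    """1-voxel-wide axis-aligned line of 31 voxels along x."""
    return am.synth_network(
        am.SynthSpec(kind="line", extent=(31, 3, 3), length=31, start=(0, 1, 1))
    )


@pytest.fixture
def ring_matrix() -> am.ConductiveMatrix:
    """Closed 1-voxel-wide diamond loop in one z-slice."""
    return am.synth_network(
        am.SynthSpec(kind="ring", extent=(21, 21, 3), ring_radius=5, start=(10, 10, 1))
    )


@pytest.fixture(scope="session")
def delaunay_matrix() -> am.ConductiveMatrix:
    """Small synthetic Delaunay bundle network."""
    return am.synth_network(
        am.SynthSpec(kind="delaunay", extent=(40, 40, 8), n_points=16, tube_radius=1.5, seed=11)
    )


def triangular_pulse(length: int, peak_t: int, height: int = 5) -> np.ndarray:
    """Integer series rising to ``height`` at 1-based time ``peak_t`` then falling."""
    v = np.zeros(length, dtype=int)
    for d in range(height):
        lo, hi = peak_t - 1 - (height - 1 - d), peak_t - 1 + (height - 1 - d)
        for idx in (lo, hi):
            if 0 <= idx < length:
                v[idx] = max(v[idx], d + 1)
    return v


@pytest.fixture
def pulse():
    return triangular_pulse
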