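"""Three-state excitable automaton on a conductive voxel matrix.

Each conductive voxel is resting, excited, or refractory, with a counter
``h`` timing the refractory decay.  All voxels update synchronously:

- a resting voxel becomes excited when its count of excited neighbours
  within Euclidean radius ``r`` is *strictly* greater than the threshold
  ``theta``;
- an excited voxel becomes refractory, with ``h`` set to the refractory
  delay ``delta``;
- a refractory voxel with ``h > 0`` stays refractory and decrements ``h``;
  with ``h = 0`` it returns to resting (so a voxel excited at step t is
  refractory for exactly ``delta + 1`` steps, t+1 .. t+delta+1).

Non-conductive voxels and positions outside the grid carry no state, can
never be excited, and contribute 0 to every neighbour count (the droplet
network is bounded; there is no wraparound).  Distances are in voxel index
units.  The dynamics are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy import ndimage

from .matrix import ConductiveMatrix

__all__ = [
    "RESTING",
    "EXCITED",
    "REFRACTORY",
    "AutomatonParams",
    "LatticeState",
    "neighbourhood_offsets",
    "neighbourhood_kernel",
    "step",
    "run",
]

RESTING: int = 0
EXCITED: int = 1
REFRACTORY: int = 2


@dataclass(frozen=True)
class AutomatonParams:
    """Excitability parameters: threshold theta, refractory delay delta, radius r.

    Defaults (theta=7, delta=20, r=3) are the values at which the bundle
    network realizes the most Boolean gates and are used to build the
    droplet machine.
    """

    theta: int = 7
    delta: int = 20
    radius: int = 3

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("neighbourhood radius must be >= 1")
        if self.theta < 0 or self.delta < 0:
            raise ValueError("theta and delta must be non-negative")


@lru_cache(maxsize=None)
def neighbourhood_offsets(radius: int) -> np.ndarray:
    """All integer offsets (dx, dy, dz) != 0 with dx²+dy²+dz² <= radius².

    Symmetric under negation; excludes the centre.  Sizes: 6 for r=1,
    32 for r=2, 122 for r=3.
    """
    radius = int(radius)
    if radius < 1:
        raise ValueError("neighbourhood radius must be >= 1")
    rng = np.arange(-radius, radius + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    norm2 = dx**2 + dy**2 + dz**2
    keep = (norm2 <= radius**2) & (norm2 > 0)
    out = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=None)
def neighbourhood_kernel(radius: int) -> np.ndarray:
    """Binary convolution kernel of the radius-r Euclidean ball, centre zeroed."""
    radius = int(radius)
    offs = neighbourhood_offsets(radius)
    k = np.zeros((2 * radius + 1,) * 3, dtype=np.int32)
    k[offs[:, 0] + radius, offs[:, 1] + radius, offs[:, 2] + radius] = 1
    k.setflags(write=False)
    return k


@dataclass
class LatticeState:
    """Per-voxel automaton state and refractory counters at one time step."""

    state: np.ndarray  # uint8: RESTING / EXCITED / REFRACTORY
    h: np.ndarray  # int32 refractory counters
    t: int = 0

    @classmethod
    def resting(cls, matrix: ConductiveMatrix) -> "LatticeState":
        return cls(
            state=np.zeros(matrix.shape, dtype=np.uint8),
            h=np.zeros(matrix.shape, dtype=np.int32),
            t=0,
        )

    @property
    def excited_mask(self) -> np.ndarray:
        return self.state == EXCITED

    def excited_count(self) -> int:
        return int(self.excited_mask.sum())

    def copy(self) -> "LatticeState":
        return LatticeState(self.state.copy(), self.h.copy(), self.t)


def excited_neighbour_counts(state: np.ndarray, radius: int) -> np.ndarray:
    """sigma(p): per-voxel count of excited neighbours within the radius ball."""
    return ndimage.convolve(
        (state == EXCITED).astype(np.int32),
        neighbourhood_kernel(radius),
        mode="constant",
        cval=0,
    )


def step(
    lattice: LatticeState, matrix: ConductiveMatrix, params: AutomatonParams
) -> LatticeState:
    """One synchronous update of all conductive voxels."""
    if lattice.state.shape != matrix.shape:
        raise ValueError(
            f"lattice shape {lattice.state.shape} != matrix shape {matrix.shape}"
        )
    was_excited = lattice.state == EXCITED
    sigma = excited_neighbour_counts(lattice.state, params.radius)

    excites = (lattice.state == RESTING) & matrix.grid & (sigma > params.theta)
    stays_refractory = (lattice.state == REFRACTORY) & (lattice.h > 0)
    refractory = was_excited | stays_refractory

    state = np.zeros_like(lattice.state)
    state[refractory] = REFRACTORY
    state[excites] = EXCITED

    h = np.zeros_like(lattice.h)
    h[stays_refractory] = lattice.h[stays_refractory] - 1
    h[was_excited] = params.delta

    return LatticeState(state=state, h=h, t=lattice.t + 1)


def run(
    lattice: LatticeState,
    matrix: ConductiveMatrix,
    params: AutomatonParams,
    steps: int,
    observer: Callable[[LatticeState], None] | None = None,
) -> LatticeState:
    """Apply :func:`step` ``steps`` times, invoking ``observer`` after each."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    for _ in range(steps):
        lattice = step(lattice, matrix, params)
        if observer is not None:
            observer(lattice)
    return lattice
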