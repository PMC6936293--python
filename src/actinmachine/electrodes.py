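"""Electrode interface: impulse stimulation and potential recording.

An electrode is a spherical voxel domain of radius ``r_e`` (default 4)
around an integer centre.  Stimulation sets every *conductive, resting*
voxel strictly closer than ``r_e`` to the centre to the excited state
(refractory voxels are never overridden); recording counts the excited
voxels strictly closer than ``r_e``.  Both use the same strict d < r_e
criterion, so for r_e = 4 the sphere comprises the 251 integer offsets
with squared norm <= 15 (centre included).

A binary input string of length k addresses bit i to electrode i; bit
values are decimal-encoded with electrode 0 as the most significant bit.

Two laboratory electrode layouts on the 1024x1024x30 confocal network are
shipped as CSV fixtures: ``E1`` (10 electrodes; the first and last are the
inputs of the two-input gate experiments) and ``E2`` (all electrodes both
stimulate and record; the digit table it was transcribed from yields
8 rows although the experiments used six — the experiment configuration
chooses which labels form the k-electrode set).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .automaton import EXCITED, RESTING, AutomatonParams, LatticeState, step
from .matrix import ConductiveMatrix

__all__ = [
    "Electrode",
    "StimulusPattern",
    "PotentialTrace",
    "sphere_offsets",
    "electrode_voxels",
    "stimulate",
    "record_potential",
    "run_experiment",
    "read_electrodes",
    "write_electrodes",
    "builtin_electrodes",
]

DEFAULT_ELECTRODE_RADIUS = 4.0


@dataclass(frozen=True)
class Electrode:
    """A spherical stimulation/recording domain centred on an integer voxel."""

    label: str
    i: int
    j: int
    z: int
    radius: float = DEFAULT_ELECTRODE_RADIUS

    @property
    def centre(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.z)


@dataclass(frozen=True)
class StimulusPattern:
    """A binary input string of length k; bit i drives electrode i."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")

    @classmethod
    def from_decimal(cls, decimal: int, k: int) -> "StimulusPattern":
        if not 0 <= decimal < 2**k:
            raise ValueError(f"decimal {decimal} out of range for k={k}")
        return cls(tuple((decimal >> (k - 1 - i)) & 1 for i in range(k)))

    @property
    def k(self) -> int:
        return len(self.bits)

    @property
    def decimal(self) -> int:
        """Integer encoding with electrode 0 as the most significant bit."""
        return sum(b << (self.k - 1 - i) for i, b in enumerate(self.bits))


@lru_cache(maxsize=None)
def sphere_offsets(radius: float = DEFAULT_ELECTRODE_RADIUS) -> np.ndarray:
    """Integer offsets strictly closer than ``radius`` to the origin (incl. it)."""
    r = float(radius)
    if r <= 0:
        raise ValueError("electrode radius must be positive")
    n = int(np.ceil(r))
    rng = np.arange(-n, n + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 < r * r
    out = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    out.setflags(write=False)
    return out


def electrode_voxels(
    matrix: ConductiveMatrix, electrode: Electrode, conductive_only: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays of the in-grid voxels strictly inside the electrode sphere."""
    shape = matrix.shape
    centre = np.array(electrode.centre)
    if np.any(centre < 0) or np.any(centre >= np.array(shape)):
        raise ValueError(
            f"electrode {electrode.label!r} centre {electrode.centre} "
            f"outside grid of shape {shape}"
        )
    pts = centre + sphere_offsets(electrode.radius)
    inside = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
    pts = pts[inside]
    idx = (pts[:, 0], pts[:, 1], pts[:, 2])
    if conductive_only:
        cond = matrix.grid[idx]
        idx = (idx[0][cond], idx[1][cond], idx[2][cond])
    return idx


def stimulate(
    lattice: LatticeState,
    matrix: ConductiveMatrix,
    electrodes: Sequence[Electrode],
    pattern: StimulusPattern,
) -> LatticeState:
    """Apply one impulse: excite the conductive resting voxels of each 1-bit electrode.

    Returns a new lattice; refractory voxels keep their state and counter.
    """
    if len(electrodes) != pattern.k:
        raise ValueError(
            f"pattern length {pattern.k} != number of electrodes {len(electrodes)}"
        )
    out = lattice.copy()
    for bit, electrode in zip(pattern.bits, electrodes):
        if not bit:
            continue
        idx = electrode_voxels(matrix, electrode)
        sel = out.state[idx] == RESTING
        out.state[idx[0][sel], idx[1][sel], idx[2][sel]] = EXCITED
    return out


def record_potential(lattice: LatticeState, electrode: Electrode) -> int:
    """Potential p_c: number of excited voxels strictly closer than r_e to the centre."""
    shape = lattice.state.shape
    centre = np.array(electrode.centre)
    pts = centre + sphere_offsets(electrode.radius)
    inside = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
    pts = pts[inside]
    return int((lattice.state[pts[:, 0], pts[:, 1], pts[:, 2]] == EXCITED).sum())


@dataclass
class PotentialTrace:
    """Per-electrode excited-voxel counts for time steps t = 1..T."""

    values: np.ndarray  # shape (T, k), integer counts
    labels: tuple[str, ...]

    @property
    def T(self) -> int:
        return self.values.shape[0]

    def column(self, electrode: int | str) -> np.ndarray:
        if isinstance(electrode, str):
            electrode = self.labels.index(electrode)
        return self.values[:, electrode]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "t", np.arange(1, self.T + 1))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PotentialTrace":
        df = pd.read_csv(path)
        labels = tuple(c for c in df.columns if c != "t")
        return cls(df[list(labels)].to_numpy(dtype=np.int64), labels)


def run_experiment(
    matrix: ConductiveMatrix,
    electrodes: Sequence[Electrode],
    pattern: StimulusPattern,
    params: AutomatonParams,
    steps: int,
    stim_steps: int = 1,
) -> PotentialTrace:
    """One virtual experiment: stimulate at t=0, run T steps, record every electrode.

    The impulse is a single-step excitation at t=0 by default; ``stim_steps``
    re-applies it at the start of that many consecutive steps for sensitivity
    studies.  Fully deterministic.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    lattice = LatticeState.resting(matrix)
    lattice = stimulate(lattice, matrix, electrodes, pattern)
    record_idx = [
        electrode_voxels(matrix, e, conductive_only=False) for e in electrodes
    ]
    values = np.zeros((steps, len(electrodes)), dtype=np.int64)
    for t in range(1, steps + 1):
        lattice = step(lattice, matrix, params)
        if t < stim_steps:
            lattice = stimulate(lattice, matrix, electrodes, pattern)
        for c, idx in enumerate(record_idx):
            values[t - 1, c] = int((lattice.state[idx] == EXCITED).sum())
    return PotentialTrace(values, tuple(e.label for e in electrodes))


# ---------------------------------------------------------------------------
# Electrode table I/O
# ---------------------------------------------------------------------------

def read_electrodes(path: str | Path) -> list[Electrode]:
    """Read a CSV electrode table with columns label,i,j,z[,radius]; '#' comments."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "i", "j", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"electrode table must have columns {sorted(required)}")
    radius = df["radius"] if "radius" in df.columns else DEFAULT_ELECTRODE_RADIUS
    out = []
    for n, row in df.iterrows():
        r = float(row["radius"]) if "radius" in df.columns else DEFAULT_ELECTRODE_RADIUS
        out.append(
            Electrode(str(row["label"]), int(row["i"]), int(row["j"]), int(row["z"]), r)
        )
    return out


def write_electrodes(electrodes: Iterable[Electrode], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"label": e.label, "i": e.i, "j": e.j, "z": e.z, "radius": e.radius}
            for e in electrodes
        ]
    ).to_csv(path, index=False)


def builtin_electrodes(name: str) -> list[Electrode]:
    """Load a shipped laboratory electrode layout: ``"E1"`` or ``"E2"``."""
    name = name.upper()
    if name not in {"E1", "E2"}:
        raise ValueError("builtin electrode tables are 'E1' and 'E2'")
    ref = resources.files("actinmachine.data") / f"electrodes_{name}.csv"
    with resources.as_file(ref) as p:
        return read_electrodes(p)
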