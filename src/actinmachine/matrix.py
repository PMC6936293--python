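"""Conductive voxel matrices: thresholding confocal stacks and synthesizing networks.

The simulation substrate is a boolean 3D grid ``C`` marking which voxels
contain actin-bundle material.  It can be derived from an RGB confocal
slice stack by a per-channel threshold, generated synthetically (Delaunay
tube networks emulating regularly spaced bundle networks in a droplet,
plus degenerate line/ring fixtures for closed-form tests), optionally
compressed along z, and serialized as a slice-per-page TIFF with a JSON
sidecar so it stays inspectable with standard viewers.

Grids are indexed ``grid[i, j, z]`` with shape ``(n_x, n_y, n_z)``.  All
geometry is in voxel index units; the physical anisotropic voxel size
(0.22 x 0.22 x 4 um for the laboratory networks) is carried as metadata
only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import numpy as np

__all__ = [
    "DEFAULT_VOXEL_SIZE",
    "ImageStack",
    "ConductiveMatrix",
    "SynthSpec",
    "threshold_stack",
    "compress_z",
    "synth_network",
    "load_stack",
    "save_matrix",
    "load_matrix",
]

#: Physical voxel size of the laboratory confocal stacks, in micrometres.
DEFAULT_VOXEL_SIZE = (0.22, 0.22, 4.0)

#: RGB channel thresholds (strict >) marking a voxel as bundle material.
DEFAULT_RGB_MIN = (40, 19, 19)


@dataclass(frozen=True)
class ImageStack:
    """An RGB confocal slice stack.

    ``data`` has shape ``(n_x, n_y, n_z, 3)`` with integer channels in
    [0, 255]; ``voxel_size`` is ``(dx, dy, dz)`` in micrometres (metadata).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim != 4 or a.shape[3] != 3:
            raise ValueError(f"stack must have shape (nx, ny, nz, 3), got {a.shape}")
        if a.min() < 0 or a.max() > 255:
            raise ValueError("RGB channels must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ConductiveMatrix:
    """Boolean voxel grid marking conductive (actin-bundle) material."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = "synthetic"  # thresholded | synthetic | loaded
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_conductive(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class SynthSpec:
    """Parameters for a synthetic conductive network.

    ``kind`` selects the geometry:

    - ``"delaunay"``: sample ``n_points`` uniformly in ``extent``, take the
      edges of the 3D Delaunay triangulation and rasterize each edge as a
      digital tube of ``tube_radius`` voxels (squared-Euclidean
      point-to-segment distance <= tube_radius**2).  Emulates the regularly
      spaced bundle networks self-assembled in droplets.
    - ``"line"``: a 1-voxel-wide axis-aligned segment of ``length`` voxels.
    - ``"ring"``: a closed 1-voxel-wide diamond loop (|di|+|dj| = ring_radius)
      in a single z-slice; every voxel has exactly two conductive
      26-neighbours, which makes wavefront behaviour exactly predictable.
    """

    kind: str
    extent: tuple[int, int, int]
    n_points: int = 24
    tube_radius: float = 2.0
    seed: int = 0
    axis: int = 0
    length: int = 0
    ring_radius: int = 0
    start: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"delaunay", "line", "ring"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if any(int(e) < 1 for e in self.extent):
            raise ValueError("extent components must be >= 1")
        if self.tube_radius < 0:
            raise ValueError("tube_radius must be >= 0")


def threshold_stack(
    stack: ImageStack | np.ndarray,
    rgb_min: tuple[int, int, int] = DEFAULT_RGB_MIN,
) -> ConductiveMatrix:
    """Convert an RGB stack to a conductive matrix by per-channel threshold.

    A voxel is conductive iff red > rgb_min[0] AND green > rgb_min[1] AND
    blue > rgb_min[2], all inequalities strict.  The defaults (40, 19, 19)
    are the ones used to segment actin bundles from confocal fluorescence.
    """
    if not isinstance(stack, ImageStack):
        stack = ImageStack(np.asarray(stack))
    data = np.asarray(stack.data)
    r, g, b = data[..., 0], data[..., 1], data[..., 2]
    grid = (r > rgb_min[0]) & (g > rgb_min[1]) & (b > rgb_min[2])
    return ConductiveMatrix(grid, voxel_size=stack.voxel_size, provenance="thresholded")


def compress_z(
    matrix: ConductiveMatrix, factor: int, reducer: str = "or"
) -> ConductiveMatrix:
    """Compress the matrix along z by an integer factor.

    Each output slice is the reducer (OR, equivalently MAX on booleans) over
    its bin of ``factor`` consecutive input slices; output depth is
    ``ceil(n_z / factor)``.  ``factor=1`` is the identity.  The z voxel size
    in the metadata is scaled by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("compression factor must be >= 1")
    if reducer.lower() not in {"or", "max"}:
        raise ValueError(f"unknown reducer {reducer!r}")
    if factor == 1:
        return replace(matrix, grid=matrix.grid.copy(), meta=dict(matrix.meta))
    nx_, ny_, nz_ = matrix.shape
    out_nz = math.ceil(nz_ / factor)
    padded = np.zeros((nx_, ny_, out_nz * factor), dtype=bool)
    padded[:, :, :nz_] = matrix.grid
    grid = padded.reshape(nx_, ny_, out_nz, factor).any(axis=3)
    dx, dy, dz = matrix.voxel_size
    return ConductiveMatrix(
        grid,
        voxel_size=(dx, dy, dz * factor),
        provenance=matrix.provenance,
        meta=dict(matrix.meta, z_compression=factor),
    )


def _segment_voxels(
    p0: np.ndarray, p1: np.ndarray, radius: float, extent: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer voxels within ``radius`` (squared-Euclidean) of segment p0-p1."""
    r = float(radius)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - r).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + r).astype(int), np.array(extent) - 1)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3).astype(float)
    d = p1 - p0
    l2 = float(d @ d)
    if l2 == 0.0:
        dist2 = ((pts - p0) ** 2).sum(axis=1)
    else:
        t = np.clip((pts - p0) @ d / l2, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=1)
    keep = dist2 <= r * r + 1e-9
    pts = pts[keep].astype(int)
    return pts[:, 0], pts[:, 1], pts[:, 2]


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int)


def synth_network(spec: SynthSpec) -> ConductiveMatrix:
    """Generate a synthetic conductive matrix; deterministic for a fixed seed."""
    extent = tuple(int(e) for e in spec.extent)
    grid = np.zeros(extent, dtype=bool)
    meta: dict[str, Any] = {"synth": spec.kind, "seed": spec.seed}

    if spec.kind == "line":
        if spec.length < 1:
            raise ValueError("line requires length >= 1")
        if spec.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        start = spec.start or tuple(
            0 if a == spec.axis else extent[a] // 2 for a in range(3)
        )
        end = list(start)
        end[spec.axis] += spec.length - 1
        if any(c < 0 or c >= extent[a] for a, c in enumerate(start)) or end[
            spec.axis
        ] >= extent[spec.axis]:
            raise ValueError("line does not fit in extent")
        idx = [np.full(spec.length, start[a]) for a in range(3)]
        idx[spec.axis] = start[spec.axis] + np.arange(spec.length)
        grid[tuple(idx)] = True

    elif spec.kind == "ring":
        R = int(spec.ring_radius)
        if R < 2:
            raise ValueError("ring requires ring_radius >= 2")
        cx, cy, cz = spec.start or (extent[0] // 2, extent[1] // 2, extent[2] // 2)
        if cx - R < 0 or cx + R >= extent[0] or cy - R < 0 or cy + R >= extent[1]:
            raise ValueError("ring does not fit in extent")
        for di in range(-R, R + 1):
            dj = R - abs(di)
            grid[cx + di, cy + dj, cz] = True
            grid[cx + di, cy - dj, cz] = True

    else:  # delaunay
        if spec.n_points < 5:
            raise ValueError("delaunay requires n_points >= 5")
        rng = np.random.default_rng(spec.seed)
        margin = max(spec.tube_radius, 1.0)
        lo = np.full(3, margin)
        hi = np.array(extent, dtype=float) - 1.0 - margin
        if np.any(hi <= lo):
            raise ValueError("extent too small for the requested tube_radius")
        points = rng.uniform(lo, hi, size=(spec.n_points, 3))
        edges = _delaunay_edges(points)
        for a, b in edges:
            grid[_segment_voxels(points[a], points[b], spec.tube_radius, extent)] = True
        meta["points"] = points
        meta["edges"] = edges

    return ConductiveMatrix(grid, provenance="synthetic", meta=meta)


# ---------------------------------------------------------------------------
# I/O: TIFF / PNG-directory readers, TIFF + JSON-sidecar matrix container
# ---------------------------------------------------------------------------

def _pages_to_grid(pages: np.ndarray) -> np.ndarray:
    """(n_z, n_y, n_x[, ch]) page array -> (n_x, n_y, n_z[, ch]) grid order."""
    if pages.ndim == 3:
        return pages.transpose(2, 1, 0)
    return pages.transpose(2, 1, 0, 3)


def load_stack(
    path: str | Path, voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
) -> ImageStack:
    """Read an RGB stack from a multi-page TIFF or a directory of slice images.

    Slices in a directory are ordered by filename.  Pages are interpreted as
    (row=j, column=i); the stack is stored grid-ordered ``(i, j, z, 3)``.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in
                       {".png", ".tif", ".tiff", ".jpg", ".jpeg"})
        if not files:
            raise ValueError(f"no slice images found in {path}")
        pages = np.stack([iio.imread(f) for f in files])
    else:
        import tifffile

        pages = tifffile.imread(path)
        if pages.ndim == 3 and pages.shape[-1] == 3:  # single RGB page
            pages = pages[None]
    if pages.ndim != 4 or pages.shape[-1] < 3:
        raise ValueError(f"expected RGB slices, got page array of shape {pages.shape}")
    return ImageStack(_pages_to_grid(pages[..., :3]), voxel_size=voxel_size)


def save_matrix(matrix: ConductiveMatrix, path: str | Path) -> Path:
    """Write the matrix as a 0/255 slice-per-page TIFF plus a JSON sidecar.

    Returns the sidecar path.  The sidecar records shape, voxel size and
    provenance so the container round-trips without loss.
    """
    import tifffile

    path = Path(path)
    pages = (matrix.grid.astype(np.uint8) * 255).transpose(2, 1, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(matrix.shape),
                "voxel_size": list(matrix.voxel_size),
                "provenance": matrix.provenance,
            },
            indent=2,
        )
    )
    return sidecar


def load_matrix(path: str | Path) -> ConductiveMatrix:
    """Read a matrix written by :func:`save_matrix` (sidecar optional)."""
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    grid = _pages_to_grid(pages) > 0
    voxel_size = (1.0, 1.0, 1.0)
    provenance = "loaded"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        voxel_size = tuple(info.get("voxel_size", voxel_size))
        if tuple(info.get("shape", grid.shape)) != grid.shape:
            raise ValueError("sidecar shape does not match TIFF contents")
    return ConductiveMatrix(grid, voxel_size=voxel_size, provenance=provenance)
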