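"""Grid-based water-density analysis of aligned trajectories.

Frames are rigidly superposed on a reference via a protein selection (7TM
backbone in the receptor use case), water-oxygen positions are binned on a
regular voxel grid with half-open voxels ``[lower, upper)`` per axis, and the
frame-summed counts are converted to a number density (Å⁻³).  Cross-sections
and a connected-component "water pathway" detector support the usual
questions about hydration of the transmembrane interior: is there a
continuous high-density water column spanning the membrane-normal (z) range?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geom import apply_rigid, superpose
from .errors import ParameterError, SelectionError
from .io_core import AtomSelection, Trajectory

__all__ = [
    "DensityGrid",
    "water_density_grid",
    "cross_section",
    "detect_pathway",
    "write_dx",
]


@dataclass
class DensityGrid:
    """Frame-summed voxel counts over a regular grid.

    ``density = counts / (n_frames × voxel volume)`` in Å⁻³.  Water positions
    falling outside the grid are tallied in ``out_of_grid`` so that
    ``counts.sum() + out_of_grid`` equals the total number of binned
    positions, exactly.
    """

    origin: np.ndarray
    voxel_size: float
    dims: tuple[int, int, int]
    counts: np.ndarray
    n_frames: int
    out_of_grid: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != tuple(self.dims):
            raise ParameterError("counts shape does not match dims")
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size ** 3)

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.n_frames * self.voxel_volume)


def water_density_grid(
    traj: Trajectory,
    water_sel: AtomSelection,
    align_sel: AtomSelection | None,
    origin,
    dims,
    voxel_size: float,
    reference_coords: np.ndarray | None = None,
    frame_range: tuple[int, int] | None = None,
) -> DensityGrid:
    """Accumulate water positions into a voxel grid over (a window of) frames.

    If ``align_sel`` is given, each frame is Kabsch-superposed onto the
    reference (first frame by default) using those atoms, and the transform is
    applied to the whole frame including the waters.  ``frame_range`` selects
    a half-open frame window, mirroring the common practice of analysing only
    the equilibrated tail of a trajectory.
    """
    if water_sel.empty:
        raise SelectionError("water selection is empty")
    origin = np.asarray(origin, dtype=float)
    dims = tuple(int(d) for d in dims)
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    if not (0 <= lo < hi <= traj.n_frames):
        raise ParameterError(f"frame range ({lo}, {hi}) invalid for {traj.n_frames} frames")
    if reference_coords is None:
        reference_coords = traj.coords[lo]
    counts = np.zeros(dims)
    out = 0.0
    wi = water_sel.indices
    for f in range(lo, hi):
        frame = traj.coords[f]
        if align_sel is not None and not align_sel.empty:
            R, t = superpose(frame[align_sel.indices], reference_coords[align_sel.indices])
            waters = apply_rigid(frame[wi], R, t)
        else:
            waters = frame[wi]
        idx = np.floor((waters - origin) / voxel_size).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        np.add.at(counts, tuple(idx[ok].T), 1.0)
        out += float((~ok).sum())
    return DensityGrid(origin, voxel_size, dims, counts, n_frames=hi - lo,
                       out_of_grid=out)


def cross_section(grid: DensityGrid, axis: str, slab: tuple[int, int]) -> np.ndarray:
    """Mean density over a slab of layers along ``axis`` (x, y or z).

    ``slab`` is an inclusive index range; the result keeps the remaining two
    dimensions in their original order.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ParameterError(f"axis must be x, y or z; got {axis!r}")
    lo, hi = slab
    if not (0 <= lo <= hi < grid.dims[ax]):
        raise ParameterError(f"slab ({lo}, {hi}) outside grid dimension {grid.dims[ax]}")
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, hi + 1)
    return grid.density[tuple(sl)].mean(axis=ax)


def detect_pathway(
    grid: DensityGrid,
    threshold: float,
    z_range: tuple[int, int] | None = None,
) -> tuple[bool, np.ndarray]:
    """Test for a continuous water column spanning a z-layer range.

    Voxels with density ≥ threshold are segmented into 26-connected
    components within ``z_range`` (inclusive layer indices; full grid by
    default).  Returns ``(spans, mask)`` where ``spans`` is True iff a single
    component reaches both the first and last layer of the range, and
    ``mask`` marks that component on the full grid (empty if none).
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    nz = grid.dims[2]
    z0, z1 = (0, nz - 1) if z_range is None else z_range
    if not (0 <= z0 <= z1 < nz):
        raise ParameterError(f"z range ({z0}, {z1}) outside grid with {nz} layers")
    dense = grid.density[:, :, z0:z1 + 1] >= threshold
    labels, n = ndimage.label(dense, structure=np.ones((3, 3, 3), dtype=int))
    full = np.zeros(grid.dims, dtype=bool)
    for k in range(1, n + 1):
        comp = labels == k
        if comp[:, :, 0].any() and comp[:, :, -1].any():
            full[:, :, z0:z1 + 1] = comp
            return True, full
    return False, full


def write_dx(grid: DensityGrid, path) -> None:
    """Serialize the density as an OpenDX scalar field (gridcount/VMD style)."""
    nx, ny, nz = grid.dims
    d = grid.density
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.voxel_size:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.voxel_size:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.voxel_size:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = d.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
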