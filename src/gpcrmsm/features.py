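"""Per-frame geometric observables and discrete state assignment.

The observables follow the conventions used for class B GPCR
extracellular-domain (ECD) analyses:

* **ECD tilt angle** — the orientation of the ECD N-terminal helix relative to
  the membrane normal (+Z).  The helix direction is the vector sum of the
  backbone C=O bond vectors over the helical residues (default 30–47); the
  tilt is the angle between that vector and +Z, in degrees.  Open receptors
  show tilts around 20–60°, closed receptors around 100–150°.
* **COM distances** — geometric (unit-mass) centers by default, with a
  mass-weighted option.
* **TM6 z-shift** — the vertical displacement of TM6 relative to TM3, with a
  reference frame subtracted so rigid-body drift cancels.
* **Polar contacts** — pair counted as hydrogen-bonded when the minimum
  donor–acceptor heavy-atom distance is ≤ 3.6 Å (inclusive); a D−H···A angle
  test is applied only when explicit hydrogens exist and the criterion is
  enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geom import apply_rigid, rmsd, superpose
from .errors import (
    DegenerateGeometryError,
    ConsistencyError,
    ParameterError,
    SelectionError,
    TopologyError,
)
from .io_core import AtomSelection, Topology, Trajectory, select_atoms

__all__ = [
    "FeatureSeries",
    "StateSequence",
    "ecd_tilt_angle",
    "com_distance",
    "helix_end_com",
    "tm6_z_shift",
    "backbone_rmsd",
    "count_hbonds",
    "min_polar_distance",
    "assign_states",
    "STATE_OPEN",
    "STATE_CLOSED",
    "STATE_INTERMEDIATE",
    "WOOTTEN_NUMBERS",
]

# Discrete conformational state labels used by the threshold scheme.
STATE_OPEN = 0
STATE_CLOSED = 1
STATE_INTERMEDIATE = 2

# Static class-B generic residue numbering (Wootten) for the PAC1R positions
# referenced in this package's documentation; lookup data only.
WOOTTEN_NUMBERS = {
    185: "ICL1", 189: "2.50", 192: "2.53", 199: "2.60", 240: "3.43",
    241: "3.44", 244: "3.47", 247: "3.50", 344: "ICL3", 358: "6.45",
    365: "6.52", 392: "7.49", 396: "7.53",
}


@dataclass
class FeatureSeries:
    """A named per-frame scalar observable with units."""

    name: str
    values: np.ndarray
    units: str  # "degrees" | "Å" | "count"
    frame_interval: float = 1.0
    selections: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.units == "degrees" and self.values.size:
            if self.values.min() < -1e-9 or self.values.max() > 180 + 1e-9:
                raise ConsistencyError("angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class StateSequence:
    """Per-frame discrete state labels in ``[0, m)``."""

    labels: np.ndarray
    m: int
    frame_interval: float = 1.0
    provenance: str = "threshold"  # "threshold" | "hidden" | "clustering"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.m):
            raise ConsistencyError("state labels outside [0, m)")

    def __len__(self) -> int:
        return int(self.labels.size)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def _atom_indices_by_residue(topology: Topology, resid: int, name: str) -> int:
    hits = np.flatnonzero((topology.resids == resid) & (topology.names == name))
    if hits.size == 0:
        raise TopologyError(f"residue {resid} has no atom named {name!r}")
    return int(hits[0])


def ecd_tilt_angle(
    traj: Trajectory,
    helix_residues: tuple[int, int] = (30, 47),
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> FeatureSeries:
    """ECD tilt angle θ (degrees) from summed backbone C=O vectors.

    Per frame, ``v = Σ_res (O − C)`` over ``helix_residues`` (inclusive) and
    ``θ = arccos(v·ẑ / |v|)``.  The reference axis is the laboratory +Z
    (membrane normal); no per-frame membrane fitting is done.
    """
    lo, hi = helix_residues
    c_idx = np.array([_atom_indices_by_residue(traj.topology, r, "C") for r in range(lo, hi + 1)])
    o_idx = np.array([_atom_indices_by_residue(traj.topology, r, "O") for r in range(lo, hi + 1)])
    v = (traj.coords[:, o_idx] - traj.coords[:, c_idx]).sum(axis=1)  # (n_frames, 3)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        bad = int(np.argmax(norms < 1e-12))
        raise DegenerateGeometryError(f"summed C=O vector vanishes at frame {bad}")
    zhat = np.asarray(axis, float)
    zhat = zhat / np.linalg.norm(zhat)
    cosang = np.clip((v @ zhat) / norms, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    return FeatureSeries(
        "ecd_tilt_angle", theta, "degrees", traj.frame_interval,
        (f"resid {lo}-{hi} and name C O",),
    )


def _com(coords: np.ndarray, idx: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    sub = coords[:, idx]
    if weights is None:
        return sub.mean(axis=1)
    w = weights[idx]
    return (sub * w[None, :, None]).sum(axis=1) / w.sum()


def com_distance(
    traj: Trajectory,
    selA: AtomSelection,
    selB: AtomSelection,
    mass_weighted: bool = False,
) -> FeatureSeries:
    """Per-frame distance (Å) between the centers of two selections."""
    if selA.empty or selB.empty:
        raise SelectionError("com_distance requires two non-empty selections")
    w = traj.topology.masses() if mass_weighted else None
    d = np.linalg.norm(
        _com(traj.coords, selA.indices, w) - _com(traj.coords, selB.indices, w), axis=1
    )
    return FeatureSeries("com_distance", d, "Å", traj.frame_interval,
                         (selA.query, selB.query))


def helix_end_com(
    traj: Trajectory,
    helix_residues: tuple[int, int],
    end: str = "extracellular",
) -> np.ndarray:
    """Per-frame COM (n_frames × 3) of the four terminal residues of a helix.

    The extracellular end is whichever terminal four-residue group sits higher
    in z in the first frame; ``end="intracellular"`` selects the other one.
    """
    lo, hi = helix_residues
    resids = list(range(lo, hi + 1))
    if len(resids) < 4:
        raise ParameterError("helix must have at least 4 residues")
    topo = traj.topology
    bb = np.isin(topo.names, ("N", "CA", "C", "O"))

    def group_idx(rs):
        mask = np.isin(topo.resids, rs) & bb
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise TopologyError(f"no backbone atoms for residues {rs}")
        return idx

    first = group_idx(resids[:4])
    last = group_idx(resids[-4:])
    z_first = traj.coords[0, first, 2].mean()
    z_last = traj.coords[0, last, 2].mean()
    upper, lower = (first, last) if z_first >= z_last else (last, first)
    idx = upper if end == "extracellular" else lower
    return traj.coords[:, idx].mean(axis=1)


def tm6_z_shift(
    traj: Trajectory,
    tm6_residues: tuple[int, int] = (351, 371),
    tm3_residues: tuple[int, int] = (231, 251),
    reference_frame: int = 0,
) -> FeatureSeries:
    """Signed z-displacement (Å) of TM6 relative to TM3, reference-subtracted."""
    if not (0 <= reference_frame < traj.n_frames):
        raise ParameterError(f"reference frame {reference_frame} out of range")
    topo = traj.topology
    i6 = np.flatnonzero((topo.resids >= tm6_residues[0]) & (topo.resids <= tm6_residues[1]))
    i3 = np.flatnonzero((topo.resids >= tm3_residues[0]) & (topo.resids <= tm3_residues[1]))
    if i6.size == 0 or i3.size == 0:
        raise SelectionError("TM6/TM3 residue ranges select no atoms")
    dz = traj.coords[:, i6, 2].mean(axis=1) - traj.coords[:, i3, 2].mean(axis=1)
    return FeatureSeries(
        "tm6_z_shift", dz - dz[reference_frame], "Å", traj.frame_interval,
        (f"resid {tm6_residues[0]}-{tm6_residues[1]}",
         f"resid {tm3_residues[0]}-{tm3_residues[1]}"),
    )


def backbone_rmsd(
    traj: Trajectory,
    ref_coords: np.ndarray,
    align_sel: AtomSelection,
    measure_sel: AtomSelection | None = None,
    align: bool = True,
) -> FeatureSeries:
    """Per-frame RMSD (Å) over ``measure_sel`` after rigid alignment on ``align_sel``.

    Alignment is an optimal proper-rotation (Kabsch) superposition onto
    ``ref_coords``, which must cover the full topology.
    """
    ref_coords = np.asarray(ref_coords, float)
    if ref_coords.shape != (traj.n_atoms, 3):
        raise ConsistencyError(
            f"reference has shape {ref_coords.shape}; expected ({traj.n_atoms}, 3)"
        )
    if measure_sel is None:
        measure_sel = align_sel
    if align_sel.empty or measure_sel.empty:
        raise SelectionError("alignment/measure selections must be non-empty")
    ai, mi = align_sel.indices, measure_sel.indices
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if align:
            R, t = superpose(frame[ai], ref_coords[ai])
            moved = apply_rigid(frame[mi], R, t)
        else:
            moved = frame[mi]
        out[f] = rmsd(moved, ref_coords[mi])
    return FeatureSeries("backbone_rmsd", out, "Å", traj.frame_interval,
                         (align_sel.query, measure_sel.query))


def _min_pair_distance(frame: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=2)
    k = np.unravel_index(np.argmin(d), d.shape)
    return d[k], int(ia[k[0]]), int(ib[k[1]])


def count_hbonds(
    traj: Trajectory,
    pairs: Sequence[tuple[AtomSelection | str, AtomSelection | str]],
    cutoff: float = 3.6,
    angle_min: float | None = None,
) -> FeatureSeries:
    """Number of donor/acceptor pairs in polar contact per frame.

    A pair counts when its minimum donor–acceptor heavy-atom distance is
    ``≤ cutoff`` (inclusive; default 3.6 Å).  If ``angle_min`` is given and
    hydrogens bonded to the closest donor exist, the best D−H···A angle must
    also be ``≥ angle_min`` degrees.
    """
    if not pairs:
        raise ParameterError("count_hbonds needs at least one donor/acceptor pair")
    topo = traj.topology
    resolved = []
    for don, acc in pairs:
        d = select_atoms(topo, don) if isinstance(don, str) else don
        a = select_atoms(topo, acc) if isinstance(acc, str) else acc
        if d.empty or a.empty:
            raise SelectionError("empty donor or acceptor selection in H-bond pair")
        resolved.append((d.indices, a.indices))
    h_mask = topo.elements == "H"
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        n = 0
        for ia, ib in resolved:
            dist, di, aj = _min_pair_distance(frame, ia, ib)
            if dist > cutoff:
                continue
            if angle_min is not None and h_mask.any():
                hs = np.flatnonzero(
                    h_mask & (np.linalg.norm(frame - frame[di], axis=1) <= 1.25)
                )
                if hs.size:
                    hd = frame[di] - frame[hs]
                    ha = frame[aj] - frame[hs]
                    cosang = (hd * ha).sum(axis=1) / (
                        np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang.max() < angle_min:
                        continue
            n += 1
        counts[f] = n
    queries = tuple(q for p in pairs for q in (p if isinstance(p[0], str) else (p[0].query, p[1].query)))
    return FeatureSeries("hbond_count", counts, "count", traj.frame_interval, queries)


def min_polar_distance(
    traj: Trajectory,
    residueA: int,
    residueB: int,
) -> FeatureSeries:
    """Minimum N/O–N/O distance (Å) between two residues, per frame.

    This is the nearest-polar-atom distance used to follow salt bridges such
    as the ICL3–ICL1 glutamate–arginine contact.
    """
    topo = traj.topology
    polar = np.isin(topo.elements, ("N", "O"))
    ia = np.flatnonzero((topo.resids == residueA) & polar)
    ib = np.flatnonzero((topo.resids == residueB) & polar)
    if ia.size == 0 or ib.size == 0:
        raise TopologyError(
            f"residue {residueA if ia.size == 0 else residueB} has no polar (N/O) atoms"
        )
    d = np.linalg.norm(
        traj.coords[:, ia][:, :, None, :] - traj.coords[:, ib][:, None, :, :], axis=3
    ).min(axis=(1, 2))
    return FeatureSeries("min_polar_distance", d, "Å", traj.frame_interval,
                         (f"resid {residueA}", f"resid {residueB}"))


# ---------------------------------------------------------------------------
# state assignment
# ---------------------------------------------------------------------------

def assign_states(
    tilt: FeatureSeries,
    scheme: str = "threshold",
    open_range: tuple[float, float] = (20.0, 60.0),
    closed_range: tuple[float, float] = (100.0, 150.0),
    feature_matrix: np.ndarray | None = None,
    n_states: int = 2,
    seed: int = 0,
) -> StateSequence:
    """Assign each frame to a discrete conformational state.

    ``threshold`` scheme: open (state 0) for tilt in ``open_range``, closed
    (state 1) for tilt in ``closed_range``, every other frame becomes the
    intermediate state 2 so the partition is complete for MSM estimation.

    ``kmeans`` scheme: seeded k-means (k-means++ initialization) on
    ``feature_matrix`` with ``n_states`` clusters.
    """
    if len(tilt) == 0:
        raise ParameterError("cannot assign states to an empty feature series")
    if scheme == "threshold":
        v = tilt.values
        labels = np.full(v.size, STATE_INTERMEDIATE, dtype=int)
        labels[(v >= open_range[0]) & (v <= open_range[1])] = STATE_OPEN
        labels[(v >= closed_range[0]) & (v <= closed_range[1])] = STATE_CLOSED
        return StateSequence(labels, m=3, frame_interval=tilt.frame_interval,
                             provenance="threshold")
    if scheme == "kmeans":
        from sklearn.cluster import KMeans

        X = tilt.values[:, None] if feature_matrix is None else np.asarray(feature_matrix, float)
        km = KMeans(n_clusters=n_states, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        return StateSequence(labels, m=n_states, frame_interval=tilt.frame_interval,
                             provenance="clustering")
    raise ParameterError(f"unknown state-assignment scheme {scheme!r}")
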