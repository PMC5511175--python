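"""Synthetic receptors, trajectories, water ensembles and Markov chains.

All test inputs for the analysis pipeline are generated here, because the
microsecond simulations this kind of analysis is normally applied to are far
too expensive to regenerate.  The generators emulate the *geometry and
statistics* the analysis assumes — an extracellular domain (ECD) helix whose
tilt angle switches between an open basin (20–60°) and a closed basin
(100–150°) under a hidden two-state Markov process, seven transmembrane (TM)
helices on a circle, uniform water ensembles — not physical dynamics.

Every generator is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ModelError, ParameterError, SpecError
from .features import StateSequence
from .io_core import Atom, Topology, Trajectory

__all__ = [
    "ToyReceptorSpec",
    "TwoBasinSpec",
    "build_ideal_helix",
    "build_toy_receptor",
    "generate_markov_chain",
    "generate_two_basin_trajectory",
    "place_waters",
]

# canonical α-helix backbone parameters
HELIX_TURN_DEG = 100.0
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
CO_BOND_LENGTH = 1.23
CO_AXIS_TILT_DEG = 12.0  # small off-axis component of the C=O bond


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking +z onto ``axis`` (unit vector)."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ParameterError("axis must be a non-zero vector")
    axis = axis / n
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _helix_backbone(n_res: int, rise: float = HELIX_RISE,
                    radius: float = HELIX_RADIUS) -> np.ndarray:
    """Backbone coordinates (n_res, 4, 3) in order N, CA, C, O, axis = +z.

    The C=O bond points mostly along +z with a small rotating radial
    component, so the summed C=O vector is near-parallel to the axis (the
    perpendicular parts cancel over full turns), as in a real α-helix.
    """
    i = np.arange(n_res)
    phi = np.radians(HELIX_TURN_DEG) * i
    alpha = np.radians(CO_AXIS_TILT_DEG)

    def ring(r, dphi, dz):
        a = phi + dphi
        return np.stack([r * np.cos(a), r * np.sin(a), i * rise + dz], axis=1)

    ca = ring(radius, 0.0, 0.0)
    n = ring(radius * 0.70, np.radians(-28.0), -0.90)
    c = ring(radius * 0.74, np.radians(+26.0), +0.55)
    co_dir = np.stack(
        [np.sin(alpha) * np.cos(phi + np.radians(26.0)),
         np.sin(alpha) * np.sin(phi + np.radians(26.0)),
         np.full(n_res, np.cos(alpha))], axis=1)
    o = c + CO_BOND_LENGTH * co_dir
    return np.stack([n, ca, c, o], axis=1)


def _helix_atoms(resid_start: int, n_res: int, chain: str = "A",
                 resname: str = "ALA", index_start: int = 1) -> list[Atom]:
    atoms = []
    idx = index_start
    for r in range(n_res):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(idx, name, resid_start + r, resname, chain, elem))
            idx += 1
    return atoms


def build_ideal_helix(
    n_res: int,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    resid_start: int = 1,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
) -> tuple[Topology, np.ndarray]:
    """Canonical α-helix backbone (N, CA, C, O) with its axis along ``axis``.

    100° turn per residue, 1.5 Å rise; the summed C=O vector is near-parallel
    to the axis by construction.
    """
    if n_res < 4:
        raise ParameterError("an ideal helix needs at least 4 residues")
    coords = _helix_backbone(n_res, rise, radius).reshape(-1, 3)
    R = _rotation_to(np.asarray(axis, float))
    coords = coords @ R.T
    topo = Topology(_helix_atoms(resid_start, n_res))
    return topo, coords


# ---------------------------------------------------------------------------
# toy receptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReceptorSpec:
    """Geometry of a toy class-B-receptor-like scaffold.

    Residue ranges default to the numbering used for PAC1R-style analyses
    (N-terminal ECD helix 30–47, linker 126–149, TM6 at 351–371); the helix
    geometry values are generator conventions.
    """

    n_tm_helices: int = 7
    residues_per_helix: int = 21
    ecd_residue_range: tuple[int, int] = (30, 47)
    linker_residue_range: tuple[int, int] = (126, 149)
    tm_residue_ranges: tuple[tuple[int, int], ...] = (
        (151, 171), (191, 211), (231, 251), (271, 291),
        (311, 331), (351, 371), (391, 411),
    )
    ecd_tilt_deg: float = 40.0
    rise_per_residue: float = HELIX_RISE
    helix_radius: float = HELIX_RADIUS
    bundle_radius: float = 12.0

    def validate(self) -> None:
        if not (0.0 <= self.ecd_tilt_deg <= 180.0):
            raise SpecError(f"ecd_tilt_deg {self.ecd_tilt_deg} outside [0, 180]")
        if len(self.tm_residue_ranges) != self.n_tm_helices:
            raise SpecError("need one residue range per TM helix")
        ranges = [self.ecd_residue_range, self.linker_residue_range,
                  *self.tm_residue_ranges]
        for lo, hi in ranges:
            if lo > hi:
                raise SpecError(f"range ({lo}, {hi}) is reversed")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
            if b_lo <= a_hi:
                raise SpecError("residue ranges must be disjoint and ordered")


def _toy_receptor_segments(spec: ToyReceptorSpec):
    """Yield (resid_range, coords_fn(tilt_deg) -> (n_res, 4, 3)) per segment."""
    tm_len = spec.residues_per_helix * spec.rise_per_residue
    ecd_base_z = tm_len + 8.0

    def ecd_coords(tilt_deg: float) -> np.ndarray:
        lo, hi = spec.ecd_residue_range
        n = hi - lo + 1
        bb = _helix_backbone(n, spec.rise_per_residue, spec.helix_radius)
        t = np.radians(tilt_deg)
        R = _rotation_to(np.array([np.sin(t), 0.0, np.cos(t)]))
        bb = bb @ R.T
        bb[:, :, 2] += ecd_base_z
        return bb

    def linker_coords(_tilt) -> np.ndarray:
        lo, hi = spec.linker_residue_range
        n = hi - lo + 1
        # extended strand from the bundle rim up toward the ECD
        t = np.linspace(0.0, 1.0, n)
        start = np.array([spec.bundle_radius, 0.0, tm_len])
        stop = np.array([2.0, 0.0, ecd_base_z])
        ca = start + t[:, None] * (stop - start)
        offs = {"N": np.array([-0.5, 0.3, -0.5]), "CA": np.zeros(3),
                "C": np.array([0.5, -0.3, 0.5]), "O": np.array([0.5, -0.3, 1.7])}
        return np.stack([ca + offs[k] for k in ("N", "CA", "C", "O")], axis=1)

    def tm_coords_fn(k):
        def tm_coords(_tilt) -> np.ndarray:
            lo, hi = spec.tm_residue_ranges[k]
            n = hi - lo + 1
            bb = _helix_backbone(n, spec.rise_per_residue, spec.helix_radius)
            ang = 2 * np.pi * k / spec.n_tm_helices
            bb[:, :, 0] += spec.bundle_radius * np.cos(ang)
            bb[:, :, 1] += spec.bundle_radius * np.sin(ang)
            return bb
        return tm_coords

    segments = [(spec.ecd_residue_range, ecd_coords),
                (spec.linker_residue_range, linker_coords)]
    for k in range(spec.n_tm_helices):
        segments.append((spec.tm_residue_ranges[k], tm_coords_fn(k)))
    segments.sort(key=lambda s: s[0][0])
    return segments


def build_toy_receptor(spec: ToyReceptorSpec) -> tuple[Topology, np.ndarray]:
    """Deterministic toy receptor: 7 TM helices on a circle (axes ‖ Z), an
    extended linker, and an ECD helix whose axis makes ``ecd_tilt_deg`` with +Z.
    """
    spec.validate()
    atoms: list[Atom] = []
    blocks: list[np.ndarray] = []
    idx = 1
    for (lo, hi), fn in _toy_receptor_segments(spec):
        n = hi - lo + 1
        atoms.extend(_helix_atoms(lo, n, index_start=idx))
        idx += 4 * n
        blocks.append(fn(spec.ecd_tilt_deg).reshape(-1, 3))
    return Topology(atoms), np.concatenate(blocks, axis=0)


def _receptor_frame_builder(spec: ToyReceptorSpec):
    """Return (topology, coords_fn) where coords_fn(tilt) rebuilds one frame."""
    spec.validate()
    segments = _toy_receptor_segments(spec)
    atoms: list[Atom] = []
    idx = 1
    for (lo, hi), _fn in segments:
        n = hi - lo + 1
        atoms.extend(_helix_atoms(lo, n, index_start=idx))
        idx += 4 * n
    topo = Topology(atoms)
    static = [None if (lo, hi) == spec.ecd_residue_range else fn(0.0).reshape(-1, 3)
              for (lo, hi), fn in segments]
    ecd_fn = dict((tuple(rng), fn) for rng, fn in segments)[tuple(spec.ecd_residue_range)]

    def coords_fn(tilt_deg: float) -> np.ndarray:
        blocks = [ecd_fn(tilt_deg).reshape(-1, 3) if blk is None else blk
                  for blk in static]
        return np.concatenate(blocks, axis=0)

    return topo, coords_fn


# ---------------------------------------------------------------------------
# Markov chains and two-basin trajectories
# ---------------------------------------------------------------------------

def _validate_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ModelError(f"transition matrix must be square; got {T.shape}")
    if (T < -1e-12).any():
        raise ModelError("transition matrix has negative entries")
    if np.abs(T.sum(axis=1) - 1.0).max() > 1e-10:
        raise ModelError("transition matrix rows must sum to 1 within 1e-10")
    return T


def generate_markov_chain(
    T: np.ndarray,
    n_steps: int,
    start: int | str = "stationary",
    seed: int = 0,
    frame_interval: float = 1.0,
) -> StateSequence:
    """Sample a discrete Markov chain of length ``n_steps`` from row-stochastic ``T``.

    ``start`` is a state index or ``"stationary"`` (initial state drawn from
    the stationary distribution).  Deterministic given (T, n_steps, start, seed).
    """
    T = _validate_stochastic(T)
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    m = T.shape[0]
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T, axis=1)
    cdf[:, -1] = 1.0
    if start == "stationary":
        from .msm import stationary_distribution

        pi = stationary_distribution(T)
        s = int(rng.choice(m, p=pi))
    else:
        s = int(start)
        if not (0 <= s < m):
            raise ParameterError(f"start state {s} outside [0, {m})")
    u = rng.random(n_steps - 1)
    labels = np.empty(n_steps, dtype=np.int64)
    labels[0] = s
    searchsorted = np.searchsorted
    for t in range(n_steps - 1):
        s = int(searchsorted(cdf[s], u[t], side="right"))
        labels[t + 1] = s
    return StateSequence(labels, m=m, frame_interval=frame_interval, provenance="hidden")


@dataclass(frozen=True)
class TwoBasinSpec:
    """Hidden two-state (open/closed) switching process for the ECD tilt.

    State 0 is open, state 1 is closed.  Per frame the tilt is drawn from the
    occupied basin's truncated normal; supports default to the open 20–60°
    and closed 100–150° partitions, which are disjoint so threshold state
    assignment can recover the hidden labels exactly.
    """

    p_stay_open: float = 0.98
    p_stay_closed: float = 0.98
    open_tilt_mean: float = 40.0
    open_tilt_sd: float = 8.0
    closed_tilt_mean: float = 125.0
    closed_tilt_sd: float = 10.0
    open_support: tuple[float, float] = (20.0, 60.0)
    closed_support: tuple[float, float] = (100.0, 150.0)
    n_frames: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_stay_open, self.p_stay_closed):
            if not (0.0 < p <= 1.0):
                raise SpecError(f"stay probability {p} outside (0, 1]")
        for sd in (self.open_tilt_sd, self.closed_tilt_sd):
            if sd <= 0:
                raise SpecError("basin standard deviations must be positive")
        for lo, hi in (self.open_support, self.closed_support):
            if not (0.0 <= lo < hi <= 180.0):
                raise SpecError(f"basin support ({lo}, {hi}) outside [0, 180]")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")

    def hidden_transition_matrix(self) -> np.ndarray:
        return np.array([
            [self.p_stay_open, 1.0 - self.p_stay_open],
            [1.0 - self.p_stay_closed, self.p_stay_closed],
        ])

    def stationary_open_fraction(self) -> float:
        a = 1.0 - self.p_stay_open
        b = 1.0 - self.p_stay_closed
        return b / (a + b)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal; exact support control."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16) * 2)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_two_basin_trajectory(
    spec: TwoBasinSpec,
    receptor: ToyReceptorSpec | None = None,
) -> tuple[Trajectory, StateSequence]:
    """Receptor trajectory whose ECD tilt switches between two basins.

    A hidden 2-state chain (open/closed) is sampled first; per frame a tilt is
    drawn from the occupied basin's truncated normal and the toy receptor is
    rebuilt at that tilt.  The hidden labels are returned for recovery tests.
    One seeded generator stream drives both the chain and the emission noise,
    so the whole trajectory regenerates exactly from (spec, receptor).
    """
    spec.validate()
    if receptor is None:
        receptor = ToyReceptorSpec()
    rng = np.random.default_rng(spec.seed)
    T = spec.hidden_transition_matrix()
    chain_seed = int(rng.integers(0, 2**31 - 1))
    hidden = generate_markov_chain(T, spec.n_frames, start="stationary", seed=chain_seed)
    tilts = np.empty(spec.n_frames)
    for state, (mean, sd, (lo, hi)) in enumerate([
        (spec.open_tilt_mean, spec.open_tilt_sd, spec.open_support),
        (spec.closed_tilt_mean, spec.closed_tilt_sd, spec.closed_support),
    ]):
        mask = hidden.labels == state
        tilts[mask] = _truncated_normal(rng, mean, sd, lo, hi, int(mask.sum()))
    topo, coords_fn = _receptor_frame_builder(receptor)
    coords = np.empty((spec.n_frames, topo.n_atoms, 3))
    for f in range(spec.n_frames):
        coords[f] = coords_fn(tilts[f])
    traj = Trajectory(topo, coords)
    return traj, hidden


# ---------------------------------------------------------------------------
# water ensembles
# ---------------------------------------------------------------------------

def place_waters(
    box: Sequence[float],
    n: int,
    region: str | dict = "uniform",
    seed: int = 0,
) -> np.ndarray:
    """Place ``n`` water-oxygen positions uniformly inside a region of ``box``.

    Regions: ``"uniform"`` (whole box); ``{"kind": "cylinder", "center":
    (x, y), "radius": r, "zmin": z0, "zmax": z1}`` (uniform in a z-aligned
    cylinder); ``{"kind": "slab_gap", "zmin": z0, "zmax": z1}`` (whole box
    minus the z-slab — a broken water column for pathway-detection tests).
    """
    box = np.asarray(box, float)
    if box.shape != (3,) or (box <= 0).any():
        raise SpecError("box must be three positive lengths")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 3))
    if region == "uniform":
        return rng.random((n, 3)) * box
    kind = region.get("kind")
    if kind == "cylinder":
        cx, cy = region["center"]
        r, z0, z1 = float(region["radius"]), float(region["zmin"]), float(region["zmax"])
        if not (0 <= cx - r and cx + r <= box[0] and 0 <= cy - r and cy + r <= box[1]
                and 0 <= z0 < z1 <= box[2]):
            raise SpecError("cylinder region extends outside the box")
        rad = r * np.sqrt(rng.random(n))
        ang = 2 * np.pi * rng.random(n)
        z = z0 + (z1 - z0) * rng.random(n)
        return np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang), z], axis=1)
    if kind == "slab_gap":
        z0, z1 = float(region["zmin"]), float(region["zmax"])
        if not (0 <= z0 < z1 <= box[2]):
            raise SpecError("slab gap outside the box")
        out = np.empty((0, 3))
        while out.shape[0] < n:
            draw = rng.random((2 * n + 16, 3)) * box
            keep = draw[(draw[:, 2] < z0) | (draw[:, 2] >= z1)]
            out = np.concatenate([out, keep])
        return out[:n]
    raise SpecError(f"unknown water region {region!r}")
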