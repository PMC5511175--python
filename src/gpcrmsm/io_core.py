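"""Structure/trajectory I/O, topology bookkeeping and atom selections.

Supported formats are deliberately minimal and text-only: PDB (single- and
multi-MODEL, the latter treated as a trajectory container) and a plain-text
xyz-per-frame dialect used for full-precision fixtures::

    N
    comment
    name resid x y z        (N lines)

Selections use a small query language over residue ids and atom names::

    resid 30-47 and backbone
    name CA or name CB
    (resid 1-10 or resid 90-100) and not name O

``backbone`` expands to atom names N, CA, C, O.  Residue ranges are inclusive
and residue numbering is 1-based throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    EmptyInputError,
    FormatError,
    SelectionError,
)

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "read_structure",
    "read_trajectory",
    "select_atoms",
    "write_pdb",
    "write_xyz",
    "write_table",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# crude element masses for the optional mass-weighted COM
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "X": 1.0,
}


@dataclass(frozen=True)
class Atom:
    """One atom record; indices and residue numbers are 1-based."""

    index: int
    name: str
    resid: int
    resname: str
    chain: str
    element: str


class Topology:
    """Ordered atom list with fast lookup arrays for selections.

    Invariants: atom indices are contiguous from 1; residue numbers are
    non-decreasing within a chain.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise EmptyInputError("topology contains no atoms")
        for i, a in enumerate(atoms, start=1):
            if a.index != i:
                raise ConsistencyError(
                    f"atom indices must be contiguous from 1; atom {i} has index {a.index}"
                )
        last: dict[str, int] = {}
        for a in atoms:
            if a.resid < last.get(a.chain, -(10**9)):
                raise ConsistencyError(
                    f"residue numbers decrease within chain {a.chain!r} at atom {a.index}"
                )
            last[a.chain] = a.resid
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.names = np.array([a.name for a in atoms])
        self.resids = np.array([a.resid for a in atoms], dtype=int)
        self.resnames = np.array([a.resname for a in atoms])
        self.chains = np.array([a.chain for a in atoms])
        self.elements = np.array([a.element for a in atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.0) for e in self.elements])

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms

    def __repr__(self) -> str:
        return f"<Topology: {self.n_atoms} atoms, {len(set(self.resids))} residues>"


@dataclass
class Trajectory:
    """Frames of coordinates (Å) over a fixed topology.

    ``frame_interval`` is the time per frame in abstract τ-units; physical
    units are the caller's responsibility.
    """

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths
    frame_interval: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError(f"coords must be (n_frames, n_atoms, 3); got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ConsistencyError(
                f"coords have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ConsistencyError("non-finite coordinates in trajectory")
        if self.frame_interval <= 0:
            raise ConsistencyError("frame_interval must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class AtomSelection:
    """Resolved selection: 0-based positional indices plus the source query."""

    topology: Topology
    indices: np.ndarray  # 0-based positions into the atom list, sorted
    query: str
    empty: bool = field(init=False)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "empty", idx.size == 0)

    @property
    def member_indices(self) -> set[int]:
        """1-based atom indices, per the file convention."""
        return set((self.indices + 1).tolist())

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

class _Tokenizer:
    def __init__(self, query: str):
        self.query = query
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        i = 0
        n = len(query)
        while i < n:
            c = query[i]
            if c.isspace():
                i += 1
                continue
            if c in "()":
                self.tokens.append((c, i))
                i += 1
                continue
            j = i
            while j < n and not query[j].isspace() and query[j] not in "()":
                j += 1
            self.tokens.append((query[i:j], i))
            i = j

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.query))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok


def _parse_resid_items(tz: _Tokenizer, topo: Topology) -> np.ndarray:
    mask = np.zeros(topo.n_atoms, dtype=bool)
    saw = False
    while True:
        tok, at = tz.peek()
        if tok is None or tok in ("and", "or", "not", ")", "(", "resid", "name", "backbone"):
            break
        tz.next()
        saw = True
        if "-" in tok[1:]:  # allow negative guard: split on first interior dash
            lo_s, _, hi_s = tok.partition("-") if not tok.startswith("-") else (tok, "", "")
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad resid range {tok!r} at position {at}")
            mask |= (topo.resids >= lo) & (topo.resids <= hi)
        else:
            try:
                r = int(tok)
            except ValueError:
                raise SelectionError(f"bad resid {tok!r} at position {at}")
            mask |= topo.resids == r
    if not saw:
        tok, at = tz.peek()
        raise SelectionError(f"'resid' expects at least one id/range at position {at}")
    return mask


def _parse_name_items(tz: _Tokenizer, topo: Topology) -> np.ndarray:
    mask = np.zeros(topo.n_atoms, dtype=bool)
    saw = False
    while True:
        tok, at = tz.peek()
        if tok is None or tok in ("and", "or", "not", ")", "(", "resid", "name", "backbone"):
            break
        tz.next()
        saw = True
        mask |= topo.names == tok
    if not saw:
        tok, at = tz.peek()
        raise SelectionError(f"'name' expects at least one atom name at position {at}")
    return mask


def _parse_factor(tz: _Tokenizer, topo: Topology) -> np.ndarray:
    tok, at = tz.next()
    if tok is None:
        raise SelectionError(f"unexpected end of query at position {at}")
    if tok == "(":
        mask = _parse_or(tz, topo)
        tok2, at2 = tz.next()
        if tok2 != ")":
            raise SelectionError(f"expected ')' at position {at2}")
        return mask
    if tok == "not":
        return ~_parse_factor(tz, topo)
    if tok == "backbone":
        return np.isin(topo.names, BACKBONE_NAMES)
    if tok == "resid":
        return _parse_resid_items(tz, topo)
    if tok == "name":
        return _parse_name_items(tz, topo)
    raise SelectionError(f"unexpected token {tok!r} at position {at}")


def _parse_and(tz: _Tokenizer, topo: Topology) -> np.ndarray:
    mask = _parse_factor(tz, topo)
    while tz.peek()[0] == "and":
        tz.next()
        mask = mask & _parse_factor(tz, topo)
    return mask


def _parse_or(tz: _Tokenizer, topo: Topology) -> np.ndarray:
    mask = _parse_and(tz, topo)
    while tz.peek()[0] == "or":
        tz.next()
        mask = mask | _parse_and(tz, topo)
    return mask


def select_atoms(topology: Topology, query: str) -> AtomSelection:
    """Resolve ``query`` on ``topology`` into an :class:`AtomSelection`.

    Pure and deterministic: identical inputs always yield identical member
    sets.  An empty result is allowed and flagged on the returned object
    (``selection.empty``).
    """
    tz = _Tokenizer(query)
    if not tz.tokens:
        raise SelectionError("empty selection query")
    mask = _parse_or(tz, topology)
    tok, at = tz.peek()
    if tok is not None:
        raise SelectionError(f"trailing token {tok!r} at position {at}")
    return AtomSelection(topology, np.flatnonzero(mask), query)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[Atom | None, np.ndarray, str]:
    """Parse one ATOM/HETATM line -> (Atom-fields sans index, xyz, altloc)."""
    try:
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:20].strip() or "UNK"
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        icode = line[26:27]
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise FormatError(f"insertion code {icode!r} at line {lineno} is not supported")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1] if name else "X"
    atom = Atom(index=0, name=name, resid=resid, resname=resname,
                chain=chain, element=element)
    return atom, xyz, altloc


def _read_pdb_models(path) -> list[tuple[list[Atom], np.ndarray]]:
    """Read all MODELs; returns [(atoms, coords)].  First altloc kept."""
    models: list[tuple[list[Atom], np.ndarray]] = []
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    altloc_seen: dict[tuple, str] = {}
    in_model = False

    def flush():
        nonlocal atoms, coords, altloc_seen
        if atoms:
            models.append((atoms, np.array(coords)))
        atoms, coords, altloc_seen = [], [], {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                flush()
                in_model = True
            elif rec.startswith("ENDMDL"):
                flush()
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                proto, xyz, altloc = _parse_pdb_atom_line(line.rstrip("\n"), lineno)
                key = (proto.chain, proto.resid, proto.name)
                if altloc.strip():
                    first = altloc_seen.setdefault(key, altloc)
                    if altloc != first:
                        continue  # keep first altloc only
                atoms.append(Atom(index=len(atoms) + 1, name=proto.name,
                                  resid=proto.resid, resname=proto.resname,
                                  chain=proto.chain, element=proto.element))
                coords.append(xyz)
    flush()
    return models


def read_structure(path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file; returns the topology and model-1 coordinates (Å)."""
    models = _read_pdb_models(path)
    if not models:
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")
    atoms, coords = models[0]
    return Topology(atoms), coords


def _read_xyz_frames(path, topology: Topology) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"expected atom count at line {i + 1}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ConsistencyError(
                f"frame {frame_no}: expected {n} atom lines, file truncated"
            )
        if n != topology.n_atoms:
            raise ConsistencyError(
                f"frame {frame_no} has {n} atoms; topology has {topology.n_atoms}"
            )
        xyz = np.empty((n, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) != 5:
                raise FormatError(f"bad xyz record at line {i + 3 + k}")
            xyz[k] = [float(parts[2]), float(parts[3]), float(parts[4])]
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise EmptyInputError(f"no frames in {path}")
    return np.array(frames)


def read_trajectory(path, topology: Topology, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB or xyz-dialect file as a trajectory.

    The format is chosen by content: a file whose first non-blank line is an
    integer is treated as the xyz dialect, anything else as PDB.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    is_xyz = first.isdigit()
    if is_xyz:
        coords = _read_xyz_frames(path, topology)
    else:
        models = _read_pdb_models(path)
        if not models:
            raise EmptyInputError(f"no ATOM/HETATM records in {path}")
        frames = []
        for fi, (atoms, xyz) in enumerate(models, start=1):
            if len(atoms) != topology.n_atoms:
                raise ConsistencyError(
                    f"frame {fi} has {len(atoms)} atoms; topology has {topology.n_atoms}"
                )
            frames.append(xyz)
        coords = np.array(frames)
    return Trajectory(topology, coords, frame_interval=frame_interval)


def write_pdb(path, topology: Topology, coords: np.ndarray) -> None:
    """Write coordinates as PDB; 3-D input becomes a multi-MODEL trajectory."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    multi = coords.shape[0] > 1
    with open(path, "w") as fh:
        for m, frame in enumerate(coords, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for a, xyz in zip(topology.atoms, frame):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.index % 100000:5d} {name}{'':1s}{a.resname:>3s} "
                    f"{a.chain:1s}{a.resid % 10000:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(path, topology: Topology, coords: np.ndarray) -> None:
    """Write the full-precision xyz dialect (one block per frame)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for fi, frame in enumerate(coords):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {fi}\n")
            for a, xyz in zip(topology.atoms, frame):
                fh.write(f"{a.name} {a.resid} "
                         f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")


def write_table(data, path, header: Iterable[str] | None = None) -> None:
    """Write a series or matrix as CSV with a header row, full precision.

    1-D input becomes (frame, value) rows; 2-D input is written row-wise with
    generated column names unless ``header`` is given.
    """
    arr = np.asarray(data, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if arr.ndim <= 1:
            w.writerow(header if header is not None else ["frame", "value"])
            for i, v in enumerate(np.atleast_1d(arr)):
                w.writerow([i, repr(float(v))])
        elif arr.ndim == 2:
            cols = list(header) if header is not None else [f"c{j}" for j in range(arr.shape[1])]
            w.writerow(cols)
            for row in arr:
                w.writerow([repr(float(v)) for v in row])
        else:
            raise ValueError("write_table accepts 1-D or 2-D data")
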