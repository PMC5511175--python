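"""Rigid-body superposition helpers (Kabsch via scipy)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` with proper rotation R (det = +1) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((d * d).sum() / len(d)))
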