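"""Pipeline configuration: defaults, YAML loading, validation, manifests.

The default selections encode the residue numbering conventions used
throughout the package (ECD N-terminal helix 30–47, ECD core 30–77 ∪
112–125, linker 126–149, TM6 351–371) and the open/closed tilt partitions
(open 20–60°, closed 100–150°).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "gpcrmsm_out",
    "input": {
        # either file paths ...
        "topology": None,       # PDB
        "trajectory": None,     # multi-model PDB or xyz dialect
        # ... or the synthetic two-basin generator below
        "synthetic": True,
    },
    "synthetic": {
        "n_frames": 5000,
        "p_stay_open": 0.98,
        "p_stay_closed": 0.98,
        "open_tilt_mean": 40.0,
        "open_tilt_sd": 8.0,
        "closed_tilt_mean": 125.0,
        "closed_tilt_sd": 10.0,
        "open_support": [20.0, 60.0],
        "closed_support": [100.0, 150.0],
    },
    "selections": {
        "nterm_helix": "resid 30-47",
        "ecd_core": "resid 30-77 112-125",
        "linker": "resid 126-149",
        "tm_all": "resid 151-171 191-211 231-251 271-291 311-331 351-371 391-411",
        "tm3": "resid 231-251",
        "tm6": "resid 351-371",
        "zipper_ecd": "resid 80-91",
        "zipper_ecl3": "resid 372-390",
        "backbone": "backbone",
    },
    "features": ["ecd_tilt", "ecd_7tm_distance", "tm6_z_shift", "rmsd_7tm"],
    "states": {
        "scheme": "threshold",
        "open_range": [20.0, 60.0],
        "closed_range": [100.0, 150.0],
    },
    "msm": {"lag": 1, "mode": "sliding", "ck_n_values": [2, 3]},
    "tpt": {"A": [0], "B": [1], "max_paths": 10},
    "hydration": {
        "synthetic_waters": {"n": 2000, "box": [50.0, 50.0, 50.0],
                             "region": "uniform", "n_frames": 1},
        "origin": [0.0, 0.0, 0.0],
        "dims": [25, 25, 25],
        "voxel_size": 2.0,
        "pathway_threshold": 0.002,
        "cross_section": {"axis": "z", "slab": [10, 14]},
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            out[key] = copy.deepcopy(val)
        elif isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None) -> dict:
    """Load YAML config merged over the defaults; ``None`` gives the defaults."""
    cfg = default_config()
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(user, dict):
            raise ConfigError("config must be a mapping")
        cfg = _merge(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Check field domains; error messages name the offending field path."""
    syn = cfg.get("synthetic", {})
    if int(syn.get("n_frames", 0)) < 1:
        raise ConfigError("synthetic.n_frames must be >= 1")
    for key in ("p_stay_open", "p_stay_closed"):
        p = float(syn.get(key, 0.98))
        if not (0.0 < p <= 1.0):
            raise ConfigError(f"synthetic.{key} must be in (0, 1]")
    st = cfg.get("states", {})
    for key in ("open_range", "closed_range"):
        rng = st.get(key)
        if not (isinstance(rng, (list, tuple)) and len(rng) == 2 and rng[0] < rng[1]):
            raise ConfigError(f"states.{key} must be [low, high] with low < high")
    if int(cfg.get("msm", {}).get("lag", 1)) < 1:
        raise ConfigError("msm.lag must be >= 1")
    t = cfg.get("tpt", {})
    A, B = set(t.get("A", [])), set(t.get("B", []))
    if not A or not B:
        raise ConfigError("tpt.A and tpt.B must be non-empty")
    if A & B:
        raise ConfigError("tpt.A and tpt.B must be disjoint")
    hyd = cfg.get("hydration", {})
    if float(hyd.get("voxel_size", 1.0)) <= 0:
        raise ConfigError("hydration.voxel_size must be positive")
    if not isinstance(cfg.get("features"), list) or not cfg["features"]:
        raise ConfigError("features must be a non-empty list")


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(outdir: Path, cfg: dict, extra: dict | None = None) -> Path:
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "version": __version__,
        "config": cfg,
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
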