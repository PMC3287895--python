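"""Flat key-value run configuration with namespaced keys.

Configuration files are YAML mappings with dotted keys, e.g.::

    prior.m: 1000
    gibbs.n_iter: 2000
    perm.J: 1000
    design.center: true

Unknown keys are rejected so typos fail loudly. Command-line overrides
take precedence over file values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

__all__ = ["KNOWN_KEYS", "load_config", "merge_config", "spawn_seeds"]

KNOWN_KEYS: dict[str, type] = {
    "prior.m": float,
    "prior.a": float,
    "prior.b": float,
    "gibbs.n_iter": int,
    "gibbs.burn_in": int,
    "gibbs.thin": int,
    "gibbs.seed": int,
    "perm.J": int,
    "perm.seed": int,
    "perm.estimator": str,
    "design.center": bool,
    "svd.rank_tol": float,
    "sim.n": int,
    "sim.k": int,
    "sim.maf_low": float,
    "sim.maf_high": float,
    "sim.n_causal": int,
    "sim.effect_size": float,
    "sim.noise_sd": float,
    "sim.n_replicates": int,
    "sim.causal_min_maf": float,
    "report.alpha": float,
}

DEFAULTS: dict[str, object] = {
    "prior.m": 1000.0,
    "prior.a": 1.0,
    "prior.b": 1.0,
    "gibbs.n_iter": 2000,
    "gibbs.burn_in": 500,
    "gibbs.thin": 1,
    "perm.J": 1000,
    "perm.estimator": "posterior_mean",
    "design.center": True,
    "report.alpha": 0.05,
}


def load_config(path) -> dict:
    """Load and validate a flat YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return _validate(raw, origin=str(path))


def _validate(cfg: dict, origin: str = "config") -> dict:
    out = {}
    for key, value in cfg.items():
        if key not in KNOWN_KEYS:
            raise KeyError(f"{origin}: unknown configuration key {key!r} "
                           f"(namespaces: prior, gibbs, perm, design, svd, sim, report)")
        typ = KNOWN_KEYS[key]
        out[key] = typ(value) if not isinstance(value, typ) else value
    return out


def merge_config(file_cfg: dict | None = None, **overrides) -> dict:
    """DEFAULTS <- file <- explicit overrides (None overrides ignored)."""
    cfg = dict(DEFAULTS)
    cfg.update(file_cfg or {})
    cfg.update(_validate({k: v for k, v in overrides.items() if v is not None},
                         origin="override"))
    return cfg


def spawn_seeds(seed: int, n: int = 3) -> list[int]:
    """Expand one global seed into independent per-component seeds
    (Gibbs, permutation, simulation streams never share state, so e.g.
    changing J cannot perturb the Gibbs chain)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]
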