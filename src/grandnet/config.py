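"""Model configuration: YAML/JSON files -> ensemble model objects.

Unknown keys are rejected (misspelled options should fail loudly, not be
silently ignored).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .degree_ensemble import DegreeEnsembleModel
from .latent_ensemble import LatentEnsembleModel
from .priors import (
    DegreePrior,
    LatentPrior,
    SizePrior,
    build_degree_prior,
    build_latent_prior,
    build_size_prior,
    exponential_degree_prior,
    exponential_latent_prior,
    power_law_degree_prior,
)


class ConfigError(ValueError):
    """Invalid configuration file."""


_TOP_KEYS = {"ensemble", "size_prior", "degree_prior", "latent_prior", "seed", "convention"}
_SIZE_KEYS = {"family", "params", "N0", "Nmax", "tail_eps"}
_DEGREE_KEYS = {"family", "params", "m_hat", "K"}
_LATENT_KEYS = {"family", "params", "grid", "probs"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {', '.join(unknown)}")


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "config")
    return cfg


def size_prior_from_config(section: dict) -> SizePrior:
    _check_keys(section, _SIZE_KEYS, "size_prior")
    kwargs = {}
    if "Nmax" in section:
        kwargs["Nmax"] = int(section["Nmax"])
    if "tail_eps" in section:
        kwargs["tail_eps"] = float(section["tail_eps"])
    return build_size_prior(
        section["family"],
        section.get("params", {}),
        N0=int(section.get("N0", 1)),
        **kwargs,
    )


def degree_prior_from_config(section: dict) -> DegreePrior:
    _check_keys(section, _DEGREE_KEYS, "degree_prior")
    family = section.get("family", "table")
    params = dict(section.get("params", {}))
    m_hat = int(section.get("m_hat", 0))
    K = section.get("K")
    if family == "exponential":
        return exponential_degree_prior(float(params["m"]), m_hat, int(K if K is not None else 16))
    if family == "power_law":
        return power_law_degree_prior(
            float(params["gamma"]),
            float(params.get("shift", 3.0)),
            m_hat,
            int(K if K is not None else 16),
        )
    if family == "table":
        return build_degree_prior(params["probs"], m_hat, None if K is None else int(K))
    raise ConfigError(f"unknown degree-prior family {family!r}")


def latent_prior_from_config(section: dict) -> LatentPrior:
    _check_keys(section, _LATENT_KEYS, "latent_prior")
    family = section.get("family", "table")
    params = dict(section.get("params", {}))
    if family == "exponential":
        return exponential_latent_prior(
            float(params["m"]),
            float(params.get("theta_max", 30.0)),
            float(params.get("step", 0.25)),
        )
    if family == "table":
        grid = section.get("grid", params.get("grid"))
        probs = section.get("probs", params.get("probs"))
        if grid is None or probs is None:
            raise ConfigError("table latent prior needs 'grid' and 'probs'")
        return build_latent_prior(np.asarray(grid, dtype=float), np.asarray(probs, dtype=float))
    raise ConfigError(f"unknown latent-prior family {family!r}")


def model_from_config(cfg: dict):
    """Build the ensemble model named by cfg['ensemble'] ('degree' or 'latent')."""
    kind = cfg.get("ensemble")
    size_prior = size_prior_from_config(cfg.get("size_prior", {}))
    if kind == "degree":
        model = DegreeEnsembleModel(
            size_prior=size_prior,
            degree_prior=degree_prior_from_config(cfg.get("degree_prior", {})),
            double_factorial_convention=cfg.get("convention", "matching"),
        )
    elif kind == "latent":
        model = LatentEnsembleModel(
            size_prior=size_prior,
            latent_prior=latent_prior_from_config(cfg.get("latent_prior", {})),
        )
    else:
        raise ConfigError(f"config 'ensemble' must be 'degree' or 'latent', got {kind!r}")
    return model


def config_hash(cfg: dict) -> str:
    """Stable content hash of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
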