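"""Configuration, serialization and run manifests.

Configs are plain YAML/JSON mappings with explicit keys; every
stochastic entry point requires an explicit seed.  Loading and dumping
round-trip exactly.  All tabular artifacts are UTF-8 CSV with a header
row; manifests are JSON carrying the config hash, seed and package
version so any artifact can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .dynamics import ModelParams
from .mating import MatingParams

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "params_from_config",
    "params_to_config",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file is malformed or incomplete."""


_MATING_KEYS = {"w_photo", "light_hours", "light_dark_propensity"}
_MODEL_KEYS = {
    "mating",
    "brood_size",
    "female_fecundity",
    "cross_fecundity",
    "sample_size",
    "n_runs",
    "max_generations",
    "n_males",
    "n_females",
    "exact_pool",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON — YAML superset) config mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def dump_config(data: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def params_from_config(cfg: dict[str, Any]) -> ModelParams:
    """Build :class:`ModelParams` from a config mapping.

    The mapping must contain a ``mating`` block with at least
    ``w_photo``; everything else is optional with model defaults.
    Unknown keys are rejected with their paths.
    """
    _check_keys(cfg, _MODEL_KEYS, "model block")
    mating_blk = cfg.get("mating")
    if not isinstance(mating_blk, dict):
        raise ConfigError("config requires a 'mating' mapping")
    _check_keys(mating_blk, _MATING_KEYS, "mating block")
    if "w_photo" not in mating_blk:
        raise ConfigError("mating.w_photo is required (no default exists)")
    try:
        mp_kwargs = dict(mating_blk)
        if "light_dark_propensity" in mp_kwargs:
            mp_kwargs["light_dark_propensity"] = tuple(
                mp_kwargs["light_dark_propensity"]
            )
        mating = MatingParams(**mp_kwargs)
        kwargs = {k: v for k, v in cfg.items() if k != "mating"}
        if "female_fecundity" in kwargs:
            kwargs["female_fecundity"] = tuple(kwargs["female_fecundity"])
        if kwargs.get("cross_fecundity") is not None:
            kwargs["cross_fecundity"] = tuple(
                tuple(row) for row in kwargs["cross_fecundity"]
            )
        return ModelParams(mating=mating, **kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def params_to_config(params: ModelParams) -> dict[str, Any]:
    """Serialize :class:`ModelParams` to a round-trippable mapping."""
    out: dict[str, Any] = {
        "mating": {
            "w_photo": params.mating.w_photo,
            "light_hours": params.mating.light_hours,
            "light_dark_propensity": list(params.mating.light_dark_propensity),
        },
        "brood_size": params.brood_size,
        "female_fecundity": list(params.female_fecundity),
        "sample_size": params.sample_size,
        "n_runs": params.n_runs,
        "max_generations": params.max_generations,
        "n_males": params.n_males,
        "n_females": params.n_females,
        "exact_pool": params.exact_pool,
    }
    if params.cross_fecundity is not None:
        out["cross_fecundity"] = [list(r) for r in params.cross_fecundity]
    return out


def config_hash(data: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    path: str | Path, config: dict[str, Any], seed: int | None
) -> dict[str, Any]:
    """Write a JSON run manifest sufficient to reproduce the artifacts."""
    from . import __version__

    manifest = {
        "package": "saacage",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
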