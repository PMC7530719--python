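"""Run configuration: schema-validated, default-filled, provenance-stamped.

A :class:`RunConfig` is a namespaced mapping of module parameters.  Unknown
keys are rejected (listing the offenders), every stochastic stage carries
an explicit seed, and the config round-trips losslessly through YAML.  A
provenance block (package version, timestamp, config hash) is attached to
outputs so every table can be traced to the exact configuration that
produced it.
"""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass, field

import yaml

from . import __version__

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    pass


# section -> {key: default}
_SCHEMA: dict[str, dict] = {
    "seed": 0,
    "sidd": {
        "sigma": -0.06,
        "a": 10.84,
        "b_AT": 0.255,
        "b_GC": 1.301,
        "C": 2.5,
        "K_coeff": 2200.0,
        "h": 10.4,
        "T": 310.0,
        "theta": 12.0,
        "max_runs": 2,
        "p_threshold": 0.5,
    },
    "segmentation": {
        "smooth_sigma": 2.0,
        "min_area": 50,
        "watershed_split": True,
        "watershed_min_distance": 10,
        "clear_border": True,
        "background_policy": "mode",
    },
    "distributions": {
        "q": 0.99,
        "alpha": 0.01,
        "n_restarts": 50,
        "k_max": 3,
        "d_min": 1.0,
    },
    "seqquant": {
        "top_n": 50,
        "subset": 10,
        "pseudocount": 0.5,
        "fc_min": 5.0,
    },
    "simulate": {
        "n_cells": 2000,
        "n_genes": 2000,
        "n_spikeins": 60,
        "amplification": 2.0,
        "dispersion": 0.05,
        "low_dose": 1.0,
        "high_dose": 4.0,
    },
}


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def section(self, name: str) -> dict:
        return self.data[name]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "package": "mycsetpoint",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "config_hash": self.config_hash(),
        }


def _defaults() -> dict:
    out = {}
    for key, val in _SCHEMA.items():
        out[key] = dict(val) if isinstance(val, dict) else val
    return out


def _validate(user: dict) -> list[str]:
    bad = []
    for key, val in user.items():
        if key not in _SCHEMA:
            bad.append(key)
        elif isinstance(_SCHEMA[key], dict):
            if not isinstance(val, dict):
                bad.append(key)
            else:
                bad.extend(f"{key}.{k}" for k in val if k not in _SCHEMA[key])
    return bad


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config, validate against the schema, fill defaults.

    An empty or absent file yields all defaults.  Unknown keys raise
    :class:`ConfigError` naming every offender.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        user = loaded or {}
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                user.setdefault(k, {}).update(v)
            else:
                user[k] = v
    bad = _validate(user)
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(bad))}")
    cfg = _defaults()
    for key, val in user.items():
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return RunConfig(data=cfg)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.data, fh, sort_keys=True)
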