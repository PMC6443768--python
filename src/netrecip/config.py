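"""Flat key/value experiment configuration.

A config document is a flat mapping (``key: value`` per line, YAML-flat
syntax) describing one experiment: model parameters, network spec, initial
placement and run/sweep settings.  Unknown keys and out-of-range values are
rejected fail-fast; derived quantities (delta_d, d_min, mean abstention
length) are echoed to the log on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engagement import mean_abstention_length
from .networks import LATTICE_KINDS, RANDOM_MODELS
from .params import ModelParams

__all__ = ["ExperimentConfig", "load_config"]

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = {"r", "delta", "h", "network", "n"}
_OPTIONAL_KEYS = {
    "d",
    "seed",
    "mean_degree",
    "transitivity",
    "scheme",
    "count_c",
    "initial_fraction",
    "max_rounds",
    "replicates",
    "r_grid",
    "out_dir",
}
_SCHEMES = ("random", "degree_rank", "connected_pairs", "single")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description (parameters + network + run spec)."""

    params: ModelParams
    network: str
    n: int
    seed: int = 0
    mean_degree: int | None = None
    transitivity: float | None = None
    scheme: str = "random"
    count_c: int | None = None
    initial_fraction: float = 0.01
    max_rounds: int = 10_000
    replicates: int = 20
    r_grid: tuple = ()
    out_dir: str = "results"

    def network_spec(self) -> dict:
        if self.network in LATTICE_KINDS:
            return {"kind": self.network, "n": self.n}
        return {
            "model": self.network,
            "n": self.n,
            "mean_degree": self.mean_degree,
            "transitivity": self.transitivity,
        }


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a flat key/value config file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value document")
    for key, value in raw.items():
        if isinstance(value, dict):
            raise ValueError(f"{path}: nested key {key!r} not allowed (flat config)")
    unknown = set(raw) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")

    params = ModelParams(
        r=float(raw["r"]),
        delta=float(raw["delta"]),
        d=float(raw.get("d", 0.0)),
        h=int(raw["h"]),
    )
    network = str(raw["network"])
    if network not in LATTICE_KINDS + RANDOM_MODELS:
        raise ValueError(f"{path}: unknown network {network!r}")
    scheme = str(raw.get("scheme", "random"))
    if scheme not in _SCHEMES:
        raise ValueError(f"{path}: unknown placement scheme {scheme!r}")
    r_grid = tuple(float(x) for x in raw.get("r_grid", ()))
    if r_grid and sorted(r_grid) != list(r_grid):
        raise ValueError(f"{path}: r_grid must be increasing")

    cfg = ExperimentConfig(
        params=params,
        network=network,
        n=int(raw["n"]),
        seed=int(raw.get("seed", 0)),
        mean_degree=int(raw["mean_degree"]) if "mean_degree" in raw else None,
        transitivity=float(raw["transitivity"]) if "transitivity" in raw else None,
        scheme=scheme,
        count_c=int(raw["count_c"]) if "count_c" in raw else None,
        initial_fraction=float(raw.get("initial_fraction", 0.01)),
        max_rounds=int(raw.get("max_rounds", 10_000)),
        replicates=int(raw.get("replicates", 20)),
        r_grid=r_grid,
        out_dir=str(raw.get("out_dir", "results")),
    )
    logger.info(
        "config %s: delta_d=%.6g, d_min=%.6g, mean abstention length <a>=%.4g",
        path,
        params.delta_d,
        params.d_min,
        mean_abstention_length(params.delta_d),
    )
    return cfg
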