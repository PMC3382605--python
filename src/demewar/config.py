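"""Configuration files, CLI overrides, and deterministic test fixtures.

The config schema is a flat YAML/JSON mapping mirroring the model
parameter names, with ``payoffs`` and ``topology`` as nested mappings
and an explicit ``schema_version`` key.  CLI flags override file
values.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .model import (
    ModelParams,
    PayoffMatrix,
    PopulationState,
    TopologyKind,
    TopologySpec,
    validate_params,
)

__all__ = ["SCHEMA_VERSION", "load_config", "params_to_dict", "make_fixture"]

SCHEMA_VERSION = 1

_SCALAR_KEYS = {
    "N": int,
    "D": int,
    "m": float,
    "E": float,
    "w": float,
    "init_coop_frac": float,
    "init_fitness": float,
    "leftover_decay": bool,
    "resample_isolated": bool,
    "max_generations": int,
    "stationarity_window": int,
    "stationarity_tol": float,
    "seed": int,
}
_PAYOFF_KEYS = {"T", "R", "P", "S"}
_TOPOLOGY_KEYS = {"kind", "mean_degree", "edge_list_path"}


def _check_keys(given, allowed, where: str) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {where} key(s): {', '.join(sorted(unknown))}")


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> ModelParams:
    """Build validated params from a YAML/JSON file plus overrides.

    ``overrides`` uses the same flat keys as the file (payoff and
    topology fields may be given flat, e.g. ``{"T": 1.6}`` or
    ``{"kind": "island"}``) and wins over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = dict(loaded)
    data.pop("schema_version", None)
    _check_keys(data, set(_SCALAR_KEYS) | {"payoffs", "topology"}, "config")

    payoffs = dict(data.pop("payoffs", {}) or {})
    _check_keys(payoffs, _PAYOFF_KEYS, "payoffs")
    topology = dict(data.pop("topology", {}) or {})
    _check_keys(topology, _TOPOLOGY_KEYS, "topology")

    overrides = dict(overrides or {})
    for k in list(overrides):
        if overrides[k] is None:
            del overrides[k]
        elif k in _PAYOFF_KEYS:
            payoffs[k] = overrides.pop(k)
        elif k in _TOPOLOGY_KEYS:
            topology[k] = overrides.pop(k)
    _check_keys(overrides, _SCALAR_KEYS, "override")
    data.update(overrides)

    kwargs: dict[str, Any] = {}
    for key, caster in _SCALAR_KEYS.items():
        if key in data:
            kwargs[key] = caster(data[key])
    if payoffs:
        kwargs["payoffs"] = PayoffMatrix(**{k: float(v) for k, v in payoffs.items()})
    if topology:
        if "kind" in topology:
            topology["kind"] = TopologyKind(topology["kind"])
        if "mean_degree" in topology:
            topology["mean_degree"] = float(topology["mean_degree"])
        kwargs["topology"] = TopologySpec(**topology)
    return validate_params(ModelParams(**kwargs))


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    """Flatten params to the config schema (round-trips through load_config)."""
    d: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    for key in _SCALAR_KEYS:
        d[key] = getattr(params, key)
    d["payoffs"] = {
        "T": params.payoffs.T,
        "R": params.payoffs.R,
        "P": params.payoffs.P,
        "S": params.payoffs.S,
    }
    d["topology"] = {
        "kind": params.topology.kind.value,
        "mean_degree": params.topology.mean_degree,
        "edge_list_path": params.topology.edge_list_path,
    }
    return d


_FIXTURE_KINDS = ("ALL_C", "ALL_D", "HALF_HALF", "ONE_EMPTY_DEME", "SINGLE_DEFECTOR")


def make_fixture(
    kind: str,
    D: int = 3,
    N0: int = 4,
    rng: np.random.Generator | None = None,
    fitness: float = 0.0,
) -> PopulationState:
    """Small deterministic population states for tests.

    Kinds: ALL_C, ALL_D, HALF_HALF (first half of each deme cooperates),
    ONE_EMPTY_DEME (deme 1 empty, others full of cooperators),
    SINGLE_DEFECTOR (one defector at a random position, cooperators
    elsewhere; needs ``rng``).
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}")
    strategies = [np.ones(N0, dtype=np.int8) for _ in range(D)]
    if kind == "ALL_D":
        strategies = [np.zeros(N0, dtype=np.int8) for _ in range(D)]
    elif kind == "HALF_HALF":
        for s in strategies:
            s[N0 // 2 :] = 0
    elif kind == "ONE_EMPTY_DEME":
        strategies[1] = np.empty(0, dtype=np.int8)
    elif kind == "SINGLE_DEFECTOR":
        if rng is None:
            raise ValueError("SINGLE_DEFECTOR needs an rng")
        flat = int(rng.integers(D * N0))
        strategies[flat // N0][flat % N0] = 0
    fit = [np.full(len(s), fitness, dtype=np.float64) for s in strategies]
    return PopulationState(generation=0, strategies=strategies, fitness=fit)


def write_manifest(params: ModelParams, path: str | Path, **extra) -> None:
    """Write a JSON run manifest with every parameter field."""
    payload = {"params": params_to_dict(params), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
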