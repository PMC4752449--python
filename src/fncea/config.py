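"""Parameter-file loading, validation and serialization.

The parameter file is a YAML document with three sections: ``parameters``
(flat keys named exactly as the :class:`~fncea.model_core.ParameterSet`
fields), ``psa`` (per-parameter sampling descriptors) and ``strategies``
(prophylaxis schedule records).  A packaged default file carries the model's
published inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import yaml

from .model_core import ParameterSet, StrategySpec
from .psa import (
    BetaDist,
    Distribution,
    FixedValue,
    GammaDist,
    LogNormalDist,
    PSADistributionSet,
)


class ConfigError(ValueError):
    """A parameter file is missing keys, out of range, or malformed."""


def default_parameters_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("fncea.data") / "default_parameters.yaml")


def _parse_distribution(name: str, node: Any) -> tuple[Distribution, bool]:
    if not isinstance(node, dict) or "dist" not in node:
        raise ConfigError(f"psa entry {name!r} must be a mapping with a 'dist' key")
    spec = dict(node)
    family = spec.pop("dist")
    cumulative = bool(spec.pop("cumulative", False))
    try:
        if family == "gamma":
            return GammaDist(shape=float(spec.pop("shape")), rate=float(spec.pop("rate"))), cumulative
        if family == "beta":
            return BetaDist(alpha=float(spec.pop("alpha")), beta=float(spec.pop("beta"))), cumulative
        if family == "lognormal":
            return LogNormalDist(mu=float(spec.pop("mu")), sigma=float(spec.pop("sigma"))), cumulative
        if family == "fixed":
            return FixedValue(value=float(spec.pop("value"))), cumulative
    except KeyError as exc:
        raise ConfigError(f"psa entry {name!r} is missing field {exc.args[0]!r}") from exc
    except ValueError as exc:
        raise ConfigError(f"psa entry {name!r}: {exc}") from exc
    raise ConfigError(f"psa entry {name!r} has unknown distribution family {family!r}")


def load_parameters(
    path: str | Path | None = None,
) -> tuple[ParameterSet, PSADistributionSet, list[StrategySpec]]:
    """Load and validate a parameter file (the packaged default when
    ``path`` is None).  Errors name the offending key."""
    path = Path(path) if path is not None else default_parameters_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: document root must be a mapping")

    raw_params = doc.get("parameters")
    if not isinstance(raw_params, dict):
        raise ConfigError(f"{path}: missing 'parameters' section")
    field_names = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(raw_params) - field_names
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    missing = field_names - set(raw_params)
    if missing:
        raise ConfigError(f"missing parameter keys: {sorted(missing)}")
    try:
        params = ParameterSet(**raw_params)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc

    raw_psa = doc.get("psa", {}) or {}
    dists: dict[str, Distribution] = {}
    cumulative: set[str] = set()
    for name, node in raw_psa.items():
        if name not in field_names:
            raise ConfigError(f"psa entry {name!r} is not a model parameter")
        dist, cum = _parse_distribution(name, node)
        dists[name] = dist
        if cum:
            cumulative.add(name)
    try:
        psa = PSADistributionSet(distributions=dists, cumulative_risk_fields=frozenset(cumulative))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    raw_strategies = doc.get("strategies", []) or []
    strategies: list[StrategySpec] = []
    for node in raw_strategies:
        if not isinstance(node, dict) or "id" not in node:
            raise ConfigError("each strategy record needs at least an 'id' key")
        try:
            strategies.append(
                StrategySpec(
                    id=str(node["id"]),
                    agent=str(node.get("agent", "none")),
                    pp_cycles=frozenset(node.get("pp_cycles", []) or []),
                    sp_enabled=bool(node.get("sp_enabled", False)),
                    label=node.get("label"),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"strategy {node.get('id')!r}: {exc}") from exc
    ids = [s.id for s in strategies]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate strategy ids in parameter file")
    return params, psa, strategies


def _dist_to_node(dist: Distribution, cumulative: bool) -> dict[str, Any]:
    if isinstance(dist, GammaDist):
        node: dict[str, Any] = {"dist": "gamma", "shape": dist.shape, "rate": dist.rate}
    elif isinstance(dist, BetaDist):
        node = {"dist": "beta", "alpha": dist.alpha, "beta": dist.beta}
    elif isinstance(dist, LogNormalDist):
        node = {"dist": "lognormal", "mu": dist.mu, "sigma": dist.sigma}
    elif isinstance(dist, FixedValue):
        node = {"dist": "fixed", "value": dist.value}
    else:  # pragma: no cover - exhaustive over Distribution
        raise TypeError(f"unknown distribution type {type(dist)!r}")
    if cumulative:
        node["cumulative"] = True
    return node


def save_parameters(
    path: str | Path,
    params: ParameterSet,
    psa: PSADistributionSet,
    strategies: Sequence[StrategySpec],
) -> None:
    """Serialize a configuration so that ``load_parameters`` round-trips."""
    doc = {
        "parameters": dataclasses.asdict(params),
        "psa": {
            name: _dist_to_node(dist, name in psa.cumulative_risk_fields)
            for name, dist in psa.distributions.items()
        },
        "strategies": [
            {
                "id": s.id,
                "agent": s.agent,
                "pp_cycles": sorted(s.pp_cycles),
                "sp_enabled": s.sp_enabled,
                "label": s.label,
            }
            for s in strategies
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
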