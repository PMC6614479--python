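"""Run configuration: loading, validation and serialization (YAML).

A run configuration has five blocks — ``fixed`` biochemical constants,
``cost`` parameters, ``mutable`` parameter ranges, ``kernel`` and ``solver``
controls, and the ``experiment`` block (fitness fractions, set counts,
mutation counts, seed).  Loading materializes every default so a saved copy
is self-describing and round-trips losslessly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .dfe import MutationKernelConfig
from .model import SolverConfig
from .params import CostParams, InvalidParamsError, LacParams, MUTABLE_FIELDS, ParameterBounds

__all__ = [
    "ExperimentConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config",
]

_FIXED_FIELDS = ("kd1", "kd2", "kd3", "K", "k1", "k2", "k3", "k4", "lac_out")


class ConfigError(ValueError):
    """Raised on parse or validation failure, naming the offending field."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale of the replicated study."""

    fractions: tuple[float, ...] = (0.001, 0.1, 0.5)
    count: int = 100
    target_tolerance: float = 0.01
    n_mutations: int = 10000
    n_backgrounds: int = 4000
    neutral_epsilon: float = 0.0
    fmax_starts: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ConfigError("experiment.fractions must be non-empty")
        for f in self.fractions:
            if not 0.0 < f <= 1.0:
                raise ConfigError(f"experiment.fractions entries must be in (0,1], got {f}")
        for name in ("count", "n_mutations", "n_backgrounds", "fmax_starts"):
            if getattr(self, name) < 1:
                raise ConfigError(f"experiment.{name} must be >= 1")
        if self.target_tolerance <= 0:
            raise ConfigError("experiment.target_tolerance must be positive")
        if self.neutral_epsilon < 0:
            raise ConfigError("experiment.neutral_epsilon must be nonnegative")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full study."""

    template: LacParams          # fixed constants + placeholder mutables
    bounds: ParameterBounds
    cost: CostParams
    kernel: MutationKernelConfig
    solver: SolverConfig
    experiment: ExperimentConfig

    def to_mapping(self) -> dict:
        return {
            "fixed": {n: getattr(self.template, n) for n in _FIXED_FIELDS},
            "cost": dataclasses.asdict(self.cost),
            "mutable": self.bounds.to_mapping(),
            "kernel": {
                "cv": self.kernel.cv,
                "out_of_range_policy": self.kernel.out_of_range_policy,
                "distribution": self.kernel.distribution,
                "max_resample": self.kernel.max_resample,
            },
            "solver": {
                "rtol": self.solver.rtol,
                "max_newton": self.solver.max_newton,
                "fallback_horizon": self.solver.fallback_horizon,
                "use_fallback": self.solver.use_fallback,
            },
            "experiment": {
                **dataclasses.asdict(self.experiment),
                "fractions": list(self.experiment.fractions),
            },
        }

    def config_hash(self) -> str:
        """Stable sha256 of the canonical YAML serialization (12 hex chars)."""
        text = yaml.safe_dump(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _build(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    for block in ("fixed", "mutable"):
        if block not in raw:
            raise ConfigError(f"missing configuration block: {block!r}")
    fixed = dict(raw["fixed"])
    unknown = set(fixed) - set(_FIXED_FIELDS)
    if unknown:
        raise ConfigError(f"unknown fixed parameters: {sorted(unknown)}")
    missing = set(_FIXED_FIELDS) - set(fixed)
    if missing:
        raise ConfigError(f"missing fixed parameters: {sorted(missing)}")

    try:
        bounds = ParameterBounds.from_mapping(raw["mutable"])
    except InvalidParamsError as exc:
        raise ConfigError(f"mutable ranges: {exc}") from exc

    # template carries the fixed block; mutables start at the lower bounds
    try:
        template = LacParams(
            **{n: float(fixed[n]) for n in _FIXED_FIELDS},
            **{n: lo for n, (lo, _hi) in bounds},
        )
    except InvalidParamsError as exc:
        raise ConfigError(f"fixed parameters: {exc}") from exc

    try:
        cost = CostParams(**{k: float(v) for k, v in raw.get("cost", {}).items()})
    except (TypeError, InvalidParamsError) as exc:
        raise ConfigError(f"cost parameters: {exc}") from exc

    try:
        kernel = MutationKernelConfig(**raw.get("kernel", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"kernel: {exc}") from exc

    try:
        solver = SolverConfig(**raw.get("solver", {}))
    except TypeError as exc:
        raise ConfigError(f"solver: {exc}") from exc
    if solver.rtol <= 0:
        raise ConfigError("solver.rtol must be positive")

    exp_raw = dict(raw.get("experiment", {}))
    if "fractions" in exp_raw:
        exp_raw["fractions"] = tuple(float(f) for f in exp_raw["fractions"])
    try:
        experiment = ExperimentConfig(**exp_raw)
    except TypeError as exc:
        raise ConfigError(f"experiment: {exc}") from exc

    return RunConfig(
        template=template,
        bounds=bounds,
        cost=cost,
        kernel=kernel,
        solver=solver,
        experiment=experiment,
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    With ``path=None`` the packaged default configuration is used.
    """
    if path is None:
        text = (
            importlib.resources.files("lacdfe")
            .joinpath("data/default_config.yaml")
            .read_text()
        )
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"configuration file not found: {p}")
        text = p.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"YAML parse error: {exc}") from exc
    return _build(raw)


def default_config() -> RunConfig:
    return load_config(None)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a fully materialized configuration (lossless round-trip)."""
    Path(path).write_text(yaml.safe_dump(config.to_mapping(), sort_keys=True))
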