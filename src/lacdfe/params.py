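"""Parameterization of the lac-operon model.

The model distinguishes five *mutable* regulatory parameters — the quantities
the mutational framework is allowed to perturb — from the fixed biochemical
constants of the proteins and the environment.  All quantities are expressed
in one consistent (arbitrary) unit system; the packaged defaults use nM for
concentrations and minutes for time.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterator, Mapping

#: Names of the five regulatory parameters subject to mutation, in canonical
#: order (p1..p5 of the epistasis protocol).
MUTABLE_FIELDS: tuple[str, ...] = ("bas1", "bas2", "Ky", "Kmy", "Kt")


class InvalidParamsError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class LacParams:
    """Full numeric parameterization of the lac-operon ODE system.

    Mutable regulatory parameters
    -----------------------------
    bas1 : basal activity of the lac promoter (conc/time)
    bas2 : basal activity of the lacI promoter (conc/time)
    Ky   : numerator of the maximal promoter activity, K^y (conc^2/time)
    Kmy  : half-saturation constant of promoter activity (conc)
    Kt   : translational capacity of LacY relative to LacZ (dimensionless)

    Fixed biochemical constants
    ---------------------------
    kd1, kd2, kd3 : first-order degradation/dilution rates of LacZ, LacY and
        LacI (1/time)
    K   : half-saturation constant of LacI-lactose binding (conc)
    k1  : maximal lactose influx rate per LacY molecule (1/time)
    k2  : half-saturation constant of influx w.r.t. external lactose (conc)
    k3  : maximal lactose metabolism rate per LacZ molecule (1/time)
    k4  : half-saturation constant of metabolism w.r.t. internal lactose (conc)
    lac_out : external lactose concentration, held constant (conc)
    """

    bas1: float
    bas2: float
    Ky: float
    Kmy: float
    Kt: float
    kd1: float = 0.02
    kd2: float = 0.02
    kd3: float = 0.02
    K: float = 100.0
    k1: float = 60.0
    k2: float = 1.0e5
    k3: float = 60.0
    k4: float = 500.0
    lac_out: float = 1.0e5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParamsError(f"{name} is not finite: {v!r}")
            if v < 0:
                raise InvalidParamsError(f"{name} must be nonnegative, got {v!r}")
        for name in ("kd1", "kd2", "kd3"):
            if getattr(self, name) <= 0:
                raise InvalidParamsError(f"{name} must be strictly positive")

    def mutable_values(self) -> tuple[float, ...]:
        """The five mutable parameters in canonical order."""
        return tuple(getattr(self, n) for n in MUTABLE_FIELDS)

    def replace(self, **changes: float) -> "LacParams":
        return dataclasses.replace(self, **changes)

    def with_mutables(self, values) -> "LacParams":
        """Return a copy with the five mutable parameters set from a vector."""
        if len(values) != len(MUTABLE_FIELDS):
            raise InvalidParamsError(
                f"expected {len(MUTABLE_FIELDS)} mutable values, got {len(values)}"
            )
        return dataclasses.replace(
            self, **{n: float(v) for n, v in zip(MUTABLE_FIELDS, values)}
        )


@dataclass(frozen=True)
class CostParams:
    """Parameters of the protein-production cost term.

    ``cost = alpha * (alpha_z*[LacZ] + alpha_y*[LacY] + alpha_i*[LacI_tot])``

    alpha is the cost per protein molecule per unit time; the per-protein
    factors alpha_z, alpha_y, alpha_i weigh each protein by the expense of
    maintaining its steady-state pool.  When built from protein lengths they
    are the product of the protein's length relative to LacZ and its
    degradation constant, so that the cost is proportional to amino acids
    polymerized per unit time.
    """

    alpha: float = 300.0
    alpha_z: float = 0.02
    alpha_y: float = 0.02 * 417.0 / 1023.0
    alpha_i: float = 0.02 * 360.0 / 1023.0

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_z", "alpha_y", "alpha_i"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParamsError(f"{name} must be finite and nonnegative")

    @classmethod
    def from_protein_lengths(
        cls,
        alpha: float,
        kd1: float,
        kd2: float,
        kd3: float,
        len_z: int = 1023,
        len_y: int = 417,
        len_i: int = 360,
    ) -> "CostParams":
        """Build per-protein cost factors from amino-acid lengths.

        Each factor is (length relative to LacZ) x (degradation constant),
        i.e. the amino-acid synthesis flux needed to hold one unit of that
        protein at steady state, normalized to LacZ's length.
        """
        return cls(
            alpha=alpha,
            alpha_z=kd1 * 1.0,
            alpha_y=kd2 * len_y / len_z,
            alpha_i=kd3 * len_i / len_z,
        )


@dataclass(frozen=True)
class ParameterBounds:
    """[min, max] ranges of the five mutable regulatory parameters."""

    bas1: tuple[float, float] = (0.001, 1.0)
    bas2: tuple[float, float] = (0.01, 20.0)
    Ky: tuple[float, float] = (1.0, 2000.0)
    Kmy: tuple[float, float] = (1.0, 200.0)
    Kt: tuple[float, float] = (0.05, 1.5)

    def __post_init__(self) -> None:
        for name in MUTABLE_FIELDS:
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise InvalidParamsError(f"range of {name} must be finite")
            if lo < 0 or hi < lo:
                raise InvalidParamsError(
                    f"range of {name} must satisfy 0 <= min <= max, got [{lo}, {hi}]"
                )

    def __iter__(self) -> Iterator[tuple[str, tuple[float, float]]]:
        for name in MUTABLE_FIELDS:
            yield name, getattr(self, name)

    def range_of(self, name: str) -> tuple[float, float]:
        if name not in MUTABLE_FIELDS:
            raise KeyError(f"{name!r} is not a mutable parameter")
        return getattr(self, name)

    def lower(self):
        return [getattr(self, n)[0] for n in MUTABLE_FIELDS]

    def upper(self):
        return [getattr(self, n)[1] for n in MUTABLE_FIELDS]

    def contains(self, params: LacParams, *, rtol: float = 1e-12) -> bool:
        """Whether all five mutable parameters of ``params`` are in range."""
        for name in MUTABLE_FIELDS:
            lo, hi = getattr(self, name)
            v = getattr(params, name)
            slack = rtol * max(abs(lo), abs(hi), 1.0)
            if v < lo - slack or v > hi + slack:
                return False
        return True

    def clip(self, name: str, value: float) -> float:
        lo, hi = self.range_of(name)
        return min(max(value, lo), hi)

    @classmethod
    def from_mapping(cls, ranges: Mapping[str, Mapping[str, float]]) -> "ParameterBounds":
        missing = set(MUTABLE_FIELDS) - set(ranges)
        if missing:
            raise InvalidParamsError(f"missing ranges for: {sorted(missing)}")
        kw = {}
        for name in MUTABLE_FIELDS:
            entry = ranges[name]
            try:
                kw[name] = (float(entry["min"]), float(entry["max"]))
            except (KeyError, TypeError) as exc:
                raise InvalidParamsError(
                    f"range of {name} must provide 'min' and 'max'"
                ) from exc
        return cls(**kw)

    def to_mapping(self) -> dict[str, dict[str, float]]:
        return {
            name: {"min": lo, "max": hi} for name, (lo, hi) in self
        }
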