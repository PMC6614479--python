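"""Pairwise epistasis between beneficial regulatory mutations.

Protocol: starting from a low-fitness parameter set P0, a focal beneficial
mutation mu in one parameter gives fitness gain delta_f = f(P0+mu) - f(P0).
The same mutation (identical new value) is then re-applied to many
backgrounds P_M, each carrying one other beneficial mutation in a different
parameter, giving delta_f* = f(P_M+mu) - f(P_M).  The ratio
delta_f/delta_f* measures how the genetic background rescales the focal
mutation's benefit: ratios above one are diminishing returns, below one
synergy, and a sign flip of delta_f* is sign epistasis.

The fitness function is injectable, so an additive toy fitness can serve as
a no-epistasis control (every ratio exactly 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dfe import Mutation, MutationKernelConfig, draw_new_value
from .model import SolverConfig, SteadyStateError, compute_fitness
from .params import MUTABLE_FIELDS, CostParams, LacParams, ParameterBounds

__all__ = [
    "EpistasisRecord",
    "NoBeneficialMutationError",
    "find_beneficial_mutation",
    "epistasis_scan",
    "ratio_vs_background_fitness",
    "diminishing_returns_stat",
    "records_to_frame",
]

FitnessFn = Callable[[LacParams], float]


class NoBeneficialMutationError(RuntimeError):
    """Raised when no fitness-increasing proposal is found within budget."""


@dataclass(frozen=True)
class EpistasisRecord:
    """One focal-mutation / background-mutation pair.

    f0 / f0_star: fitness of P0 without / with the focal mutation.
    fM / fM_star: fitness of the mutated background without / with it.
    ratio is delta_f / delta_f_star, NaN when delta_f_star = 0 (undefined,
    excluded from trend statistics).  The benefit/cost deltas of the focal
    mutation on P0 are carried when the model fitness is used (NaN for an
    injected plain fitness function).
    """

    focal_param: str
    background_param: str
    background_old: float
    background_new: float
    f0: float
    f0_star: float
    fM: float
    fM_star: float
    focal_delta_benefit: float = float("nan")
    focal_delta_cost: float = float("nan")

    @property
    def delta_f(self) -> float:
        return self.f0_star - self.f0

    @property
    def delta_f_star(self) -> float:
        return self.fM_star - self.fM

    @property
    def ratio(self) -> float:
        if self.delta_f_star == 0.0:
            return float("nan")
        return self.delta_f / self.delta_f_star

    @property
    def sign_epistatic(self) -> bool:
        return (self.delta_f > 0) != (self.delta_f_star > 0)


def _model_fitness_fn(
    cost_params: CostParams, solver: SolverConfig | None
) -> FitnessFn:
    cfg = solver or SolverConfig()

    def f(params: LacParams) -> float:
        return compute_fitness(params, cost_params, cfg).fitness

    return f


def find_beneficial_mutation(
    background: LacParams,
    param_id: str,
    kernel: MutationKernelConfig,
    bounds: ParameterBounds,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    *,
    max_draws: int = 500,
    f_background: float | None = None,
) -> Mutation:
    """Search for a kernel proposal in ``param_id`` that increases fitness.

    Draws repeatedly from the mutation kernel and returns the first proposal
    with a positive fitness change; raises
    :class:`NoBeneficialMutationError` when the budget is exhausted (as
    happens near a one-dimensional optimum).
    """
    f0 = fitness_fn(background) if f_background is None else f_background
    old = getattr(background, param_id)
    for _ in range(max_draws):
        new = draw_new_value(param_id, old, bounds, kernel, rng)
        if new == old:
            continue
        try:
            f1 = fitness_fn(background.replace(**{param_id: new}))
        except SteadyStateError:
            continue
        if f1 - f0 > 0:
            return Mutation(param_id, old, new, delta_fitness=f1 - f0)
    raise NoBeneficialMutationError(
        f"no beneficial mutation in {param_id!r} found in {max_draws} draws"
    )


def epistasis_scan(
    P0: LacParams,
    focal: Mutation,
    n_backgrounds: int,
    kernel: MutationKernelConfig,
    bounds: ParameterBounds,
    cost_params: CostParams | None = None,
    solver: SolverConfig | None = None,
    *,
    seed: int | None = None,
    fitness_fn: FitnessFn | None = None,
    max_draws: int = 500,
) -> list[EpistasisRecord]:
    """Re-apply one focal beneficial mutation across mutated backgrounds.

    Backgrounds carry one beneficial mutation in a parameter other than the
    focal one, spread as evenly as possible over the four remaining
    parameters; the focal mutation's new value is re-applied bit-identically
    to each.  A shortfall of beneficial background mutations in some
    parameter shrinks the output rather than raising.  Reproducible given
    ``seed``; pass ``fitness_fn`` to replace the lac-model fitness (e.g. an
    additive control).
    """
    model_based = fitness_fn is None
    if model_based:
        if cost_params is None:
            raise ValueError("cost_params required when using the model fitness")
        fitness_fn = _model_fitness_fn(cost_params, solver)
    rng = np.random.default_rng(seed)

    f0 = fitness_fn(P0)
    P0_star = P0.replace(**{focal.param_id: focal.new_value})
    f0_star = fitness_fn(P0_star)
    if f0_star - f0 <= 0:
        raise ValueError("focal mutation must be beneficial on P0")

    d_ben = d_cost = float("nan")
    if model_based:
        fb0 = compute_fitness(P0, cost_params, solver)
        fb1 = compute_fitness(P0_star, cost_params, solver)
        d_ben = fb1.benefit - fb0.benefit
        d_cost = fb1.cost - fb0.cost

    others = [p for p in MUTABLE_FIELDS if p != focal.param_id]
    per_param = [n_backgrounds // len(others)] * len(others)
    for i in range(n_backgrounds % len(others)):
        per_param[i] += 1

    records: list[EpistasisRecord] = []
    for param, n_this in zip(others, per_param):
        for _ in range(n_this):
            try:
                bg = find_beneficial_mutation(
                    P0, param, kernel, bounds, fitness_fn, rng,
                    max_draws=max_draws, f_background=f0,
                )
            except NoBeneficialMutationError:
                continue
            PM = P0.replace(**{param: bg.new_value})
            fM = f0 + bg.delta_fitness
            PM_star = PM.replace(**{focal.param_id: focal.new_value})
            try:
                fM_star = fitness_fn(PM_star)
            except SteadyStateError:
                continue
            records.append(
                EpistasisRecord(
                    focal_param=focal.param_id,
                    background_param=param,
                    background_old=bg.old_value,
                    background_new=bg.new_value,
                    f0=f0,
                    f0_star=f0_star,
                    fM=fM,
                    fM_star=fM_star,
                    focal_delta_benefit=d_ben,
                    focal_delta_cost=d_cost,
                )
            )
    return records


def records_to_frame(records: Sequence[EpistasisRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "focal_param": r.focal_param,
                "background_param": r.background_param,
                "background_old": r.background_old,
                "background_new": r.background_new,
                "f0": r.f0,
                "f0_star": r.f0_star,
                "fM": r.fM,
                "fM_star": r.fM_star,
                "delta_f": r.delta_f,
                "delta_f_star": r.delta_f_star,
                "ratio": r.ratio,
                "sign_epistatic": r.sign_epistatic,
                "focal_delta_benefit": r.focal_delta_benefit,
                "focal_delta_cost": r.focal_delta_cost,
            }
        )
    return pd.DataFrame(rows)


def ratio_vs_background_fitness(records: Sequence[EpistasisRecord]) -> pd.DataFrame:
    """Records with defined ratios, ordered by background fitness.

    Returns a frame sorted by ``fM`` ascending with a ``rank`` column, the
    sign-epistasis flag per record, and an ``fM_tied`` marker set when every
    background fitness is identical (ordering then reflects input order).
    """
    defined = [r for r in records if math.isfinite(r.ratio)]
    if len(defined) < 2:
        raise ValueError("need at least 2 records with defined ratios")
    df = records_to_frame(defined).sort_values("fM", kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["fM_tied"] = bool(df["fM"].nunique() == 1)
    return df


def diminishing_returns_stat(records: Sequence[EpistasisRecord]):
    """Spearman rank correlation between background fitness and the ratio.

    A significantly positive correlation means the focal mutation's benefit
    shrinks on fitter backgrounds (diminishing returns); negative means it
    grows (synergistic / increasing returns).  Returns (rho, p_value).
    """
    df = ratio_vs_background_fitness(records)
    rho, p = spearmanr(df["fM"], df["ratio"])
    return float(rho), float(p)
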