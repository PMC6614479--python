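"""Fitness-landscape exploration: fmax estimation and same-fitness sampling.

This module is the pipeline's synthetic-input generator.  It estimates the
maximum fitness attainable over the box of mutable regulatory parameters
(``fmax``) by multi-start bounded optimization, and assembles collections of
distinct parameter sets whose fitness equals a requested fraction of fmax —
the backgrounds on which DFEs and epistasis scans are built.

Sampling uses a rejection/refinement hybrid: uniform draws in the box are
adjusted along one randomly chosen coordinate by bracketed root finding
until the fitness hits the target, which yields scattered sets rather than
clustered optimizer output.  Collections record a shortfall flag when fewer
sets than requested are found within the proposal budget; sets at higher
fitness fractions are genuinely sparser in the box.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import qmc

from .model import SolverConfig, SteadyStateError, compute_fitness
from .params import MUTABLE_FIELDS, CostParams, LacParams, ParameterBounds

__all__ = [
    "FitnessTarget",
    "ParameterSetCollection",
    "SamplingError",
    "estimate_fmax",
    "sample_at_fitness",
]


class SamplingError(RuntimeError):
    """Raised when no parameter set at the requested fitness can be found."""


@dataclass(frozen=True)
class FitnessTarget:
    """A requested fitness level, as a fraction of fmax."""

    fraction: float
    tolerance: float = 0.01
    count: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class ParameterSetCollection:
    """Distinct parameter sets annotated with their achieved fitness."""

    sets: list[LacParams]
    fitness: list[float]
    target: FitnessTarget
    fmax_used: float
    shortfall: bool = False
    n_proposals: int = 0
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(zip(self.sets, self.fitness))


def _fitness_of_vector(x, template: LacParams, cost: CostParams, solver: SolverConfig):
    p = template.with_mutables(x)
    return compute_fitness(p, cost, solver).fitness


def estimate_fmax(
    bounds: ParameterBounds,
    template: LacParams,
    cost_params: CostParams,
    solver: SolverConfig | None = None,
    *,
    n_starts: int = 32,
    seed: int | None = None,
) -> float:
    """Largest fitness found over the mutable-parameter box.

    Runs bounded L-BFGS-B from ``n_starts`` Latin-hypercube starting points
    and reports the best value found.  Deterministic given ``seed``.  Fixed
    parameters are taken from ``template``.
    """
    solver = solver or SolverConfig()
    lo = np.array(bounds.lower())
    hi = np.array(bounds.upper())
    span = hi - lo
    if np.all(span == 0):
        return _fitness_of_vector(lo, template, cost_params, solver)

    def neg_fitness(x):
        try:
            return -_fitness_of_vector(np.clip(x, lo, hi), template, cost_params, solver)
        except SteadyStateError:
            return 1e300

    sampler = qmc.LatinHypercube(
        d=len(MUTABLE_FIELDS), seed=np.random.default_rng(seed)
    )
    starts = lo + sampler.random(n=n_starts) * span
    best = -math.inf
    n_fail = 0
    for x0 in starts:
        res = minimize(
            neg_fitness,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200},
        )
        if not math.isfinite(res.fun) or res.fun >= 1e299:
            n_fail += 1
            continue
        best = max(best, -float(res.fun))
    if best == -math.inf:
        raise SteadyStateError(
            f"all {n_fail} optimization starts failed to produce a converged fitness"
        )
    return best


def sample_at_fitness(
    target: FitnessTarget,
    fmax: float,
    bounds: ParameterBounds,
    template: LacParams,
    cost_params: CostParams,
    solver: SolverConfig | None = None,
    *,
    seed: int | None = None,
    max_proposals_per_set: int = 400,
    distinct_rtol: float = 1e-6,
) -> ParameterSetCollection:
    """Collect distinct parameter sets with fitness = fraction x fmax.

    Each proposal is a uniform draw in the box; a randomly ordered sweep over
    the five coordinates looks for one along which the target fitness is
    bracketed between the box edges, and bisects (Brent) along it.  Accepted
    sets must match the target within ``target.tolerance`` (relative) and be
    pairwise distinct (> ``distinct_rtol`` relative difference in at least
    one mutable coordinate).

    Returns fewer than ``target.count`` sets with ``shortfall=True`` when the
    proposal budget is exhausted; raises :class:`SamplingError` when not a
    single set is found.
    """
    solver = solver or SolverConfig()
    f_target = target.fraction * fmax
    if f_target > fmax:
        raise SamplingError(
            f"target fitness {f_target} exceeds fmax {fmax}: unattainable"
        )
    rng = np.random.default_rng(seed)
    lo = np.array(bounds.lower())
    hi = np.array(bounds.upper())
    span = hi - lo

    def fit(x):
        try:
            return _fitness_of_vector(x, template, cost_params, solver)
        except SteadyStateError:
            return math.nan

    accepted: list[np.ndarray] = []
    fitnesses: list[float] = []
    budget = max_proposals_per_set * target.count
    n_prop = 0
    while len(accepted) < target.count and n_prop < budget:
        n_prop += 1
        x = lo + rng.random(len(MUTABLE_FIELDS)) * span
        fx = fit(x)
        if not math.isfinite(fx):
            continue
        for j in rng.permutation(len(MUTABLE_FIELDS)):
            if span[j] == 0:
                continue
            xa, xb = x.copy(), x.copy()
            xa[j], xb[j] = lo[j], hi[j]
            fa, fb = fit(xa), fit(xb)
            if not (math.isfinite(fa) and math.isfinite(fb)):
                continue
            if (fa - f_target) * (fb - f_target) > 0:
                continue

            def g(t, j=j):
                xt = x.copy()
                xt[j] = t
                return fit(xt) - f_target

            try:
                root = brentq(g, lo[j], hi[j], xtol=1e-14 * max(hi[j], 1.0), rtol=1e-15)
            except ValueError:
                continue
            cand = x.copy()
            cand[j] = root
            f_cand = fit(cand)
            scale = abs(f_target) if f_target != 0 else 1.0
            if abs(f_cand - f_target) / scale > target.tolerance:
                continue
            distinct = all(
                np.any(np.abs(cand - prev) > distinct_rtol * np.maximum(np.abs(prev), 1e-300))
                for prev in accepted
            )
            if not distinct:
                continue
            accepted.append(cand)
            fitnesses.append(f_cand)
            break

    if not accepted:
        raise SamplingError(
            f"no parameter set at fitness {f_target} found in {n_prop} proposals"
        )
    return ParameterSetCollection(
        sets=[template.with_mutables(x) for x in accepted],
        fitness=fitnesses,
        target=target,
        fmax_used=fmax,
        shortfall=len(accepted) < target.count,
        n_proposals=n_prop,
        seed=seed,
    )
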