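"""Mutational framework and distributions of fitness effects (DFE).

A mutation perturbs exactly one of the five regulatory parameters, chosen
uniformly at random; the new value is drawn from a normal distribution
centred on the current value with standard deviation cv x value (a
multiplicative kernel, so each parameter is perturbed on its own scale).
Proposals outside the parameter's allowed range are redrawn by default.

Repeating this ~10,000 times on one background and recording the fitness
change of each single mutant yields that background's DFE, which is split
into beneficial and deleterious branches, each fitted by an exponential
density via binned least squares, with a peak count on the deleterious
branch to flag two-peaked shapes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .landscape import ParameterSetCollection
from .model import SolverConfig, SteadyStateError, compute_fitness
from .params import MUTABLE_FIELDS, CostParams, LacParams, ParameterBounds

__all__ = [
    "MutationKernelConfig",
    "Mutation",
    "DFESample",
    "ExpFit",
    "BimodalityReport",
    "mutate",
    "draw_new_value",
    "build_dfe",
    "classify",
    "fit_exponential",
    "detect_bimodality",
    "dfe_experiment",
]


@dataclass(frozen=True)
class MutationKernelConfig:
    """Proposal kernel of the mutational framework.

    cv : standard deviation of the normal proposal as a fraction of the
        current parameter value.  When the current value is exactly zero the
        kernel falls back to an absolute std of cv x (range width).
    out_of_range_policy : 'resample' redraws until the proposal is in range
        (at most ``max_resample`` attempts, then clips); 'clip' clips
        immediately.
    distribution : 'normal' (default) or 'uniform'; the uniform mode draws
        from value +- sqrt(3)*std, matching the normal kernel's variance.
    """

    cv: float = 0.1
    out_of_range_policy: str = "resample"
    mutable_ids: tuple[str, ...] = MUTABLE_FIELDS
    distribution: str = "normal"
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.out_of_range_policy not in ("resample", "clip"):
            raise ValueError("out_of_range_policy must be 'resample' or 'clip'")
        if self.distribution not in ("normal", "uniform"):
            raise ValueError("distribution must be 'normal' or 'uniform'")
        if tuple(self.mutable_ids) != MUTABLE_FIELDS:
            if len(self.mutable_ids) != 5 or set(self.mutable_ids) != set(MUTABLE_FIELDS):
                raise ValueError(
                    f"mutable_ids must be the five fields {MUTABLE_FIELDS}"
                )


@dataclass(frozen=True)
class Mutation:
    """A single-parameter change and (once scored) its fitness effect."""

    param_id: str
    old_value: float
    new_value: float
    delta_fitness: float | None = None


@dataclass
class DFESample:
    """Fitness deltas of n single mutations on one background."""

    background: LacParams
    background_fitness: float
    mutations: list[Mutation]
    neutral_epsilon: float = 0.0
    n_failed: int = 0

    @property
    def deltas(self) -> np.ndarray:
        return np.array([m.delta_fitness for m in self.mutations], dtype=float)

    @property
    def beneficial_effects(self) -> np.ndarray:
        d = self.deltas
        return d[d > self.neutral_epsilon]

    @property
    def deleterious_magnitudes(self) -> np.ndarray:
        d = self.deltas
        return -d[d < -self.neutral_epsilon]


@dataclass(frozen=True)
class ExpFit:
    """Least-squares exponential fit of a binned effect-size density.

    The fitted density is a support-truncated exponential
    ``lam*exp(-lam*(x-lo)) / (1 - exp(-lam*(hi-lo)))`` on the sample range
    [lo, hi]; negative ``lam`` (an increasing density) is admitted, mirroring
    heavy right-shifted samples that a decaying exponential cannot describe.
    """

    lam: float
    r2: float
    n_bins: int
    sign_ok: bool


@dataclass(frozen=True)
class BimodalityReport:
    """Peak count of the smoothed binned distribution of effect magnitudes."""

    n_peaks: int
    peak_locations: tuple[float, ...]


def draw_new_value(
    param_id: str,
    old: float,
    bounds: ParameterBounds,
    kernel: MutationKernelConfig,
    rng: np.random.Generator,
) -> float:
    """Draw an in-range proposal for one parameter from the kernel."""
    lo, hi = bounds.range_of(param_id)
    std = kernel.cv * old if old > 0 else kernel.cv * (hi - lo)
    if std == 0.0:
        return old
    half_width = math.sqrt(3.0) * std  # uniform mode: equal variance

    def draw():
        if kernel.distribution == "normal":
            return rng.normal(old, std)
        return rng.uniform(old - half_width, old + half_width)

    if kernel.out_of_range_policy == "clip":
        return bounds.clip(param_id, draw())
    for _ in range(kernel.max_resample):
        v = draw()
        if lo <= v <= hi:
            return v
    return bounds.clip(param_id, draw())


def mutate(
    background: LacParams,
    bounds: ParameterBounds,
    kernel: MutationKernelConfig,
    rng: np.random.Generator,
) -> Mutation:
    """Perturb one regulatory parameter, chosen uniformly among the five."""
    param_id = kernel.mutable_ids[int(rng.integers(len(kernel.mutable_ids)))]
    old = getattr(background, param_id)
    new = draw_new_value(param_id, old, bounds, kernel, rng)
    return Mutation(param_id=param_id, old_value=old, new_value=new)


def build_dfe(
    background: LacParams,
    n_mutations: int,
    kernel: MutationKernelConfig,
    bounds: ParameterBounds,
    cost_params: CostParams,
    solver: SolverConfig | None = None,
    *,
    seed: int | None = None,
    neutral_epsilon: float = 0.0,
) -> DFESample:
    """Score ``n_mutations`` independent single mutations on one background.

    The background fitness is computed once and reused.  Mutants whose steady
    state fails to converge are excluded and counted in ``n_failed`` rather
    than scored.
    """
    solver = solver or SolverConfig()
    rng = np.random.default_rng(seed)
    f0 = compute_fitness(background, cost_params, solver).fitness
    mutations: list[Mutation] = []
    n_failed = 0
    for _ in range(n_mutations):
        m = mutate(background, bounds, kernel, rng)
        try:
            f1 = compute_fitness(
                background.replace(**{m.param_id: m.new_value}), cost_params, solver
            ).fitness
        except SteadyStateError:
            n_failed += 1
            continue
        mutations.append(
            Mutation(m.param_id, m.old_value, m.new_value, delta_fitness=f1 - f0)
        )
    return DFESample(
        background=background,
        background_fitness=f0,
        mutations=mutations,
        neutral_epsilon=neutral_epsilon,
        n_failed=n_failed,
    )


def classify(sample: DFESample) -> tuple[float, float, float]:
    """(fraction beneficial, fraction deleterious, fraction neutral).

    Beneficial means delta > epsilon, deleterious delta < -epsilon; with the
    default epsilon = 0 the neutral class collects exact zeros only.
    """
    d = sample.deltas
    if d.size == 0:
        raise ValueError("cannot classify an empty sample")
    eps = sample.neutral_epsilon
    n = d.size
    n_ben = int(np.sum(d > eps))
    n_del = int(np.sum(d < -eps))
    return n_ben / n, n_del / n, (n - n_ben - n_del) / n


def _freedman_diaconis_bins(x: np.ndarray, lo_cap: int = 10, hi_cap: int = 60) -> int:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return lo_cap
    h = 2.0 * iqr / x.size ** (1.0 / 3.0)
    span = float(x.max() - x.min())
    if h <= 0 or span <= 0:
        return lo_cap
    return int(np.clip(math.ceil(span / h), lo_cap, hi_cap))


def _trunc_exp_density(x: np.ndarray, lam: float, lo: float, width: float) -> np.ndarray:
    """Exponential density truncated to [lo, lo+width]; lam may be negative."""
    u = lam * width
    if abs(u) < 1e-8:
        # lam -> 0 limit: uniform density, first-order correction in lam
        return (1.0 / width) * (1.0 - lam * (x - lo - width / 2.0))
    if u > 0:
        return lam * np.exp(-lam * (x - lo)) / (1.0 - math.exp(-u))
    # lam < 0: rewrite with m = -lam so all exponents are nonpositive
    m = -lam
    return m * np.exp(m * (x - lo - width)) / (1.0 - math.exp(-m * width))


def fit_exponential(effects, n_bins: int | None = None) -> ExpFit:
    """Fit an exponential density to positive effect magnitudes.

    The sample is binned (Freedman-Diaconis count, bounded to [10, 60]) into
    a density-normalized histogram, and the rate ``lam`` minimizes the
    Euclidean distance between the histogram and the truncated-exponential
    density at the bin centers.  R^2 is 1 - SS_res/SS_tot on the same binned
    representation.  Raises ValueError for fewer than two distinct values.
    """
    x = np.asarray(effects, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two distinct positive values to fit")
    if np.any(x < 0):
        raise ValueError("effect magnitudes must be nonnegative")
    nb = n_bins if n_bins is not None else _freedman_diaconis_bins(x)
    dens, edges = np.histogram(x, bins=nb, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo = float(edges[0])
    width = float(edges[-1] - edges[0])

    def sse(lam):
        model = _trunc_exp_density(centers, lam, lo, width)
        return float(np.sum((dens - model) ** 2))

    lam0 = 1.0 / max(float(np.mean(x)) - lo, 1e-300)
    # coarse scan over both signs, then local refinement
    grid = np.concatenate(
        [lam0 * np.logspace(-2, 2, 41), -lam0 * np.logspace(-2, 2, 41), [0.0]]
    )
    best_lam = min(grid, key=sse)
    span = 10.0 ** 0.5
    lo_b, hi_b = (best_lam / span, best_lam * span) if best_lam > 0 else (
        (best_lam * span, best_lam / span) if best_lam < 0 else (-lam0, lam0)
    )
    res = minimize_scalar(sse, bounds=(min(lo_b, hi_b), max(lo_b, hi_b)), method="bounded",
                          options={"xatol": abs(lam0) * 1e-8})
    lam = float(res.x) if res.fun <= sse(best_lam) else float(best_lam)
    ss_res = sse(lam)
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ExpFit(lam=lam, r2=r2, n_bins=nb, sign_ok=lam > 0)


def detect_bimodality(
    effects,
    *,
    n_bins: int = 40,
    smooth_sigma_bins: float = 1.5,
    prominence_frac: float = 0.05,
) -> BimodalityReport:
    """Count local maxima of the smoothed binned distribution.

    The histogram of effect magnitudes is smoothed with a Gaussian kernel
    (width in bins) and zero-padded so boundary modes count; peaks must
    exceed ``prominence_frac`` of the global maximum in prominence.
    """
    x = np.asarray(effects, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 values for a peak count")
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _props = find_peaks(padded, prominence=prominence_frac * padded.max())
    if peaks.size == 0:
        # degenerate flat/single-bin histogram: report the modal bin
        return BimodalityReport(1, (float(centers[int(np.argmax(smooth))]),))
    locs = tuple(float(centers[i - 1]) for i in peaks)
    return BimodalityReport(n_peaks=len(locs), peak_locations=locs)


def dfe_experiment(
    collections: dict[float, ParameterSetCollection],
    n_mutations: int,
    kernel: MutationKernelConfig,
    bounds: ParameterBounds,
    cost_params: CostParams,
    solver: SolverConfig | None = None,
    *,
    seed: int | None = None,
    neutral_epsilon: float = 0.0,
    min_effects_for_fit: int = 10,
) -> pd.DataFrame:
    """DFE summaries for every (fitness level, parameter set) pair.

    ``collections`` maps a fitness fraction to its sampled parameter sets.
    Returns one row per set: classification fractions, mean beneficial
    effect, exponential-fit lambda and R^2 for both DFE branches, and a
    two-peaked flag for the deleterious branch.  Per-set failures surface as
    NaN columns rather than aborting the run.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for fraction in sorted(collections):
        coll = collections[fraction]
        child_seeds = ss.spawn(len(coll.sets))
        for i, (params, f_bg) in enumerate(coll):
            sample = build_dfe(
                params,
                n_mutations,
                kernel,
                bounds,
                cost_params,
                solver,
                seed=child_seeds[i],
                neutral_epsilon=neutral_epsilon,
            )
            row = {
                "fraction": fraction,
                "set_id": i,
                "background_fitness": sample.background_fitness,
                "n_mutations": len(sample.mutations),
                "n_failed": sample.n_failed,
            }
            try:
                fb, fd, fn = classify(sample)
            except ValueError:
                fb = fd = fn = float("nan")
            row.update(
                frac_beneficial=fb, frac_deleterious=fd, frac_neutral=fn
            )
            ben = sample.beneficial_effects
            dele = sample.deleterious_magnitudes
            row["mean_beneficial_effect"] = (
                float(ben.mean()) if ben.size else float("nan")
            )
            row["mean_deleterious_magnitude"] = (
                float(dele.mean()) if dele.size else float("nan")
            )
            for label, eff in (("ben", ben), ("del", dele)):
                lam = r2 = float("nan")
                if eff.size >= min_effects_for_fit and np.unique(eff).size >= 2:
                    fit = fit_exponential(eff)
                    lam, r2 = fit.lam, fit.r2
                row[f"lam_{label}"] = lam
                row[f"r2_{label}"] = r2
            try:
                row["two_peaked_del"] = detect_bimodality(dele).n_peaks >= 2
            except ValueError:
                row["two_peaked_del"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
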