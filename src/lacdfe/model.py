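"""ODE model of the lac operon and its cost-benefit fitness.

The dynamic state is (LacZ, LacY, lac_in).  Total repressor follows a
decoupled linear equation whose steady state is lacI_tot = bas2/kd3, so
lacI_tot is held at that closed form and free repressor is recomputed from
the lactose-sequestration relation

    lacI_free = lacI_tot / (1 + lac_in/K)

at every right-hand-side evaluation.  Promoter activity is

    P(lac_in) = bas1 + Ky / (Kmy + lacI_free)

and the dynamics read

    d[LacZ]/dt   = P - kd1*[LacZ]
    d[LacY]/dt   = P*Kt - kd2*[LacY]
    d[lac_in]/dt = k1*[LacY]*lac_out/(k2+lac_out)
                   - k3*[LacZ]*[lac_in]/(k4+[lac_in])

Fitness is benefit minus cost, both evaluated at steady state:

    benefit = k3*[LacZ]*[lac_in]/(k4+[lac_in])      (lactose metabolized/time)
    cost    = alpha*(alpha_z*[LacZ] + alpha_y*[LacY] + alpha_i*[lacI_tot])

The steady state is located by a damped Newton iteration on the
three-dimensional right-hand side with an analytic Jacobian, started from a
quasi-steady-state guess, with stiff time integration from (0, 0, 0) as a
fallback.  When the per-enzyme influx capacity exceeds the per-enzyme
metabolic capacity (ratio r >= 1 below) the lactose pool has no finite
steady state and the solver reports non-convergence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import CostParams, InvalidParamsError, LacParams

__all__ = [
    "SolverConfig",
    "SteadyState",
    "FitnessBreakdown",
    "SteadyStateError",
    "rhs",
    "steady_state",
    "compute_benefit",
    "compute_cost",
    "compute_fitness",
]


class SteadyStateError(RuntimeError):
    """Raised when no converged steady state can be produced."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls of the steady-state computation.

    rtol            relative residual tolerance: each component of the rhs
                    must fall below rtol x (magnitude of its flux terms).
    max_newton      Newton iteration budget.
    fallback_horizon  time horizon of the stiff-integration fallback.
    use_fallback    disable to make Newton failures immediately fatal.
    """

    rtol: float = 1e-9
    max_newton: int = 80
    fallback_horizon: float = 1.0e5
    use_fallback: bool = True


DEFAULT_SOLVER = SolverConfig()


@dataclass(frozen=True)
class SteadyState:
    """Steady-state concentrations of all model species."""

    lacZ: float
    lacY: float
    lacI_tot: float
    lacI_free: float
    lac_in: float
    converged: bool


@dataclass(frozen=True)
class FitnessBreakdown:
    """Benefit, cost and net fitness of one parameter set at steady state."""

    benefit: float
    cost: float
    fitness: float


def _influx_coeff(p: LacParams) -> float:
    """Lactose influx per LacY molecule: k1*lac_out/(k2+lac_out)."""
    denom = p.k2 + p.lac_out
    if denom == 0.0:
        return 0.0
    return p.k1 * p.lac_out / denom


def _promoter_activity(lac_in: float, p: LacParams, lacI_tot: float) -> float:
    lacI_free = lacI_tot / (1.0 + lac_in / p.K) if p.K > 0 else (
        lacI_tot if lac_in == 0.0 else 0.0
    )
    denom = p.Kmy + lacI_free
    if denom <= 0.0:
        raise InvalidParamsError(
            "promoter activity denominator Kmy + lacI_free is not positive"
        )
    return p.bas1 + p.Ky / denom


def rhs(state, params: LacParams) -> np.ndarray:
    """Time derivatives of (LacZ, LacY, lac_in).

    ``state`` is any length-3 sequence.  lacI_tot is held at its closed-form
    steady state bas2/kd3 and free repressor recomputed from the current
    lac_in, so the returned vector is the full dynamics of the reduced
    three-species system.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (3,):
        raise ValueError(f"state must have 3 components, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise InvalidParamsError(f"non-finite state: {s!r}")
    z, y, lac = float(s[0]), float(s[1]), float(s[2])
    lacI_tot = params.bas2 / params.kd3
    prod = _promoter_activity(lac, params, lacI_tot)
    influx = _influx_coeff(params) * y
    met = params.k3 * z * lac / (params.k4 + lac) if (params.k4 + lac) != 0 else 0.0
    return np.array(
        [
            prod - params.kd1 * z,
            prod * params.Kt - params.kd2 * y,
            influx - met,
        ]
    )


def _residual_ok(z, y, lac, p, lacI_tot, rtol):
    """Componentwise relative residual test against the flux magnitudes."""
    prod = _promoter_activity(lac, p, lacI_tot)
    a = _influx_coeff(p)
    met = p.k3 * z * lac / (p.k4 + lac)
    f1 = prod - p.kd1 * z
    f2 = prod * p.Kt - p.kd2 * y
    f3 = a * y - met
    s1 = max(prod, p.kd1 * z, 1e-300)
    s2 = max(prod * p.Kt, p.kd2 * y, 1e-300)
    s3 = max(a * y, met, 1e-300)
    return (
        abs(f1) <= rtol * s1 and abs(f2) <= rtol * s2 and abs(f3) <= rtol * s3,
        (f1, f2, f3),
    )


def _newton(z, y, lac, p, lacI_tot, cfg: SolverConfig):
    """Damped Newton iteration on the 3-dim rhs; returns (z, y, lac, ok)."""
    a = _influx_coeff(p)
    K = p.K

    def fvec(z, y, lac):
        prod = _promoter_activity(lac, p, lacI_tot)
        met = p.k3 * z * lac / (p.k4 + lac)
        return (
            prod - p.kd1 * z,
            prod * p.Kt - p.kd2 * y,
            a * y - met,
        )

    def norm(f):
        return abs(f[0]) + abs(f[1]) + abs(f[2])

    f = fvec(z, y, lac)
    for _ in range(cfg.max_newton):
        ok, _res = _residual_ok(z, y, lac, p, lacI_tot, cfg.rtol)
        if ok:
            return z, y, lac, True
        # analytic Jacobian
        if K > 0:
            u = 1.0 + lac / K
            lacI_free = lacI_tot / u
            dI = -lacI_tot / (K * u * u)
        else:
            lacI_free = lacI_tot if lac == 0.0 else 0.0
            dI = 0.0
        denom = p.Kmy + lacI_free
        dP = -p.Ky / (denom * denom) * dI  # dP/dlac_in >= 0
        g = p.k4 + lac
        j11, j13 = -p.kd1, dP
        j22, j23 = -p.kd2, p.Kt * dP
        j31 = -p.k3 * lac / g
        j32 = a
        j33 = -p.k3 * z * p.k4 / (g * g)
        # solve J * d = -f by Cramer's rule (J has zero entries j12, j21)
        det = (
            j11 * (j22 * j33 - j23 * j32)
            - j13 * (j22 * j31)
        )
        if det == 0.0 or not math.isfinite(det):
            return z, y, lac, False
        b1, b2, b3 = -f[0], -f[1], -f[2]
        d1 = (b1 * (j22 * j33 - j23 * j32) + j13 * (j32 * b2 - j22 * b3)) / det
        d2 = (j11 * (b2 * j33 - j23 * b3) + b1 * j23 * j31 - j13 * b2 * j31) / det
        d3 = (j11 * (j22 * b3 - j32 * b2) - b1 * j22 * j31) / det
        # damped step with projection to the nonnegative orthant
        t = 1.0
        base = norm(f)
        improved = False
        for _half in range(30):
            zn = max(z + t * d1, 0.0)
            yn = max(y + t * d2, 0.0)
            ln = max(lac + t * d3, 0.0)
            fn = fvec(zn, yn, ln)
            if norm(fn) < base:
                z, y, lac, f = zn, yn, ln, fn
                improved = True
                break
            t *= 0.5
        if not improved:
            return z, y, lac, False
    ok, _res = _residual_ok(z, y, lac, p, lacI_tot, cfg.rtol)
    return z, y, lac, ok


def steady_state(params: LacParams, config: SolverConfig | None = None) -> SteadyState:
    """Locate the steady state of the three-species system.

    Returns a :class:`SteadyState` whose ``converged`` flag reports whether
    the relative residual tolerance was met.  lacI_tot is always the exact
    closed form bas2/kd3; lacI_free is evaluated at the converged lac_in.
    """
    cfg = config or DEFAULT_SOLVER
    lacI_tot = params.bas2 / params.kd3
    if params.bas1 == 0.0 and params.Ky == 0.0:
        # no expression ever: absorbing zero state (lac_in(0) = 0 convention)
        return SteadyState(0.0, 0.0, lacI_tot, lacI_tot, 0.0, True)

    a = _influx_coeff(params)
    r = a * params.Kt * params.kd1 / (params.kd2 * params.k3) if params.k3 > 0 else math.inf
    if r >= 1.0 and a > 0.0:
        # influx capacity >= metabolic capacity per unit enzyme: the lactose
        # pool grows without bound, no finite steady state exists
        return SteadyState(math.nan, math.nan, lacI_tot, math.nan, math.nan, False)

    # quasi-steady-state initial guess: proteins slaved to promoter activity,
    # lac_in from the flux balance with the protein ratio at its fixed point
    lac0 = r * params.k4 / (1.0 - r) if r < 1.0 else 0.0
    prod0 = _promoter_activity(lac0, params, lacI_tot)
    z0 = prod0 / params.kd1
    y0 = prod0 * params.Kt / params.kd2

    z, y, lac, ok = _newton(z0, y0, lac0, params, lacI_tot, cfg)
    if not ok and cfg.use_fallback:
        z, y, lac, ok = _integrate_fallback(params, lacI_tot, cfg)
    lacI_free = lacI_tot / (1.0 + lac / params.K) if params.K > 0 else (
        lacI_tot if lac == 0.0 else 0.0
    )
    return SteadyState(z, y, lacI_tot, lacI_free, lac, ok)


def _integrate_fallback(params: LacParams, lacI_tot, cfg: SolverConfig):
    """Stiff time integration from (0,0,0), then a Newton polish."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda _t, s: rhs(np.maximum(s, 0.0), params),
        (0.0, cfg.fallback_horizon),
        [0.0, 0.0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    z, y, lac = (max(float(v), 0.0) for v in sol.y[:, -1])
    z, y, lac, ok = _newton(z, y, lac, params, lacI_tot, cfg)
    if not ok:
        ok, _ = _residual_ok(z, y, lac, params, lacI_tot, cfg.rtol)
    return z, y, lac, ok


def compute_benefit(ss: SteadyState, params: LacParams) -> float:
    """Lactose metabolized per unit time: k3*[LacZ]*[lac_in]/(k4+[lac_in])."""
    denom = params.k4 + ss.lac_in
    if denom == 0.0:
        raise InvalidParamsError("degenerate half-saturation: k4 + lac_in = 0")
    if ss.lacZ == 0.0 or ss.lac_in == 0.0:
        return 0.0
    return params.k3 * ss.lacZ * ss.lac_in / denom


def compute_cost(ss: SteadyState, cost_params: CostParams) -> float:
    """Protein-production cost; the LacI term charges the total pool."""
    return cost_params.alpha * (
        cost_params.alpha_z * ss.lacZ
        + cost_params.alpha_y * ss.lacY
        + cost_params.alpha_i * ss.lacI_tot
    )


def compute_fitness(
    params: LacParams,
    cost_params: CostParams,
    config: SolverConfig | None = None,
) -> FitnessBreakdown:
    """Benefit, cost and net fitness at the converged steady state.

    Raises :class:`SteadyStateError` when the steady state does not converge.
    """
    ss = steady_state(params, config)
    if not ss.converged:
        raise SteadyStateError(
            "steady state did not converge for the given parameter set"
        )
    benefit = compute_benefit(ss, params)
    cost = compute_cost(ss, cost_params)
    return FitnessBreakdown(benefit=benefit, cost=cost, fitness=benefit - cost)
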