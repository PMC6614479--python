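# Methods

## Model

The lactose-utilization network is reduced to three dynamic species — the
enzyme LacZ, the permease LacY, and intracellular lactose — plus the
repressor LacI, whose total concentration obeys a decoupled linear balance
`d[LacI_tot]/dt = Bas2 − kd3·[LacI_tot]`.  Because that equation is linear
and independent of the rest of the system, the implementation holds
`[LacI_tot]` at its closed-form steady state `Bas2/kd3` everywhere and
recomputes free repressor from the lactose-sequestration relation
`[LacI] = [LacI_tot]/(1 + [lac_in]/K)` at every right-hand-side
evaluation.  This is exact at steady state, faster than integrating the
extra equation, and leaves a three-dimensional system.

Assumptions inherited by everything downstream:

* the environment is constant (fixed `lac_out`, high enough that the
  system is monostable and induced);
* fitness is read from the deterministic steady state — no stochastic gene
  expression, no transient dynamics;
* mutations act on the five transcription/translation parameters
  (`Bas1, Bas2, K^y, K_m^y, Kt`) only; protein biochemistry (`k1..k4, K`)
  and turnover (`kd1..kd3`) are fixed;
* cost is linear in the protein pools that must be maintained, with the
  total repressor pool (free plus lactose-bound) charged, since every LacI
  molecule has to be produced regardless of its binding state.

## Steady-state geometry and its consequences

At any steady state with nonzero promoter activity
`P = Bas1 + K^y/(K_m^y + [LacI])`, the protein balances give
`[LacZ] = P/kd1` and `[LacY] = P·Kt/kd2`, so the lactose flux balance

    k1·[LacY]·lac_out/(k2+lac_out) = k3·[LacZ]·[lac_in]/(k4+[lac_in])

has `P` on both sides and cancels.  Writing
`A = k1·lac_out/(k2+lac_out)` and `r = A·Kt·kd1/(kd2·k3)`, the steady-state
lactose level is `lac_in* = r·k4/(1−r)`, **independent of four of the five
mutable parameters** — only `Kt` moves it.  For `r ≥ 1` (per-enzyme influx
capacity at or above per-enzyme metabolic capacity) the pool grows without
bound and no finite steady state exists; the default ranges keep `r < 1`
across the whole box, and the solver reports non-convergence if a
configuration crosses the threshold.

Two structural consequences follow, and the pipeline's outputs should be
read with them in mind:

1. **Fitness is monotone in every mutable coordinate.**  Benefit equals
   `A·[LacY]`, so fitness is `C(Kt)·P − α·α_I·Bas2/kd3` with `C` linear in
   `Kt`.  Each coordinate moves fitness in one direction, so the fitness
   maximum over the box (`fmax`) sits at a vertex, not at an interior
   optimum.
2. **Epistasis between beneficial mutations is synergistic.**  The
   repression-relief term `K^y/(K_m^y + [LacI])` is convex in its
   beneficial directions: a beneficial background mutation (lower
   `K_m^y`, lower `Bas2`, higher `Kt`, …) weakly *increases* the gain a
   second beneficial mutation confers, so the ratio Δf/Δf\* is ≤ 1 and
   falls as background fitness rises (negative Spearman correlation in the
   epistasis scan), and beneficial effect sizes scale up, rather than
   peak, as the starting fitness of the background increases.  A model
   variant in which benefit saturates with expression (e.g. an
   enzyme-independent lactose-loss term) would instead show diminishing
   returns; with the equations above, saturation is structurally absent.
   Sign epistasis remains possible only between expression-increasing and
   cost-reducing mutations, i.e. when backgrounds straddle the `C(Kt) = 0`
   boundary, and is correspondingly rare.

## Default parameterization

Concentrations are in nM, time in minutes, fitness in nM lactose
metabolized per minute.  The defaults are a plausibility-driven package
choice (there is no canonical published value set for this reduced model):

| parameter | default | rationale |
|---|---|---|
| `kd1, kd2, kd3` | 0.02 /min | dilution-dominated protein turnover, ~35 min doubling |
| `K` | 100 nM | repressor–lactose binding in the sub-µM range |
| `k1` | 60 /min | transport events per permease per minute |
| `k2` | 1e5 nM | external half-saturation at the 0.1 mM scale |
| `k3` | 60 /min | catalytic turnover per enzyme per minute |
| `k4` | 500 nM | internal half-saturation |
| `lac_out` | 1e5 nM | constant, saturating lactose supply |
| `α` | 300 | scales cost against benefit so that `C(Kt)` changes sign inside the `Kt` range (at `Kt ≈ 0.22`), keeping both benefit-dominated and cost-dominated regimes in the box |
| `α_z, α_y, α_I` | 0.02, 0.00815, 0.00704 | protein length relative to LacZ (1023, 417, 360 aa) × degradation constant |

Mutable ranges: `Bas1 ∈ [0.001, 1]` nM/min (leaky transcription up to
moderate basal expression), `Bas2 ∈ [0.01, 20]` nM/min (repressor pools of
0.5–1000 nM), `K^y ∈ [1, 2000]` nM²/min, `K_m^y ∈ [1, 200]` nM,
`Kt ∈ [0.05, 1.5]` (the upper end keeps `r ≤ 0.75 < 1`).

## Numerical steady state

The primary path is a damped Newton iteration on the three-dimensional
right-hand side with an analytic Jacobian, nonnegativity projection, and
step halving on residual increase.  The initial guess is the
quasi-steady-state point (`lac_in` from the flux-balance closed form,
proteins slaved to the promoter activity there), so the iteration usually
polishes to tolerance in one or two steps.  Convergence requires each
residual component to fall below `rtol = 1e-9` relative to the magnitude of
its production/consumption fluxes.  On Newton failure the solver falls back
to stiff time integration (LSODA) from `(0, 0, 0)` followed by a Newton
polish.  The `r ≥ 1` divergence and the no-expression case
(`Bas1 = K^y = 0`, where the whole nonnegative `lac_in` axis is stationary
and the `lac_in(0) = 0` convention picks the origin) are handled before
iterating.  Agreement between Newton and long-horizon integration is
verified to 1e-6 relative in every species in the test suite.

## Landscape sampling (the synthetic-input generator)

`estimate_fmax` runs bounded L-BFGS-B from 32 Latin-hypercube starts; with
a monotone landscape this reliably reaches the optimal vertex, and a
10,000-point random lower bound is asserted in tests.

`sample_at_fitness` generates the study backgrounds: uniform draws in the
box, then Brent root finding along one randomly chosen coordinate that
brackets the target fitness, accepting sets within 1% relative tolerance of
`fraction × fmax` and pairwise distinct by more than 1e-6 relative in at
least one coordinate.  The default study conditions are 100 sets per level
at fractions 0.001, 0.1 and 0.5 of `fmax`; sets become genuinely sparser at
higher fractions (the sampler reports proposals used and a shortfall flag
rather than silently shrinking).

What the generator emulates: scattered, same-fitness regulatory genotypes
across the whole box.  What it does not emulate: correlated parameter
combinations produced by real mutational processes, measurement noise, or
any population-genetic filtering of the backgrounds — so passing tests
speak to the model's landscape, not to inference from noisy biological
data.

## Mutational kernel and DFE statistics

One of the five parameters is chosen uniformly; the new value is
`Normal(value, cv·value)` with cv = 0.1 by default (a multiplicative kernel
respects the parameters' very different scales; a variance-matched uniform
mode is available).  Out-of-range proposals are redrawn up to 100 times,
then clipped; a parameter sitting at exactly zero uses an absolute width of
cv × range instead.  Mutants whose steady state does not converge are
excluded and counted, not scored.  The neutral threshold defaults to zero:
in this framework almost every parameter change moves fitness, so the
beneficial/deleterious split is essentially exhaustive.

Exponential fits minimize the Euclidean distance between the
density-normalized histogram (Freedman–Diaconis bin count, clamped to
[10, 60]) and a support-truncated exponential density
`λ·e^{−λ(x−lo)}/(1−e^{−λ(hi−lo)})` evaluated at bin centers, via a coarse
signed grid around 1/mean followed by bounded scalar minimization.  The
truncated form admits negative λ — an increasing density — which is the
natural least-squares description of deleterious branches whose mass piles
up at large effects; `sign_ok` records the sign.  R² is computed on the
same binned representation.  On genuinely exponential samples of 1e5 draws
the fit recovers λ to well within 5% (verified for λ = 0.5, 3, 20).

Two-peak detection smooths the histogram (Gaussian, σ = 1.5 bins),
zero-pads so boundary modes count, and counts peaks with prominence above
5% of the maximum.

## Epistasis protocol

From a background P0 at 0.001·fmax, a focal beneficial mutation is found by
repeated kernel draws in one parameter (budgeted; near a one-dimensional
optimum the search correctly fails).  Backgrounds carry one beneficial
mutation in a different parameter, spread evenly over the other four; the
focal new value is re-applied bit-identically to each.  Ratios with
Δf\* = 0 are recorded as undefined and excluded from trend statistics.  The
trend against background fitness is summarized by Spearman rank correlation
rather than strict monotonicity, since backgrounds are stochastic.  The
default scan size is 4,000 backgrounds (1,000 per non-focal parameter);
tests and the summary script use 200 for speed.  An injectable fitness
function allows an additive stub as a no-epistasis control, for which every
ratio must equal 1 to machine precision.

## Problem sizes used by the test suite and summary script

Full-scale defaults (100 sets/level, 10,000 mutations/set, 4,000
backgrounds) are wired into the configuration, while the automated checks
run the same code at reduced scale: 10 sets per level × 2,000 mutations for
the cross-level trends, 20 sets × 10,000 mutations for low-fitness fit
quality, 200 backgrounds per focal parameter for epistasis, 100 random sets
for the solver/oracle comparison.  These sizes are the package's standard
evaluation scale; all are plain arguments, so full-scale runs only change
numbers in the calls.

## Known limitations

* Steady-state fitness ignores induction transients, bistability at low
  external lactose, catabolite repression, inducer exclusion and LacA.
* The default parameterization is not a calibrated fit to measurements;
  all quantitative outputs (λ, R², beneficial percentages) depend on it
  and on the kernel width cv, and should be read comparatively, not as
  biological point estimates.
* The monotone landscape and synergistic epistasis described above are
  properties of this model's steady-state algebra; models with saturating
  benefit will behave qualitatively differently, and conclusions should
  not be transferred across that structural boundary.
* DFEs are built from single mutations; multi-step adaptive walks and
  epistasis among deleterious mutations are out of scope.
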