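# Methods

## The model

LK-DFBA (Linear Kinetics–Dynamic Flux Balance Analysis) models metabolite
dynamics in a constraint-based framework.  Time on `[t0, tf]` is discretized
into `K` uniform steps of length `Δt`, and the whole trajectory becomes one
decision vector

```
ω = [w(t1), …, w(tK), x(t0), …, x(tK)],    w = [v; v_p]
```

with reaction fluxes `v`, pooling fluxes `v_p = dx/dt`, and concentrations
`x`.  One convex program couples them:

```
max_ω   c'ω − λ‖ω‖²
s.t.    S v(tk) − v_p(tk) = 0                      k = 1..K   (mass balance)
        x(tk) = x(tk−1) + Δt·v_p(tk)               k = 1..K   (Euler update)
        x(t0) = x0                                            (initial state)
        w_LB ≤ w ≤ w_UB,  x_LB ≤ x ≤ x_UB                     (box bounds)
        Σ_i v_i,n(tk+1) ≤ f_n(x(tk))               per group n (kinetics)
```

The kinetics constraints are the scientific core: each bounds a flux from
above by a function of its *controller* metabolites — substrates (mass
action) and declared allosteric regulators.  They are fitted by least squares
to time-course concentration/flux data, pairing `v(t_k)` with `x(t_k)`
(a configurable lag of 1 reproduces the staggered pairing of the program
rows; on the dense grids used here the difference is negligible).
Four constraint classes are available:

| class | form | controllers per constraint | grouping |
|-------|------|---------------------------|----------|
| LR  | `v ≤ a·x + b` | 1 | one constraint per (controller, flux) pair |
| NLR | `v ≤ a·x² + b·x + c`, `a < 0` | 1 | as LR |
| DR  | `v ≤ a·PC1(x…) + b` | all | one per flux |
| HP  | `v ≤ b + Σ aᵢxᵢ` | all | one per flux |

NLR keeps the quadratic only when the fitted curvature is strictly negative
(threshold `a < −1e−10`), so the feasible region stays convex; otherwise it
falls back to the LR line.  DR autoscales the controller matrix
(mean-centred, unit variance — standard for metabolomics data), projects onto
the first principal component, and fixes the PC sign so the fitted slope is
non-negative.  HP uses the minimum-norm least-squares solution when the
design is rank-deficient.  Zero-variance controllers are dropped from DR/HP
designs with a diagnostic.

Because all kinetics rows are upper bounds, the program needs an objective
that pulls flux through the network.  When no validated objective exists the
default rewards *cumulative production*: unit weight on the concentration of
every terminal product (produced but never consumed, e.g. biomass) at every
time point, plus unit weight on pure efflux fluxes.  Weighting concentrations
rather than flux sums matters: a flux-sum objective is indifferent to *when*
product is made, and the optimizer then hoards intermediates early and dumps
them just before the horizon ends, which bears no resemblance to the training
dynamics.  Cumulative production counts early synthesis at every later time
point and suppresses that artifact.  The weights are always overridable per
model.

The ridge term `λ‖ω‖²` removes solution degeneracy; results are insensitive
to `λ` over 1e−6…1e−3 (identical NRMSE to four decimals on the reference
fixture), and the default is `1e−4`, which conditions the program well.
Default box bounds are `[0, 1e4]` for irreversible fluxes and concentrations
(symmetric for reversible reactions) — deliberately arbitrary and
configurable.

### Kinetics-row index range

Kinetics rows bound `v(t_{k+1})` by `f(x(t_k))` for `k = 0..K−1` by default:
the first flux step is constrained through the initial concentrations.
Leaving `v(t_1)` bounded only by box bounds (available as
`kinetics_from_step=1`) lets a maximizing objective buy an unphysical
first-step flux spike up to the box bound, which ruins every fit.  The cost
of the default is that a fitted line that is negative at `x0` makes the whole
program infeasible — a real failure mode of linear kinetics fits on strongly
curved power-law data.  Infeasibility is reported as a first-class status and
such cases are excluded (with counts) from ensemble statistics.

## Solving

With LR/DR/HP rows the program is a convex QP; active NLR rows make it a
convex QCQP (the right-hand side is concave).  The default backend is a
Mehrotra predictor-corrector primal-dual interior-point method
(`lkdfba.qcp`): because each quadratic row is univariate in one concentration
variable, the Hessian of the Lagrangian stays diagonal and each iteration is
a single sparse factorization of the `(n + m_eq)` augmented KKT system.
Typical ensemble-size programs (≈750 variables) converge in 15–40 iterations
to complementarity ≤1e−8, with constraint violations ≈1e−12.  When the
iteration fails to converge, feasibility of the linear relaxation is
certified with HiGHS to distinguish "infeasible" from "numerical failure";
infeasible is an expected outcome (e.g. strong down-regulation), never an
exception.

OSQP is available as an alternative backend (`solver="osqp"`), handling NLR
rows through an outer tangent cutting-plane loop (tangents of a concave
right-hand side are valid outer approximations, so the loop converges to the
QCP optimum from above).  The two backends agree on fixture problems to 3–4
decimals in NRMSE and serve as mutual cross-checks; the test suite
additionally verifies both against an independently assembled dense
SLSQP/HiGHS formulation on small instances.

## Dynamic flux estimation (DFE)

When only concentrations are measured, fluxes are inferred per time point:
each metabolite series is smoothed with a cubic smoothing spline whose
penalty is chosen by generalized cross-validation (`lam=None`; pass a float
to fix the penalty, or `smoothing=None` to interpolate noiseless data), the
spline derivative gives `v_p`, and `S v = v_p` is solved pointwise by least
squares with non-negativity on irreversible fluxes.  Rank-deficient
stoichiometries return minimum-norm solutions with an explicit warning —
flux estimates far from truth propagate directly into the constraints, so
dense, low-noise concentration data are strongly recommended before relying
on DFE.

## Synthetic ground truth

The generator emulates a branched pathway with five metabolites (x1–x4 plus
a biomass species xBM), five irreversible fluxes, and power-law
(biochemical-systems-theory) kinetics:

```
v1:  → x1      v1 = a1·x3^g13   (g13 < 0: end-product inhibition, "red" edge)
v2: x1 → x2    v2 = a2·x1^g21
v3: x2 → x3    v3 = a3·x2^g32
v4: x2 → x4    v4 = a4·x2^g42·x3^g43  (g43 > 0: activation, "green" edge)
v5: x3 → xBM   v5 = a5·x3^g53
```

This topology is the package's reference test system — a minimal branched
pathway with five metabolites including biomass, five fluxes, and one
positive plus one negative regulatory edge, the smallest structure that
exercises mass action, activation, inhibition, and a branch point at once.
The parameterization in `reference_branched_model()` is a package-defined
fixture chosen once for well-scaled, non-trivial transients.

Defaults: a 10-time-unit horizon sampled at 50
points; random models drawn per seed with rate constants log-uniform on
[0.1, 10], kinetic-order magnitudes uniform on [0.2, 1] with regulatory signs
preserved, and initial conditions log-uniform on [0.2, 2] (sampling ranges
are the package's choice; candidates whose ODE solution fails, diverges, or
is flat are rejected and redrawn).  Ground truth is integrated with LSODA at
rtol 1e−8 / atol 1e−10.  Perturbations scale only the mass-action
coefficient of the targeted flux (0.5×/2× for up/down-regulation, 0.1× to
emulate knockouts — full removal frequently makes the program infeasible).
Whole-model resampling replaces each parameter magnitude by `|N(p, p)|`
(folded normal; signs of regulatory exponents preserved, zero stays zero).

Noise replicates down-sample to `nT` evenly spaced points (endpoints exact;
linear interpolation when the target grid is not an index subset) and replace
every metabolite and flux value `y` with a draw from `N(y, CoV·|y|)`.  Draws
are *not* clipped at zero by default, staying faithful to the stated
distribution; `clip_nonnegative=True` is available for concentrations.
Replicates use independent spawned substreams of one seed and are
bit-reproducible.  Optional smoothing fits each series to the six-parameter
double-sigmoid impulse family by bounded nonlinear least squares with five
seeded starts; a series whose impulse fit is worse than the constant-mean
model is returned unsmoothed and flagged, since forcing the impulse shape
onto incompatible data increases error.

What the generator does **not** emulate: correlated measurement error across
metabolites, missing observations, non-uniform sampling, and the scale and
stiffness of real central-carbon models.  Passing tests therefore demonstrate
correctness of the machinery and behavior under the stated noise model, not
performance on experimental data.

## Evaluation and approach selection

NRMSE between predicted and reference concentration trajectories is computed
per metabolite as RMSE divided by the *reference* range (max − min; fallback
to |mean| with floor 1 for constant series), then averaged across
metabolites.  Fluxes are excluded from NRMSE by default.  Normalizing by the
reference makes the measure asymmetric under argument swap — intentional and
tested.

The comparison workflow fits every approach to wild-type data, simulates the
wild type and each perturbation (constraints on the targeted fluxes scaled by
the same factor as the ODE truth), and tabulates NRMSE (mean across noisy
replicates; infeasible cells are missing and excluded from best-cell logic).
The approach with minimal wild-type NRMSE is selected; ties break
deterministically toward the simplest class (LR > NLR > DR > HP).  The
*consistency rate* pools, over an ensemble of models and data conditions, the
fraction of perturbation columns whose best approach equals the wild-type
best of the same comparison.

Average flux (arithmetic mean of the predicted time course, for simulations
that do not reach steady state) and Pearson correlations of average-flux
profiles across phenotypes support comparisons against steady-state
experimental flux data; zero-variance vectors yield a missing value rather
than an error.

## Problem sizes used in the shipped experiments

The packaged ensemble experiment (`lkdfba.experiments.consistency_experiment`,
driven by `scripts/acceptance.py`) uses 40 random parameterizations of the
branched pathway (12 in the test suite), each with a noiseless nT = 50
condition and a noisy nT = 15 / CoV = 0.15 condition with 3 replicates, and
six perturbations (v2/v3/v4 at 0.5× and 2×).  These sizes balance
statistical stability of the pooled rate against runtime on a single CPU;
the model count and conditions are arguments.

## Known limitations

* Linear/quadratic ceilings extrapolate poorly outside the training range of
  the controllers; optimizing objectives will exploit that freedom.  DR and
  HP, which consolidate all controllers into a single constraint per flux,
  are the most exploitable and can produce large errors on some models —
  which is precisely why selection among approaches is part of the workflow.
* Wild-type infeasibility (fitted ceiling negative at the initial state)
  removes a model/approach pair from consideration; ensembles report how many
  columns were excluded.
* The secondary re-optimization of constraint parameters (beyond plain
  regression) is out of scope, as is bundling any external kinetic model;
  SBML ingestion covers stoichiometry and modifier edges only (modifier signs
  default to positive).
* The Euler update is first-order; errors shrink with denser grids, and the
  discretization is part of the model definition rather than a numerical
  tolerance.
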