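# lkdfba

Dynamic metabolic modeling with fitted kinetics constraints — an
implementation of **LK-DFBA** (Linear Kinetics–Dynamic Flux Balance
Analysis) for systems biologists who have time-course metabolomics (and
ideally fluxomics) data and want a constraint-based model that captures
metabolite *dynamics* and allosteric regulation while staying a convex
program.

Classic FBA assumes steady state; ODE kinetic models capture dynamics but
need mechanistic rate laws and hard parameter estimation.  LK-DFBA sits in
between: time is discretized and unrolled, so fluxes `v`, pooling fluxes
`v_p = dx/dt`, and concentrations `x` at every time point form one decision
vector ω constrained by

```
max_ω  c'ω − λ‖ω‖²
s.t.   S·v(t_k) = v_p(t_k)                       (mass balance per time point)
       x(t_k) = x(t_{k−1}) + Δt·v_p(t_k)         (concentration updates)
       x(t_0) = x_0
       bounds on v, v_p, x
       Σ_i v_{i,n}(t_{k+1}) ≤ f_n(x(t_k))        (kinetics constraints)
```

The kinetics constraints bound each flux by the concentrations of its
*controller* metabolites (substrates and allosteric regulators) and are
fitted to data by least squares.  Four constraint classes are provided, and
choosing among them per system is the point of the package:

* **LR** — one line `v ≤ a·x + b` per controller–flux pair;
* **NLR** — concave quadratic `v ≤ a·x² + b·x + c` (`a < 0`, else it falls
  back to LR), keeping the program a convex QCQP;
* **DR** — all controllers of a flux compressed to their first principal
  component, `v ≤ a·PC1 + b`;
* **HP** — a hyperplane in all controllers, `v ≤ b + Σ aᵢxᵢ`.

The workflow: fit all four classes to wild-type data (running dynamic flux
estimation first if fluxes were not measured), simulate, score each fit by
NRMSE against the training trajectories, and select the lowest-error class.
The selected class is then used for in-silico predictions — up-/
down-regulating or knocking out reactions by scaling their constraint
parameters.  The package also ships the synthetic branched-pathway generator
(power-law kinetics, seeded random parameterizations, signal-proportional
Gaussian noise, impulse smoothing) used to validate that the wild-type-best
class usually stays the best class under genetic perturbations.

## Worked example

```python
import lkdfba as lk

model = lk.reference_branched_model()       # 5 metabolites, 5 fluxes, 2 regulatory edges
data = lk.simulate_ode(model)               # ground truth: 50 samples over 10 time units

scores = {}
for approach in lk.APPROACHES:
    est = lk.LKDFBA(network=model.network, approach=approach).fit(data)
    scores[approach] = -est.score(data)     # score() is negative NRMSE
    print(f"{approach:3s}  wild-type NRMSE = {scores[approach]:.4f}")

best = min(scores, key=scores.get)
print("selected approach:", best)

est = lk.LKDFBA(network=model.network, approach=best).fit(data)
down = est.perturbed(["v2"], 0.5)           # halve the v2 constraint parameters
truth = lk.simulate_ode(lk.perturb_ode_parameters(model, ["v2"], 0.5))
sol = down.predict(truth)
print(f"dV2 prediction NRMSE vs perturbed truth = {lk.nrmse(sol.to_dataset(), truth):.4f}")
```

prints

```
LR   wild-type NRMSE = 0.0936
NLR  wild-type NRMSE = 0.0950
DR   wild-type NRMSE = 2.5931
HP   wild-type NRMSE = 2.7384
selected approach: LR
dV2 prediction NRMSE vs perturbed truth = 0.1667
```

On this parameterization the single-controller classes track the training
data to within ~9% of each metabolite's range, while the consolidated DR/HP
constraints are exploitable by the optimizer and fit poorly — exactly the
kind of spread the selection step exists to resolve.  The model fitted on
wild-type data then predicts the down-regulated phenotype at NRMSE 0.17
(final biomass drops from 6.91 to 6.55 concentration units).

A command-line interface mirrors the pipeline stages
(`lkdfba generate | dfe | fit | simulate | perturb | evaluate | run |
select`); `lkdfba run --config config.yaml` executes the whole workflow and
writes the NRMSE comparison matrix, fitted constraint sets, and a manifest
with seeds and a config hash.

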