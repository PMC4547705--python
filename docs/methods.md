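# Methods

## 1. Model

### State space

Cells are typed by a pair `(compartment, generation)`. Compartments form a
feedforward network: a source `DR` (draining lymph nodes), a chain of transfer
stages (`TR1, TR2` by default), and sinks `SPL`, `ILN`, `MLN`. Generations run
from 0 (undivided) to a dye-saturation cap `p = 7`. The canonical type order is
compartments in network order, generations ascending within a compartment; the
default type space has `D = 6 × 8 = 48` types.

The process evolves in discrete steps of `dt = 4 h`, indexed `n = 0, 1, 2, …`
with `n = 0` anchored at `T0 = 72 h` post-immunization (the earliest time at
which an initial generation profile can be measured). Conditional on the
current population, every cell acts independently according to a type-dependent
offspring law — a multi-type Galton–Watson process.

### Offspring law

Source cell of generation `i`:

| fate | probability | offspring |
| --- | --- | --- |
| divide | `gamma_i` | two `(DR, min(i+1, p))` cells |
| quiesce | `delta_i` | one `(DR, i)` cell |
| migrate | `m` if `i ∈ {1, 2, 3}`, else 0 | one `(TR1, i)` cell |
| die | residual | none |

Generations `i ≥ 2` reuse the generation-2 probabilities (`gamma_2, delta_2`);
at the cap, division produces two generation-`p` cells (configurable:
`divide_at_cap=False` routes that probability to death). Transfer stages are
pure unit delays (`TRk → TRk+1` with probability 1); the last stage routes its
cell to sink `s` with probability `rho_s`, where
`rho_spl + rho_il + rho_mes = 1`. Sink cells divide / quiesce / die with the
source per-generation probabilities but never migrate. Each generation's fate
probabilities must lie in the simplex (`gamma_i + delta_i + m·1{i migrates}
≤ 1`), which the fit enforces as hard constraints.

The default two-transfer-stage chain discretizes a 12 h source-to-sink transit
at the 4 h step: a cell that emigrates at step `n` occupies `TR1` at `n+1`,
`TR2` at `n+2`, and reaches its sink at `n+3` — three transitions. Topologies
with any number of stages can be built directly; `NetworkTopology.from_transit_time`
converts a physical transit time into the stage count.

### Reference parameterization

`reference_parameters()` returns the probabilities estimated in the murine
nasal-immunization CFSE study the model was developed against:
`gamma = (0.06, 0.29, 0.24)`, `delta = (0.43, 0.31, 0.23)`, `m = 0.14`,
`rho = (0.95, 0.01, 0.04)` for (SPL, ILN, MLN). Notably, generation-0 cells
die with per-step probability `1 − 0.43 − 0.06 = 0.51`.

## 2. Moments

With `M[j, k] = E[# type-k offspring of one type-j cell]` and `V_j` the
offspring covariance of a type-j cell, the population mean `mu(n)` and
covariance `Sigma(n)` satisfy exactly

```
mu(n+1)    = Mᵀ mu(n)
Sigma(n+1) = Mᵀ Sigma(n) M + Σ_j mu_j(n) V_j
```

`M` and the `(D, D, D)` tensor of `V_j` are precomputed once per parameter
vector; the covariance update contracts the tensor with `mu(n)` via
`numpy.tensordot`. The initial state is treated as deterministic
(`Sigma(0) = 0`).

### Frequency moments (delta method)

Sacrifice sampling makes only within-animal *frequencies* comparable across
time points. For a category index set `s` (organ × generation cells of the
measured compartments), the frequency vector `f = Z_s / 1ᵀZ_s` is approximated
to first order around `mu_s = mu(n)[s]`:

```
pi    = mu_s / (1ᵀ mu_s)
J     = (I − pi 1ᵀ) / (1ᵀ mu_s)
Omega = J Sigma_s Jᵀ
```

`Omega` is singular by construction (rows sum to zero).

## 3. Likelihood and fit

Each animal sacrificed at step `n` contributes a normal log density of its
frequency vector with mean `pi(n)` and covariance `Omega(n)`. Because `Omega`
is singular, the last category is dropped; for matrices whose rows and columns
sum to zero all cofactors coincide, so the value does not depend on which
category is dropped (up to the ridge below). Numerical choices:

- **Active categories** are fixed before optimization as the structurally
  reachable measured types (support of the mean under a strictly positive
  placeholder parameter set, propagated from the data's initial state). This
  keeps the active set — hence the likelihood — independent of `theta` and
  continuous during optimization.
- A trace-scaled ridge `1e-10 · tr(Omega_r)/k · I` is added before the Cholesky
  factorization.
- Step-0 animals carry no information (the initial state is the deterministic
  anchor, estimated as the rounded mean of their source generation profile)
  and are skipped, as are animals with zero cells in a scope.
- Scope `"global"` uses one frequency vector over all measured organs per
  animal (default); `"per_organ"` normalizes within each organ separately.

The MLE minimizes the total NLL over the 9 free coordinates
(`rho_mes = 1 − rho_spl − rho_il`) with SLSQP under box bounds
`[1e-6, 1 − 1e-6]` and the simplex inequality constraints, taking the best of
20 uniform feasible starts (deterministic given the fit seed). Infinite NLL
values (constraint violations) are clipped to `1e12` inside the objective.

**Standard errors** come from the observed Fisher information: a central
finite-difference Hessian of the NLL on the reduced space (relative step
`1e-4` with an absolute floor), inverted if well-conditioned; otherwise the
pseudo-inverse is used and the `singular_information` flag raised.
`SE(rho_mes)` follows by the delta method,
`Var(rho_mes) = Var(rho_spl) + Var(rho_il) + 2 Cov`. If the data contain no
sink cells at all, the splitting probabilities are structurally
non-identifiable: they are reported as `NaN` with `rho_identifiable = False`.

**Relative sensitivity.** For coordinate `theta_i` at the estimate,

```
S(d) = (|L(theta + d·e_i) − L(theta)| / |L(theta)|) / (|d| / theta_i)
```

on a symmetric 21-point grid `d ∈ [−0.1 theta_i, 0.1 theta_i]` (the `d = 0`
point is excluded). The perturbation is applied to the single coordinate
as-is; perturbing one `rho` deliberately leaves the splitting simplex
unnormalized (the likelihood tolerates this in a dedicated evaluation mode),
with optional renormalization via configuration. The per-parameter score is
the mean `|S|` over the grid.

## 4. Simulator and synthetic data

The simulator is exact: for each type with `Z > 0` cells it draws one
multinomial over the enumerated fate outcomes and adds the resulting offspring
to the next state. Ensembles use independent `SeedSequence`-spawned substreams
per path, so a path's trajectory is invariant to the ensemble size and every
result is reproducible from one integer seed.

The synthetic generator reproduces the sacrifice design: each animal is an
independent path from a common deterministic initial draining-node population
(default `5 × 10⁴` cells spread over generations 0–4 as
`10/25/30/25/10 %`, qualitatively matching a 72 h dye-dilution histogram) to
its sacrifice step (`n ∈ {0, 3, 6}`, i.e. 72/84/96 h), recording only the
measured organs (source and sinks — cells in transit are inaccessible).
An optional lognormal jitter of the initial size (mean-one, given CV) emulates
extra inter-individual heterogeneity. Data are stored long-form:
`animal_id, time_hours, n, organ, generation, count`.

## 5. Identifiability notes

Scaling all of `(gamma, delta, m)` by a constant `c` scales the expected
source population by exactly `cⁿ`. On a source-only network this makes
frequencies scale-invariant. On the full network the delay-line and splitting
transitions carry no parameter factor, so sink blocks scale as `c^(n−2)`:
*per-organ* frequencies remain scale-invariant, while the across-organ
frequency vector shifts. The default global scope therefore retains
information about the absolute scale; `scale_profile` exposes the NLL along
this direction as a diagnostic.

## 6. Limitations

- The frequency likelihood is a first-order (delta-method) normal
  approximation; it degrades for small populations and near-deterministic
  scopes, and treats an animal's categories as jointly normal rather than
  compositional-discrete.
- The initial state is a deterministic plug-in (mean of step-0 animals);
  uncertainty in it is not propagated into the standard errors.
- Transfer stages are pure delays: no division or death in transit (a
  `proliferate_in_transit` switch is reserved but not implemented as
  likelihood-supported behavior).
- Per-generation probabilities are constant in time; antigen decay or
  contraction-phase dynamics are out of scope.
- Fisher standard errors assume a locally quadratic likelihood at an interior
  optimum; estimates pinned at constraint boundaries make them unreliable
  (flagged via `singular_information`).
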