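# Methods

`mitommp` models the mitochondrial membrane potential (MMP, Ψ) of live cells
exposed to OXPHOS inhibitors, calibrates the model to DMSO-normalized Rho123
imaging trajectories, and quantifies parameter uncertainty. This note records
the model, its assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## The kinetic model

Two state variables, both in arbitrary units (a.u.): the mitochondrial oxygen
level `[O]` and the MMP `Ψ`. With `H(t)` the Heaviside step (exposure starts
at t = 0 h; `H(0) = 1`):

```
d[O]/dt = r · ( supply − K_E·[O] · K_Ei/(K_Ei + [D_E]) )
dΨ/dt   = r · ( C_f·OCR − V_A·Ψ/(K_A + Ψ) · K_Ai/(K_Ai + [D_A])
                − V_U·[D_U]/(K_U + [D_U])·Ψ  [ − α·(Ψ − Ψ°)·H(t) ] )
```

where `OCR = K_E·[O]·K_Ei/(K_Ei + [D_E])` is the oxygen consumption rate.
Oxygen is supplied at the constant rate `supply = 0.6` and consumed by ETC
activity; ETC inhibitors (acting through `[D_E]`) reduce consumption by
Michaelis–Menten inhibition. Proton pumping is proportional to the OCR
(coefficient `C_f`); the gradient is dissipated by ATP synthesis through
complex V (maximal rate `V_A`, half-maximal MMP `K_A`, inhibitable through
`[D_A]` with half-inhibition constant `K_Ai`) and by uncoupler-mediated
proton backflow (`V_U = K_U = 1` by convention). The time-scale factor `r`
multiplies both right-hand sides; all rates are therefore in arbitrary units
per hour. The optional linear ion-leakage flux `α·(Ψ − Ψ°)` (the bracketed
term) vanishes at the baseline MMP, so the unexposed steady state is
unchanged.

The pre-exposure steady state is analytic:

```
[O]_ss = supply / K_E          Ψ° = supply·C_f·K_A / (V_A − supply·C_f)
```

which requires `V_A > supply·C_f`; the parameter container enforces this, and
fit problems raise the `V_A` lower bound to `1.001·supply·C_f` when `supply`
and `C_f` are fixed (below it no positive steady state exists).

Observation map: microscope intensities are linear in the MMP in the
non-saturating regime, so the model output is `y = c1·Ψ + c0`, fitted against
DMSO-normalized intensities. `K_E = K_Ei = 1` by default: MMP data alone do
not constrain them separately from the arbitrary units, so they act as unit
conventions unless overridden.

### Effective-concentration pharmacokinetics

The concentration driving the inhibition terms is
`[D_X]_i(t) = [D°_X]_i · exp(−γ t) · H(t)` for dose index *i* (ascending in
applied concentration). Variants:

* `basic` — γ = 0 (constant exposure);
* `pk_decay` — one decay rate γ for all doses (intracellular degradation,
  chemical instability, or plastic binding);
* `pk_decay_leakage` — `pk_decay` plus the leakage term; only admitted for
  ATP-synthase inhibitors, where hyperpolarisation makes leakage relevant;
* `conc_dep_decay` — fast rate `γ_L` for the lowest doses (default: the 4
  lowest) and slow `γ_H` for the rest, for saturable elimination.

The per-dose effective doses `[D°_X]_i` are free parameters with no
monotonicity constraint across the dose index.

### A structural symmetry worth knowing

With relative (normalized) observations, `C_f` fixed, and the leakage variant,
the map `(V_A, K_A, r, α, c1) → (V_A, λK_A, λr, α/λ, c1/λ)` leaves `y(t)`
exactly invariant for any λ > 0 (the oxygen equation is at steady state, so
the `r` rescaling is invisible there). The leakage rate α is therefore
structurally non-identifiable from relative MMP trajectories — its profile
likelihood is flat along this manifold — while γ, untouched by the symmetry,
remains identifiable. Absolute MMP measurements would break the symmetry.

### Monotonicity is exact only without ETC inhibition

Without `[D_E]`, oxygen stays at its steady state and the basic model's MMP
moves monotonically to its new equilibrium (down for uncouplers, up for
ATP-synthase inhibitors). Under constant ETC inhibition, however, oxygen
accumulates until the OCR returns to the supply rate, after which the MMP
slowly relaxes back — the MMP decrease is monotone only while oxygen
relaxation (rate `r·K_E·K_Ei/(K_Ei+[D_E])`) is slow relative to the
observation window. The ETC demonstration panel uses `K_E = 0.02`,
`K_Ei = 0.2`, which keeps any late recovery below 5·10⁻³ per hour (about 1%
of the response amplitude) over 23 h; the corresponding property test uses
that tolerance.

## Simulation and sensitivities

LSODA (via `scipy.integrate.odeint`) with `rtol = 1e-8`, `atol = 1e-10`;
right-hand sides are numba-compiled. Integration always starts at t = 0 from
the analytic steady state with the post-exposure vector field, so the
Heaviside switch needs no event handling. Parameter sensitivities `∂y/∂θ`
are propagated with the forward (augmented) ODE system using hand-derived
partials of the vector field, including the dependence of the steady-state
initial condition on the parameters; they are validated against central
finite differences (step `1e-6·|θ|`) to better than 1e-4 relative error and
serve as the exact least-squares Jacobian.

## Calibration

Per condition (compound × concentration), the weighted sum of squares is
`R² = Σᵢ (y_model,i − y_data,i)²/σᵢ²` over the `n_t = 23` hourly time points,
with σ the standard error among biological replicates; the total cost is the
negative log-likelihood `logL = Σⱼ R²ⱼ/2`. Where the SE is zero or
unavailable (single replicate) the calibration weight uses a floor of 5% of
the condition's mean signal (configurable).

Estimation is bounded Trust Region Reflective least squares on the stacked
weighted residuals, multi-started from 100 random points (default) sampled
log-uniformly over four decades around the nominal values (linear-uniform for
`c0`, which may be near zero), ranked by final cost; exact cost ties break to
the lexicographically smallest parameter vector. Practical caps — 150
residual evaluations per start and 500 internal LSODA steps per output
point — cut off starts stranded in ultra-fast-dynamics corners of the start
range; an integration failure during optimisation yields a penalty cost of
1e10 plus a mild distance regulariser instead of an exception. Unit `x_scale`
outperformed Jacobian-based scaling here (fewer excursions into stiff
parameter regions) and is the default.

Joint fitting shares `{V_A, K_A, r}` across compounds while `{c1, c0, D°}`
stay compound-specific; with one compound it reduces exactly to the separate
fit. Fit quality across inhibitor classes is compared with two-sample
two-sided Kolmogorov–Smirnov tests on per-compound costs, exact p-values for
small samples.

## Profile likelihood

`NPL(v)` is twice the re-optimised cost with the profiled quantity fixed at
`v`; the CI is cut at `min(NPL) + χ²(confidence, df = 1)` (3.8415 at 95%,
6.6349 at 99%). The grid walks outward from the MLE multiplicatively
(step ×1.3, warm-starting each refit from its neighbour) until the threshold
is exceeded, six decades are covered, or hard bounds are reached; each
crossing is then refined by ~6 bisection refits before linear interpolation,
which makes the CI endpoints accurate to ~1% (validated against the
closed-form linear-Gaussian interval). A crossing is discarded as an
artifact when, at the re-optimised solution, a nuisance parameter sits at a
box bound with a non-vanishing cost gradient pointing beyond it (log-scale
gradient test): the bound, not the data, is then what raises the NPL — the
compensation-direction situation of the leakage rate α. A flat nuisance that
merely happens to rest at a bound (zero gradient) does not invalidate the
crossing. Discarded sides are reported open and the parameter
non-identifiable. Derived quantities are profiled by
substitution when invertible in a single parameter (e.g. the decay ratio
`R = exp(−γΔT)` through γ), otherwise by a quadratic penalty with escalating
weight; locally constant quantities are flagged degenerate.

## Hierarchical bootstrap

Artificial replicates mirror the experimental design: plates (biological
replicates) are resampled with replacement to the original count; within each
selected plate the single cells of every condition × time point (technical
replicate wells pooled) are resampled with replacement to the original count;
the preprocessing chain is re-applied and the model re-fitted warm-started at
the original MLE (full multistart per sample available behind a flag).
Samples whose refit fails are logged and redrawn, capped at twice the
requested count. 95% and 99% CIs are sample quantiles of the bootstrap
estimates, taken as order statistics (lower/higher interpolation) so the 99%
interval always contains the 95% one.

## PK ratio predictions

Because the effective concentration decays exponentially, the predicted
compound ratio between two sampling times is `R_T2/T1 = exp(−γ(T2 − T1))`,
computed by default for the pairs (2, 8), (2, 24) and (8, 24) h. CIs follow
from the γ CI by the monotone transform (open γ sides map to the natural
limits 0 and 1). Externally measured per-replicate ratios (e.g. LC-MS/MS)
are compared against the profile-likelihood and bootstrap CIs; a measurement
inside some intervals but not others is flagged `mixed`.

## Synthetic data generator

Treated-well signals are `drift_p(t) · s_pc · (c1·Ψ(t) + c0)` and DMSO wells
`drift_p(t) · (c1·Ψ° + c0)`, with per-cell intensities log-normal around the
well signal (median = signal; default log-SD 0.5, a typical spread for
integrated single-cell intensities). `drift_p(t)` is a per-plate positive
function (default: baseline ×exp(−quench·t) with a transient uptake bump,
quench rate 0.01–0.04 /h) shared by treated and control wells — exactly the
assumption DMSO normalization relies on, and the generator property tests
verify the cancellation is exact. `s_pc` is a per-plate × compound scale
jitter (default ±10%) reproducing the compound-specific baseline scatter of
normalized intensities (≈0.8–1.2); it does not cancel in normalization and is
the main inter-plate variance component the bootstrap sees. Defaults: 4
biological replicate plates (3 for the ATP-synthase panel), 2 technical
wells per condition, 2 DMSO wells per plate, ~300 cells per well
(negative-binomial, dispersion 20), 23 hourly time points starting 1 h
post-exposure.

Three canned panels mirror the classical study designs: an ETC-inhibitor
panel (basic variant, 10 concentrations), an uncoupler panel (`pk_decay`,
γ = 0.1/h, giving the depolarise-then-recover pattern), and an ATP-synthase
panel (`conc_dep_decay`, γ_L = 0.6, γ_H = 0.04, K_Ai = 0.05 µM, 8 doses:
low doses rise then fall, high doses stay hyperpolarised through 23 h).

What the generator does **not** emulate: image segmentation errors, cell
death and its selection effects, saturating detector response, non-linear
(Nernst-style) leakage, time-varying `C_f`, compound metabolite activity, or
correlated (non-log-normal) cell populations. Passing tests therefore show
the pipeline recovers what it assumes — log-normal cells, multiplicative
plate drift, linear observation — not that those assumptions hold for any
particular instrument.

## Problem sizes used in tests and the acceptance script

Chosen as representative scaled-down study conditions: parameter recovery
uses the noiseless 8-dose ETC design with 100 starts (40 in the acceptance
script); the identifiability study uses 4 doses with observation noise 0.02;
bootstrap coverage uses 3 doses × 3 plates × 2 technical wells × 40 cells
with `{γ, c1, c0, D°}` free and the kinetic constants fixed at their
generator values, 50 repetitions × 100 bootstraps in the test suite (20 × 50
in the script); model selection on the ATP-synthase panel uses 12 starts per
variant (8 in the script).

## Known limitations

* α and γ estimates from relative data inherit the symmetry above: only the
  leakage variant's γ and combinations of the others are identified.
* The least-squares weights treat time points as independent; drifts shared
  across time within a plate induce correlations the likelihood ignores
  (the bootstrap, which resamples whole plates, is the robust alternative).
* The penalty for failed integrations has zero gradient, so a start that
  lands in an infeasible region terminates there rather than escaping.
* `conc_dep_decay` fixes the low/high block boundary (default 4 lowest
  doses); the boundary itself is not estimated.
* Exact KS p-values are valid for continuous data; ties (unlikely for
  costs) would make them conservative.
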