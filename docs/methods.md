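# Methods

## The model

`coldcarb` implements a condensed kinetic model of the central
carbohydrate metabolism of *Arabidopsis thaliana* leaf tissue during
cold acclimation. Five pools are tracked — the hexose phosphates F6P
and G6P, sucrose (Suc), fructose (Frc) and glucose (Glc), all in
µmol gDW⁻¹ — connected by twelve processes: a constant photosynthetic
influx rNPS = k_NPS/6 (hexose equivalents), sucrose phosphate synthase
(rSPS, a lumped two-substrate law consuming F6P and a fraction k_udp of
G6P, standing in for the omitted UDP-glucose intermediate),
fructokinase and glucokinase (rFRCK/rGLCK, Michaelis–Menten with
product-pathway feedback inhibition by F6P and G6P respectively),
invertase (rINV, inhibited by both of its products), two directional
phosphoglucoisomerase fluxes (rPGI1 consuming F6P, rPGI2 producing
G6P) balanced by the fraction f, two first-order exports (r1 = k1·Suc
to sink organs, r2 = k2·F6P to other pathways), lumped starch synthesis
(rSTAsyn = k_STA·G6P), lumped anthocyanin synthesis (rANTHO = k_ANT·F6P)
and a constant starch-degradation input rSTAdeg with no rate law of its
own, fixed at 0 in every steady-state condition realization (midday
conditions; net starch turnover is absorbed into k_STA).

Time is in hours, fluxes in µmol gDW⁻¹ h⁻¹. The source publication
never states rate units; this is a declared convention propagated
through all I/O.

### Two deliberate oddities, kept verbatim

* **Sucrose balance.** The published ODE system drains sucrose through
  r2 (= k2·F6P) even though r1 (= k1·Suc) is defined as the sucrose
  export and is analysed as a flux throughout; r1 otherwise appears in
  no balance at all. The default mode `scheme-consistent` uses
  dSuc/dt = rSPS − r1 − rINV; mode `as-printed` reproduces the
  published typography literally. Neither is asserted to be the
  authors' intent.
* **The PGI pair is not mass-coupled.** rPGI1 removes F6P without
  producing G6P, and rPGI2 produces G6P through a law saturable in G6P
  itself. No conservation correction is applied, because the published
  parameters were fitted to this form. One measurable consequence,
  asserted in the tests: with zero influx the system does **not** drain
  to the empty state unless f = 1 — the rPGI2 branch self-feeds G6P to
  the root of vmax_PGI·(1−f)/(Km_PGI+G6P) = k_STA. A second
  consequence: the downstream pools (G6P, Suc, Frc, Glc) have no
  F6P-coupled source, so in fully first-order (linear) parameter
  regimes they drain to zero and only the F6P branch carries flux.
  The reported "rPGI" measure is rPGI1 by default (configurable to
  rPGI2 or their mean, recorded in output metadata); rPGI1 = rPGI2 is
  not structurally enforced at fitted steady states.

k_udp is restricted to [0.2, 0.5] (20–50 % of G6P available to SPS);
f to [0, 1]. k_NPS may be 0 (darkness); all other rate constants are
strictly positive.

## Steady states

`find_steady_state` integrates the stiff system (LSODA, rtol 1e-10) to
t = 1e4 h and refines with a hybrid-Powell (damped Newton) root solve;
the returned state satisfies |dX/dt| < 1e-9 µmol gDW⁻¹ h⁻¹ in **every**
component (both the horizon and the tolerance are configurable, and the
integration can be skipped when a good initial guess is available, as
inside calibration and MCA loops). Non-convergence raises an error
carrying the final residual. Because each flux is proportional to
exactly one of the ten rate-scaling constants {k_NPS, the five vmax,
k1_exp, k2_exp, k_STA, k_ANT}, scaling all ten by λ leaves steady-state
concentrations unchanged and scales all fluxes by λ — the structural
basis of the control-coefficient summation theorems.

## Sensitivity score

For a measure x (pool or flux) and a set of influx perturbations i,

γ_x = ( ∏ᵢ |log₂((xᵢ/x₀)·(r₀/rᵢ))| )^(1/N),

the geometric mean of absolute log₂ perturbation-normalized fold
changes; a measure responding exactly proportionally to the influx
scores 0. The default protocol rescales k_NPS by ±5…±30 % in 5 % steps
(N = 12) at 2 h and reads xᵢ at the end of the 4 h window (a
relaxed-state readout is available); the influx ratio rᵢ/r₀ equals the
k_NPS ratio since rNPS = k_NPS/6. The high-light variant applies a
single +25 % step and treats exposure durations (3 h and 6 h after the
step) as the perturbations, with rᵢ/r₀ = 1.25 throughout. The 14
reported measures are the five pools and nine fluxes (rSPS, rPGI,
rFRCK, rGLCK, r1, rINV, r2, rSTAsyn, rANTHO). Measures driven to zero
or below at readout are reported as missing with a warning — an epsilon
substitute would bias γ downward unpredictably. A perturbation of
exactly 0 annihilates the geometric mean (the unperturbed system is
left at its steady state exactly, so the inner term is an exact 0); the
protocol warns when one is configured.

## Metabolic control analysis

C_p^X = dln(X)/dln(p) of a fully relaxed system: the parameter is
perturbed multiplicatively by (1 ± h), the steady state re-solved per
side, and the central difference taken in log-log space (default
h = 1e-4). For the bounded fractions f and k_udp the step is shrunk so
both sides stay within the admissible range — never silently
one-sided. An independent implicit-function-theorem route
(dS/dp = −J⁻¹·∂F/∂p, with the flux chain rule for flux measures)
serves as a cross-check oracle, and the finite-difference core is
additionally verified against the closed-form coefficients (±1, 0) of
a three-step first-order chain. k_STAdeg (fixed 0) is excluded from
the analysed parameter set; f and k_udp are included. The
high-coefficient frequency analysis counts |C_p^X| > 1.5 per genotype
or per sampling day; absolute values are used because large negative
coefficients are equally "sensitive", and the published threshold does
not state sign handling.

## Calibration

Each genotype × day condition is fitted individually (the strategy the
study selected; joint and pairwise Km/Ki strategies are out of scope):
bounded multi-start least squares on weighted log-residuals between the
model steady state and the observed pools plus any observed flux
targets (influx from gas exchange, net starch balance, exports). Log
residuals are a declared choice — the observations span orders of
magnitude — with weights 1/dispersion²; the original study's error
model is not published. Starts are Latin-hypercube draws in log-bound
space plus one informed start that pins the analytically identifiable
first-order constants (k_NPS, k1_exp, k2_exp, k_STA, k_ANT) to their
flux/pool ratios where the corresponding target is observed; each start
runs a trust-region reflective solve. Order relations are enforced by
hinge penalties during optimization and re-verified on the result; an
infeasible result is discarded, so returned parameters always satisfy
bounds and relations. The signature default is 50 starts; the analysis
drivers and acceptance checks use 3 per condition, which is already
sufficient for near-zero residuals in this over-parameterized fit and
keeps a 25-condition calibration under two minutes on one CPU.

Constraints: all Km/Ki share common bounds (default [0.5, 50]
µmol gDW⁻¹); Km_FRCK > Km_GLCK is enforced; "Km_INV similar to
Km_FRCK" is operationalized as the ratio band [1/3, 3] (configurable).
The third published relation is printed self-contradictorily
("Km_FRCK > Km_PGI > Km_FRCK"), so neither reading is a silent
default: `frck-pgi-glck` and `inv-pgi-frck` are available as named
presets. The one-order-of-magnitude cross-condition cohesion of each
Km/Ki symbol is checked post hoc (conditions are fitted
independently), not imposed as a joint penalty.

Only steady-state-identifiable quantities are meaningfully recovered;
the recovery acceptance check therefore scores the five analytically
identifiable rate constants, not the full 24-parameter vector, and
additionally requires the fitted steady state to reproduce the
observations to < 1e-3 relative.

## PCA and robustness

The conditions × 14 γ matrix is column-standardized (mean 0, sd 1,
population scaling) and decomposed by full SVD; all components are
kept, so explained-variance fractions sum to 1. Signs are fixed so the
Suc loading is non-positive on every component where it is nonzero
(matching the published loading table's orientation), recorded in the
result. Conditions with undefined γ are excluded with a warning —
imputation would fabricate sensitivity; zero-variance measures are
dropped (they cannot be standardized). The day-0 separation statistic
is |mean(PC1|day 0) − mean(PC1|other days)| over the pooled
within-group sd of PC1 scores, plus a silhouette score of the two
groups along PC1; it is invariant to the sign convention and condition
order. The robustness test multiplies every γ entry by an independent
lognormal factor whose log-sd puts the central 95 % of factors at
±noise_level (default 0.5, echoing the reported worst-case
model-vs-data deviations above 50 %), redoes the PCA, and counts a
repetition as preserving the separation if the statistic stays above
half its noise-free value (a declared threshold).

## The synthetic-data generator

The generator emulates the study design — 5 genotypes (wild type, two
flavonoid-pathway mutants, two starch mutants) × 5 sampling days (day 0
warm, days 1–14 cold) = 25 steady-state realizations — so every stage
of the pipeline is testable without external downloads. Km/Ki values
are drawn as one shared log-uniform condition factor times a small
per-symbol factor, split so that each symbol's cross-condition spread
stays within the cohesion factor (10×) and the base set's
order-relation margins survive — generated studies satisfy the
constraint set by construction. Cold days halve the influx and vmax
capacities with a mild log-linear recovery toward day 14 (acclimation);
genotype defects are multiplicative: k_ANT × 0.1 and k2_exp × 0.5 for
the flavonoid archetypes (the study reports the lowest k_ANT and k_r2
values for those mutants), k_STA × 0.25 for the starch-synthesis-
deficient archetype and × 0.5 for the degradation-deficient one. The
0.25 floor (rather than 0.1) keeps the G6P pool within the
experimentally observed tens of µmol gDW⁻¹; at 0.1 the model's
starch-deficient regime accumulates G6P an order of magnitude beyond
it. Observation noise is multiplicative lognormal with CV 0.1 by
default (the scale of 4–6-replicate dispersion in the experiments).
Base parameters put the wild-type day-0 pools at F6P ≈ 2.6, G6P ≈ 25,
Suc ≈ 2.4, Frc ≈ 0.9, Glc ≈ 1.0 µmol gDW⁻¹ — inside the measured
ranges.

What the generator does **not** emulate: the published fitted parameter
values themselves, diurnal dynamics, compartmentalization, or any
correlation structure between enzymes beyond the shared Km/Ki factor.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and self-consistent under the study's design, not that the
published biological conclusions re-derive from measured data. The
planted-structure generator for PCA tests supports additive planting
(exact low rank; used for variance-recovery oracles) and log-scale
planting (the natural scale for positive scores under multiplicative
noise; used for separation and robustness oracles).

## Numerical choices and degenerate inputs

* Integrator LSODA, rtol 1e-9/atol 1e-12 for protocol simulations,
  tighter (1e-10/1e-12) inside steady-state solving; perturbations are
  instantaneous parameter steps, not ramps.
* Newton refinement operates on |state| so transient small negatives
  cannot leave the domain; positivity is asserted in tests.
* Control coefficients of measures that vanish at the base point or
  under perturbation are missing (NaN) with a warning, and excluded
  (with a logged count) from frequency analyses.
* Pipeline outputs are UTF-8 comma-separated text with '.' decimals;
  the run manifest records package version, seed, and a SHA-256
  configuration hash; a fixed seed reproduces every artifact
  bit-for-bit.

## Known limitations

* No compartmentalization (plastid/cytosol lumped), no UDP-glucose
  pool, no explicit starch or anthocyanin state variables — inherited
  simplifications of the source model.
* SBML export is not provided; the parameter/observation tables and
  their JSON equivalents are the interchange formats.
* The 24-parameter steady-state fit is structurally unidentifiable
  beyond the five pinned rate constants; fitted Km/Ki values are
  bounded and ordered but not unique.
* The linear "proportional response" limit of the sensitivity score is
  only realizable on the F6P branch (see the PGI note above).
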