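# Methods

`ldopapop` models the disposition of intravenously infused L-DOPA in the
unilateral rat rotenone model of Parkinson's disease: plasma
pharmacokinetics, transport across the blood-brain barrier (BBB) into the
striatal extracellular fluid (ECF) of each cerebral hemisphere, and the
intra-brain conversion of L-DOPA — via dopamine, which is itself
unquantifiable in dialysate — into DOPAC and HVA.  The package contains a
synthetic-trial generator that reproduces the original study design, a
nonlinear mixed-effects (population) estimation engine, the
hemisphere-symmetry hypothesis grid, microdialysis recovery calibration,
and tyrosine-hydroxylase (TH) responder classification.

## Structural model

Nine compartments:

| # | state | unit | content |
|---|-------|------|---------|
| 1 | amount / V1 | ng, mL | plasma (central) |
| 2, 3 | amount / V2, V3 | ng, mL | plasma peripherals (Q2, Q3) |
| 4 | amount / V4 | ng, mL | brain ECF L-DOPA, control hemisphere |
| 5 | amount / V5 | ng, mL | brain ECF L-DOPA, diseased hemisphere |
| 6, 8 | concentration | pmol/mL | DOPAC, control / diseased |
| 7, 9 | concentration | pmol/mL | HVA, control / diseased |

Central elimination is Cl/V1; plasma-brain exchange is bidirectional via the
inter-compartmental clearances Q4 and Q5 (a saturable LAT-1 formulation is
deliberately out of scope: the data support no transport asymmetry or
concentration dependence); brain elimination is first order (k40, k50).

**Endogenous synthesis.** Baseline ECF L-DOPA is maintained by a zero-order
input `Kin` into each brain-ECF compartment.  `Kin` is implemented in
ng/min although the historically printed unit label is 1/min; a first-order
reading has no source amount in this model and cannot sustain a nonzero
baseline in a linear system.  The printed label is preserved as metadata
(`defaults.PARAMETER_UNITS`).  The implied plasma baseline (endogenous
L-DOPA leaking back across the BBB) is ~1.5 x 10^-3 ng/mL at the default
values — three orders of magnitude below the 1 ng/mL plasma quantification
limit, consistent with endogenous plasma L-DOPA being unmeasurable.

**Metabolites.** DOPAC and HVA compartments have no estimable volume and
are concentration states (pmol/mL): formation is first order in the parent
ECF concentration (converted ng/mL -> pmol/mL through the L-DOPA molar
mass, 197.19 g/mol), elimination first order (k60/k80, k70/k90).
Metabolite formation does not deplete the parent; the conversion loss is
part of k40/k50.

**Symmetry constraints.** The hemisphere-symmetry hypotheses tie diseased
to control parameters: Q5=Q4, V5=V4, k50=k40.  Each tie removes exactly one
free parameter; all eight subsets form the assumption grid.

Default parameter values (`defaults.py`) are the published population
estimates for this design — e.g. Cl 30 mL/min, V4 13,300 mL (an *apparent*
volume; no physiological reading is attempted), Kin 5.8, shared
k40 = k50 = 0.175 1/min in the accepted symmetric parent model.  The
sequential metabolite sub-models re-estimate their own hemisphere parent
elimination (0.53/0.36 for the DOPAC fits, 0.19/0.14 for HVA), mirroring
the sequential analysis that produced them.  One printed inconsistency is
carried as-is: discussion text elsewhere quotes the control HVA elimination
as 0.044 1/min while the estimate table prints 0.0044; the table value is
used.  A second one is noted but cannot be repaired: at the default values
the brain path adds ~44 mL/min of apparent plasma clearance on top of
Cl = 30, which is why the plasma-clearance recovery exercise uses the
plasma-only three-compartment model, where Cl is the total clearance.

## Solver

Between dose switch points the system is linear and time invariant, so
each segment is solved exactly by eigendecomposition of the rate matrix;
window-averaged states (microdialysis collects continuously over an
interval) use the closed-form segment integral.  The solver is vectorised
over a batch axis — subjects x finite-difference perturbations x outer
optimisation points — which is what makes population fits affordable.
Elements whose matrix is singular or numerically non-diagonalisable
(checked by a reconstruction residual < 1e-8) fall back to an augmented
matrix exponential per segment (SciPy `expm`), which also yields the
running integral exactly and handles deliberately closed systems
(mass-balance checks).  Trajectories agree with an independent per-interval
matrix-exponential oracle to < 1e-6 relative over 100 random log-uniform
parameter draws spanning 4 decades, and with `solve_ivp` at rtol 1e-11 to
~1e-9.

## Synthetic-trial generator

The generator reproduces the study conditions; its defaults are not tuning
knobs.  Three IV dose groups (10/25/50 mg/kg over 20 min, 4/4/5 rats for
plasma), body weight N(288, 13) g, the printed plasma schedule (-5 to 360
min), dialysate windows (10-min to 120, 20-min to 180, 30-min to 360, plus
three 10-min pre-dose baseline fractions), retrodialysis (6 fractions,
perfusate 10/100/200 ng/mL by dose group, 5% proportional measurement
noise), probe recovery drawn once per animal from N(0.30, 0.06) truncated
to (0, 1], responder prevalence 12/17 with TH% < 40 for responders and
> 90 for non-responders.  Inter-individual variability is lognormal
(parameter_i = typical x exp(eta_i)) on exactly the parameters the study
flagged; residual error is proportional for L-DOPA (SD 0.087 plasma, 0.17
ECF) and additive for the metabolites (SDs 0.0020/0.0028/0.0014/0.0034
pmol/mL).  The printed residual-error magnitudes are read as standard
deviations: the proportional entry then reproduces the stated 8.7% CV; the
additive entries' unit is not printed and is taken as the concentration
unit of the fit (pmol/mL).

Design choices: dialysate observations are time-averages of the ECF
concentration over the collection window (continuous 2 uL/min collection),
with a midpoint mode available for sensitivity checks; the probe recovery
multiplies L-DOPA dialysate only (the study corrected only L-DOPA);
negative metabolite concentrations from additive error are clamped to zero
and logged, not resampled (resampling would bias the error distribution);
below-LOQ rows are flagged and excluded from fitting (M1) — there is no
censoring likelihood to reproduce, and dopamine is below LOQ everywhere and
never simulated.  The ECF L-DOPA dialysate LOQ is set to 1e-4 ng/mL: it is
not printed, but the assay demonstrably resolves the ~0.005 ng/mL baselines,
so the LOQ must lie well below them.  Diseased-hemisphere data are
generated only for responders; cohort factories pin the printed n's
(13 plasma, 12 control-ECF, 7 diseased-ECF, 8 diseased-metabolite).
Randomness descends from one root seed through per-subject child streams,
so populations are reproducible and subjects independent of cohort size.

What the generator does **not** emulate: assay chemistry and drift, probe
failure beyond a simple exclusion, carryover in the washout phase,
circadian or handling effects, model misspecification (data are generated
from the fitted model family).  Passing recovery tests therefore
demonstrate estimator correctness under the study design, not robustness
to real-data violations.

## Estimation

The marginal likelihood over random effects is approximated by a Laplace
expansion around each subject's conditional mode (empirical Bayes
estimate) with the interaction convention: proportional residual variances
are evaluated at conditional predictions.  This is the same approximation
family as FOCE-I; it is fully specified here rather than re-implemented
instruction-for-instruction, and the objective includes the full
-2 log-likelihood constant (2*pi terms), so absolute values differ from
other software by a data-dependent constant and only differences are
compared.  With all IIV variances zero the objective reduces exactly to
the naive-pooled -2 log-likelihood; on a one-compartment single-subject
problem it agrees with adaptive quadrature over eta to < 0.02 units.

Inner problem: per-subject Newton on g(eta) with a Gauss-Newton-plus-
interaction Hessian, finite-difference prediction Jacobians (central,
step 1e-4), a trust-region cap of 2 log units per step, persistent step
damping, and an Aitken-style acceleration when the gradient decays
geometrically (without it, occasional subjects crawl in a linear-
convergence tail).  Freeze at gradient < 1e-4 or improvement < 1e-8.
Outer problem: L-BFGS-B on log-transformed free parameters (typical
values, IIV variances, residual SDs) with batched forward-difference
gradients (step 1e-4); multi-start (init, x2, /2) by default.  Parameters
are unbounded on the log scale — positivity is built into the transform.
Standard errors come from the delta method on the inverse of half the
central-difference Hessian of the objective (computed in a single batched
evaluation); CIs are estimate +/- 1.96 SE and CV% = 100 SE/estimate.  A
non-positive-definite Hessian leaves SEs empty and flags the fit — the
grid reports such cells as failed in place ("minimisation terminated"),
as happens for one assumption combination in the original analysis.

Sequential metabolite analysis: each rat's parent disposition is fixed at
its empirical Bayes parent parameters; the hemisphere's formation,
parent-elimination and metabolite-elimination constants, their IIV and the
additive SD are estimated from the dialysate concentrations; DOPAC and HVA
are fitted independently per hemisphere.

Model selection: a drop of >= 10.8 objective points for one added
parameter (chi-square, p = 0.001).  Grid decisions with several
constraints use the chi-square quantile at the matching df (13.82 at 2,
16.27 at 3).  The grid selects the most parsimonious cell not
significantly worse than the unconstrained model.  Pre-dose ECF baseline
fractions are included in the parent fit — they are what identifies Kin.

## Microdialysis and TH stages

Retrodialysis: per-fraction relative loss (C_in - C_out)/C_in; fractions
showing net gain are excluded with a warning; the across-animal mean
recovery is applied study-wide (per-subject correction available but off
by default, matching the original analysis).  Baseline summaries use the
per-subject mean of pre-dose fractions, group mean +/- SEM across animals,
and Welch's unequal-variance t-test with Welch-Satterthwaite df.

TH staining: striatal mean grey values corrected by subtracting the
cortical MGV (corpus callosum selectable); TH% is the corrected treated-
hemisphere MGV as a percentage of the untreated side, computed on the
dorsal striatum (the dialysis target) with the ventral striatum reported
alongside; responder iff TH% < 40 (strict).  Slide-background MGV is
recorded but not used in the correction.

## Problem sizes and tolerances

Recovery checks run at the printed cohort sizes (13/12/7/8 rats) — the
quantity of interest is whether the printed confidence intervals cover the
recovered values across seeds, so inflating n is unnecessary; seed counts
are 10-20 per check.  Fits in the test-suite and reproduction script use
a single start from the default values (the published estimates) with
iteration caps chosen at the point where doubling them no longer changed
the estimates (parent fit: identical to 3 decimal places between caps of
80 and 150); the hemisphere-symmetry decision checks fix plasma
disposition at truth and disable IIV, isolating the brain-side contrast
the decision is actually about.

## Known limitations

- Diagonal Omega (no eta correlations; the study does not state any).
- No covariate modelling: TH% is bimodal (< 40 or > 90) by design, leaving
  no range to support a covariate, and none is attempted.
- No SAEM/MCMC alternative estimator and no bootstrap CIs.
- Absolute objective values are not comparable with other NLME software;
  only differences are.
- Wald CIs only; the profile-likelihood check (objective rises by ~3.84 at
  a 95% Wald bound) agrees within 25% for structural parameters but can be
  asymmetric for parameters that trade off with their own IIV variance.
- The generator draws data from the model family being fitted; estimator
  robustness to structural misspecification is untested by design.
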