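# Methods

## The kinetic model

The methionine metabolism cycle is represented as seven well-stirred
compartments with first-order transfer throughout: methionine peripheral
(A1) and central (A2), SAM (A3), SAH (A4), homocysteine central (A5), a
cysteine/cystathionine sink (A6) and homocysteine peripheral (A7). Doses —
IV boluses and simulated dietary methionine alike — enter A2
instantaneously; the model has no absorption compartment. The only true
elimination is K_EL out of A2; transsulfuration (K_HC) moves mass into the
absorbing sink A6 but keeps it inside the state vector, so with K_EL = 0
total mass is conserved exactly. Both plasma analytes are scaled by the
single reported apparent volume Vc (no separate homocysteine volume is
available). Amounts are carried in mmol per kg body weight and times in
hours (the sampling design, specified in minutes, is converted on ingest),
so concentrations are mmol/L.

Two modelling choices deserve a note:

- **The transsulfuration sink.** Statements of this system sometimes write
  the A6 balance with source K_HC·A4. We use K_HC·A5, matching the
  K_HC·A5 outflow in the A5 equation and the definition of K_HC as the
  homocysteine→cysteine rate. A6 is a pure sink, so plasma predictions are
  identical either way; only mass conservation distinguishes the forms.
- **No endogenous baseline.** The system has no zero-order production, so
  trajectories are dose-derived amounts above baseline, and pre-dose
  samples predict zero.

Linearity makes the solution a superposition of matrix exponentials. The
exact solver diagonalises M once per parameter set and propagates the state
segment-by-segment between doses (O(n_times + n_doses) work), falling back
to `scipy.linalg.expm` if the eigenbasis is ill-conditioned. A stiff BDF
integration (`solve_numeric`) exists purely as an independent cross-check:
K_SS ≈ 3220 h⁻¹ against rates of order 0.1 h⁻¹ makes the system stiff, and
the two routes agree to a relative 10⁻⁶ in the tests. An output time equal
to a dose time follows the 0⁺ (post-dose) convention on simulation grids and
the pre-dose (trough) convention for observation records.

## Covariates, variability and error

Diabetic (ZDF) status is a dichotomous covariate. The five rate constants
whose typical values differ between groups (K_SH, K_HM, K_HC, K_HP, K_PH)
each carry one multiplicative group factor, the ratio of the ZDF to the
control typical value; K_HM and K_HP additionally carry log-normal subject
random effects η₁, η₂. With ZDF = 0 and η = 0 the individual parameters
reproduce the control typical values exactly.

The published inter-individual variabilities are %CVs (70.1% on K_HM,
45.4% on K_HP); they are converted to random-effect SDs by
ω = √ln(1 + (CV/100)²). The residual-error magnitudes of the source
analysis are not published; the packaged defaults are σ_prop = 0.15
(15% proportional) and σ_add = 0.01 mmol/L, typical assay-scale values for
LC-MS/MS plasma concentrations, both configurable in the preset files. At
late homocysteine time points the additive floor dominates the signal,
which is the main reason the control-group K_SH is only weakly identified
(see Limitations).

## Estimation

Each subject's marginal likelihood integrates over η = (η₁, η₂). Writing
g(η) = −2[log p(y|η) + log p(η)] with observation variance
σ_add² + (σ_prop f(η))² evaluated at the conditional prediction (the
"interaction" convention), the objective is the Laplace approximation

    OFV = Σᵢ [ g(η̂ᵢ) − d·log 2π + log det(g''(η̂ᵢ)/2) ].

The conditional mode η̂ is found by a damped Newton iteration whose
gradient and Hessian come from one shared central-difference stencil
(relative step 10⁻⁴); the same Hessian supplies the Laplace curvature. The
gradient tolerance (10⁻³) sits above the finite-difference noise floor of
the matrix-exponential likelihood; because the Laplace value is
second-order insensitive to mode error, this costs < 10⁻⁶ OFV units. Modes
are warm-started across outer iterations, with jittered restarts on
non-convergence. In tests the Laplace OFV tracks an adaptive 21-point
tensor Gauss–Hermite quadrature within 0.5 units on ten-subject datasets;
the residual gap (~0.04 units/subject) is genuine Laplace skew error under
the wide IIV and proportional error, not optimizer noise.

Population parameters are optimized on the log scale by L-BFGS-B inside
±3 log₁₀ box constraints, restarted from three jittered initial points.
RSEs are delta-method standard errors from the inverse finite-difference
Fisher information (2% log-step with Richardson refinement — wide enough
that the curvature signal dominates inner-solver noise). Model comparison
uses ΔOFV against χ² quantiles (the 1-df, α = 0.001 criterion is 10.83);
CWRES standardize residuals by the covariance of the model linearized
about η̂. Observations that fall below zero after noise are retained
unchanged in fitting (no LLOQ rule is imposed), and both analytes are
fitted jointly per subject with shared η.

## Simulation and NCA

"Three times daily" dosing is implemented as strict q8h boluses, which
makes the day-1 accumulation ratio AUC(8–16 h)/AUC(0–8 h) well-posed; the
"AUC over the 8-h interval at 1350 h" endpoint is the AUC over
[1344, 1352] h, the dosing interval containing t = 1350 h. NCA uses the
linear trapezoid throughout on the simulator's dense 0.1 h grid (trapezoid
error < 0.1% for these rate constants, making interpolation-rule choices
immaterial), with linear interpolation at window edges. Group contrasts use
Welch's unequal-variance t test (the source analysis names no test).

One master seed drives everything; each subject's stream derives
deterministically from (seed, group, subject index), so enlarging a
simulated cohort never reshuffles earlier subjects, and VPC replicates
derive from (seed, replicate).

The VPC bins observations by exact nominal time (the design has eight fixed
sampling times), estimates 5th/50th/95th percentiles by linear
interpolation between order statistics on both the observed and simulated
sides, and reports the central 95% envelope of each percentile across
replicates. Plots default to a log concentration axis with a linear option.

## Synthetic data

No individual-animal data are deposited with the source study, so the
generator emulates its design: ZDF and control groups, a single
0.8 mmol/kg IV methionine bolus (the original tracer mixture of unlabelled
and d4-labelled methionine is collapsed into one total dose), plasma
methionine and homocysteine at 0, 10, 30, 60, 120, 210, 300 and 420 min.
The default cohort size is 8 per group — the source study does not print
its group size, and 8 is a typical rodent PK cohort — and t = 0 samples are
emitted pre-dose by default. What the generator does *not* emulate: assay
censoring (LLOQ), inter-occasion variability, endogenous baselines, and
food-matrix absorption kinetics. Passing tests therefore demonstrate
internal consistency of estimator and simulator under the stated model,
not robustness to those real-data features.

## Problem sizes and numerical choices

The packaged experiments use 100 subjects/group for parameter recovery
(single free K_SH per group, everything else fixed at truth), 1000
subjects/group for the day-1 diet simulation, and 150 subjects/group on the
dense 0.1 h grid for the 60-day diet — sizes at which the Monte-Carlo error
of each reported mean is far below its comparison tolerance. Solver
tolerances: BDF cross-check at rtol 10⁻⁹/atol 10⁻¹²; eigenbasis condition
cut-off 10¹⁰ before the expm fallback; compartments are non-negative within
−10⁻¹⁰ on all tested regimens. Ties in Tmax resolve to the earliest time.
A VPC needs at least 40 replicates for its 95% envelopes to be meaningful;
fewer is an error.

## Known limitations

- **Control-group K_SH is weakly identified.** With K_SS and K_SH fast
  relative to sampling, SAH is near quasi-steady state and K_SH nearly
  cancels from the plasma homocysteine profile; identification rests on the
  first minutes of the transient. Single-free-parameter recovery at
  n = 100/group scatters with SD ≈ 8–10% around the truth (the source
  analysis itself reports 20.5% RSE for control K_SH, 106.6% for ZDF).
- **Laplace, not exact, marginal likelihood.** Bias is small but nonzero at
  these noise levels; no SAEM/importance-sampling alternative is provided.
- **Day-1 ZDF accumulation.** Under the packaged final parameters the model
  yields a mean day-1 methionine accumulation ratio of ≈ 1.04 in ZDF rats
  and ≈ 1.12 in controls, and a ZDF homocysteine ratio of ≈ 1.22. Published
  summaries of these endpoints pair the numbers differently across
  groups/analytes and are mutually inconsistent; this package reports what
  the model computes. Likewise the 60-day homocysteine interval-AUC
  contrast computed from the model (≈ 14-fold, ZDF over control) is far
  larger than the ≈ 3-fold figure sometimes quoted, while the 60-day
  methionine contrast (≈ 2-fold) agrees.
- AUC_total carries no terminal-slope extrapolation; it is the area to the
  end of the simulated window.
- Human extrapolation, saturable enzyme kinetics and tissue-level SAM/SAH
  submodels are out of scope.
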