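# Methods

`remipkpd` implements a population pharmacokinetic/pharmacodynamic (PK/PD)
analysis of the ultra-short-acting benzodiazepine remimazolam tosilate
(HR7056) given as short intravenous infusions, together with a
Monte-Carlo trial simulator for loading + maintenance dosing regimens and
a synthetic-trial generator that reproduces the first-in-human ascending
single-dose study design. This note documents the models, the estimation
machinery, the numerical choices, and what the synthetic data can and
cannot demonstrate.

## Structural pharmacokinetic model

Drug disposition follows a three-compartment mammillary model
parameterised as clearances and volumes, driven by zero-order infusions:

    dA1/dt = in(t) − (CL + Q2 + Q3)/V1 · A1 + Q2/V2 · A2 + Q3/V3 · A3
    dA2/dt = Q2/V1 · A1 − Q2/V2 · A2
    dA3/dt = Q3/V1 · A1 − Q3/V3 · A3

with arterial plasma concentration Cp = A1/V1. Time is in minutes, doses
in mg, volumes in L and clearances in L·min⁻¹; amounts are carried in µg
so that Cp comes out in ng·mL⁻¹ (≡ µg·L⁻¹). The published typical values
(V1 2.11 L, CL 1.49 L·min⁻¹, V2 10.5 L, Q2 0.96 L·min⁻¹, V3 22.7 L,
Q3 0.27 L·min⁻¹; Vss = 35.3 L) are shipped in `remipkpd.published` and
serve as the data-generating truth everywhere.

Each PD endpoint is linked to plasma through its own hypothetical effect
compartment, dCe/dt = ke0·(Cp − Ce), appended as an additional linear
state. The 1-min "injection" is modelled as a 1-min zero-order infusion,
never as a bolus.

Because the whole system is linear with piecewise-constant inputs, the
solver diagonalises the rate matrix once per subject and evaluates the
response of each infusion event in the eigenbasis, superposing events.
This is exact (no step-size error) and fast enough for 1000-subject
Monte-Carlo runs and for the many likelihood evaluations inside the
estimator. If the eigendecomposition looks unreliable (eigenvalue gap
below 10⁻⁸ of the spectral radius, complex parts above 10⁻⁹, or
non-finite output — e.g. a collapsed compartment with Q = 0), the solver
falls back to a piecewise matrix-exponential propagation on the augmented
system, which handles repeated eigenvalues exactly. An adaptive stiff ODE
integration (LSODA at rtol 10⁻¹¹) is kept in the test suite as an
independent oracle; the two agree to better than 10⁻⁶ relative on the
typical subject over 0–480 min.

## Inter-individual variability and residual error

Every structural parameter carries log-normal inter-individual
variability, θᵢ = θ_TV·e^ηᵢ with ηᵢ ~ N(0, ω²) independent across
parameters (diagonal Ω, as only per-parameter variabilities were
reported). The reported IIV percentages are used directly as log-scale
SDs (ω ≈ CV).

Residual error: concentrations use a proportional model
y = Cp·(1 + ε), σ = 0.138, with negative draws truncated at zero and
flagged. BIS uses a multiplicative (log-scale additive) residual by
default, y = BIS·e^ε with σ = 0.0653: the reported magnitude is far too
small to be additive on a 0–100 scale but is a plausible ≈6.5% CV, and a
multiplicative model also cannot produce the BIS > 100 artefacts that a
symmetric additive error allows at baseline. A strictly additive variant
remains available (`residual_model="additive"`).

## BIS model

Sigmoid inhibitory Emax: E = E0 − Imax·Ce^γ/(IC50^γ + Ce^γ), with E0
95.3, Imax 47.9, IC50 503 ng·mL⁻¹, γ 1.50, ke0 0.0855 min⁻¹
(equilibration half-life ln2/ke0 = 8.1 min). IIV applies log-normally to
all five parameters; individuals violating the physical constraint
E0 − Imax ≥ 0 (BIS cannot go negative) are redrawn, with a bounded number
of retries.

## MOAA/S model

MOAA/S (5 fully alert … 0 unresponsive) is modelled with a cumulative
logit (proportional odds) structure: for k = 0..4,

    logit P(score ≤ k) = B_{k+1} + Imax·Ce^γ/(IC50^γ + Ce^γ) [+ η]

with P(score ≤ 5) = 1 and category probabilities by differencing. The
strictly increasing baselines (−8.52, −2.44, −1.30, −1.15, −0.895) plus
the shared drug shift guarantee non-negative probabilities at any
concentration. The MOAA/S endpoint has its own effect compartment,
ke0 = 0.05 min⁻¹ (half-life 13.9 min), independent of the BIS track.

Two details were genuinely open:

- The model equation carries an additive subject-level logit η, but the
  reported parameter table lists IIV on ke0, IC50, γ and Imax and no
  variance for an additive η. Default: log-normal IIV on the four
  parameters and no extra logit η; the literal additive-η mode is
  available through `eta_sd`.
- The baselines imply P(score ≤ 4) ≈ 0.29 at zero drug — a nontrivial
  probability of non-alert scores pre-dose. This is retained as a
  property of the published model, not "fixed".

## Estimation

The mixed-effects fits use a Laplace approximation to the marginal
likelihood. Per subject, the joint −2 log density of (data, η) is
minimised over η by a damped Newton iteration whose gradient and Hessian
come from batched central finite differences (step 10⁻³); steps are
capped, fall back to steepest descent when the Newton direction fails,
and etas are kept inside |η| ≤ 30. The subject contribution is

    −2LLᵢ = m2(η̂) + log det(H/2) − d·log 2π,

with m2 the joint −2 log density and H its Hessian at the mode. For a
linear-Gaussian model this is exact; on one-dimensional toy problems it
agrees with a 51-node adaptive Gauss–Hermite quadrature oracle to well
within 0.1 OFV units (continuous and categorical likelihoods). This is a
Laplace stand-in for the original analyses' FOCE-I; the exact interaction
terms of commercial implementations are not replicated.

Population parameters (log-transformed fixed effects, log-ω, log-σ;
category baselines and covariate coefficients untransformed) are
estimated with L-BFGS-B on the total −2LL with finite-difference
gradients. One subtlety proved load-bearing: the inner η-search is
warm-started from the modes of the *best outer point seen so far*, never
from the previous evaluation. Warm-starting from the last point makes the
objective depend on the evaluation order, which corrupts the
finite-difference gradients and can stall the optimiser far from the
optimum; pinning the starting modes to the incumbent best point keeps
every gradient group consistent. Multi-start (jittered initials) is
available; convergence is reported from the optimiser status, the OFV
trajectory keeps only accepted (improving) values, and AIC = OFV + 2p.
Standard errors, when requested, come from a central-difference Hessian
of the OFV with the delta method back to the natural scale (RSE% of a
log-transformed parameter is 100·SE of its log).

The PD models are estimated by the study's two-stage workflow: the PK fit
supplies empirical Bayes (conditional-mode) parameters per subject, each
subject's concentration and effect-site profiles are fixed at those
values, and the BIS / MOAA/S population parameters are then maximised
with the PK stage frozen.

For the MOAA/S stage the reference workflow estimates IC50, ke0 and the
variabilities conditional on the five baselines, γ = 1.50 and Imax. The
reason is identifiability, and it is worth being explicit about: the drug
term saturates the cumulative logits once it exceeds a few units, so a
steeper/lower-midpoint curve and a shallower/higher-midpoint curve fit a
63-subject single-ascending-dose design almost equally well — IC50, γ and
Imax lie on a flat likelihood ridge. Estimated jointly, replicate
synthetic trials scatter the IC50 estimate by roughly ±40%; conditioned
on γ and Imax its replicate spread drops to ~15%, matching the precision
reported for the original analysis (and the identical γ in both PD tables
suggests at least γ was fixed there as well). Fully free fits remain
available through the `fix` argument.

Covariate screening follows the reported procedure: weight, height, age
(power or linear, centred at the study medians) and a sex shift are added
one at a time and judged by the OFV drop against the χ²₁ thresholds
3.84 / 6.63 / 10.83 (α = 0.05 / 0.01 / 0.001). Profile-likelihood
confidence intervals re-optimise all other parameters at fixed values of
the target parameter and bisect for the OFV rise of χ²₁(0.95) = 3.84,
flagging bounds not bracketed within ten standard errors as open.

## Synthetic trial generator

The generator reproduces the study design: 63 subjects in 11 ascending
cohorts (0.01–0.45 mg·kg⁻¹ over 1 min; default allocation
3,4,4,6,6,6,6,7,7,7,7 — the true per-cohort split was not published, so
it is configurable), arterial PK samples at pre-dose and 18 post-dose
times to 480 min, BIS and MOAA/S at pre-dose and 18 times to 120 min,
giving exactly 1197 records per endpoint. Body weight is drawn from a
log-normal with median 63.8 kg and 9% CV truncated to the observed
52.8–83.8 kg (a uniform draw would misplace the median at 68.3 kg); BMI
is drawn within the entry window and height derived from it; ages are
uniform over 18–44; sex follows the reported 51:12 ratio. Pre-dose
concentrations are recorded as zero and flagged below the 0.5 ng·mL⁻¹
quantification limit, as is any later record under that limit; flagged
records are retained in the files but excluded from likelihoods by
default.

What passing on these data shows — and does not. The generator draws
from exactly the model family the estimator assumes, with nominal
sampling times, no dropout, no assay bias and no model misspecification.
Successful parameter recovery therefore validates the estimation
machinery and the identifiability of the design, not the model's adequacy
for real patients; conversely the VPC calibration check on self-simulated
data verifies the diagnostic, not the model.

## Monte-Carlo regimen simulation

Virtual subjects get independent log-normal draws of all PK, BIS and
MOAA/S parameters and, by default, uniform body weights over the study
range (weight only scales the mg/kg dosing). Effects are model
predictions without residual error, matching how regimen performance is
normally displayed. The default grid is 0.5-min spacing over 0–240 min,
fine enough to resolve the 1-min loading infusion.

Summary definitions:

- "Reached modal MOAA/S 0 by t": the subject's predicted P(score = 0)
  exceeded 0.5 at some time ≤ t. Modal (probability > 0.5) summaries are
  the default; sampled-score summaries are available via
  `pd_moaas.sample_scores`.
- Target attainment: longest contiguous run with P(score < 2) > 0.5 of at
  least 90 min.
- BIS band occupancy: fraction of the 30–120 min window in which the
  pointwise median BIS lies in [60, 65]. The window starts at 30 min to
  exclude the post-loading transient, during which the claim is not meant
  to hold.
- The maintenance window for the P(MOAA/S < 2) summary runs from 5 min
  (sedation is fully established within ~4 min of the loading dose) to
  the end of the maintenance infusion at 121 min; the single grid point
  at the very start of maintenance still reflects induction onset, not
  maintenance performance.

Grid-search ranking scores each candidate maintenance rate by the product
of target-attainment fraction and BIS band occupancy under common random
numbers, so a regimen must both keep subjects unconscious and avoid
overshooting the BIS band.

## Diagnostics

GOF tables report PRED (η = 0), IPRED (η at the EBE) and CWRES computed
from the first-order linearisation around the EBE: the model Jacobian G
in η gives the marginal covariance GΩGᵀ + R (R proportional to the
linearised prediction for the concentration and multiplicative-BIS
models), and the population residual y − (F(η̂) − Gη̂) is whitened by its
Cholesky factor. VPCs re-simulate the fitted (or evaluated) model under
the observed design — default 500 replicates, bins at the distinct
nominal times — and compare observed 5/50/95th percentiles (per-category
frequencies for MOAA/S) with the 95% interval of the same statistic
across replicates. Prediction correction rescales by bin-median PRED over
subject-time PRED; the LLOQ lower-bound term is omitted, but simulated
concentration replicates are censored at the LLOQ exactly as the
observations were, which matters in low-dose cohorts. Coverage statements
across bins are correlated (all bins share the same subjects), so
small-trial coverage fluctuates more than a binomial count would suggest.

## Problem sizes used in the checked experiments

The test suite keeps every stochastic experiment at a size where it runs
in minutes: the regimen simulation uses the full 1000 virtual subjects;
single-trial parameter recovery uses the full 63-subject design with
starting values perturbed ×1.3 off the truth; the replicate-bias check
uses twenty 12-subject replicates with the variability and residual
parameters held at truth (bias of the fixed effects is the question
there, and this keeps twenty maximisations affordable); VPC calibration
uses 300–400 replicates. Optimiser stopping for the large fits uses a
projected-gradient tolerance of 0.05 on the OFV scale, which locates
parameters to well under a percent — far tighter than any tolerance
checked.

## Known limitations

- Laplace ≠ exact FOCE-I; small systematic OFV offsets against
  NONMEM/Phoenix are expected, though parameter estimates agree closely.
- Diagonal Ω only; no η correlations.
- The real study's observed-data results (measured exposure, recovery
  times, concentration at loss of consciousness) are not reproducible
  from synthetic data and are out of scope.
- BQL records are excluded rather than integrated (no M3-style
  likelihood).
- Covariate relations are limited to power/linear/sex-shift forms on the
  PK parameters.
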