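# remipkpd

Population pharmacokinetic/pharmacodynamic (PK/PD) modelling and
dose-regimen simulation for the ultra-short-acting intravenous sedative
remimazolam tosilate (HR7056).

Remimazolam is a benzodiazepine designed to be hydrolysed by nonspecific
tissue esterases, giving very fast onset and recovery. Planning its use
for induction and maintenance of anaesthesia requires a quantitative
chain from infusion rate to plasma concentration to depth of sedation.
This package implements that chain for two sedation endpoints — the
continuous Bispectral Index (BIS) and the ordinal Modified Observer's
Assessment of Alertness/Sedation score (MOAA/S, 5 = alert … 0 =
unresponsive) — for pharmacometricians and anaesthesia trialists who want
to re-estimate the models on trial-format data, simulate candidate
regimens, or test estimation workflows on a faithfully synthetic copy of
the first-in-human ascending-dose study.

## The models

**Kinetics.** A three-compartment mammillary model with zero-order
infusion input, parameterised as clearances/volumes (CL, Q2, Q3; V1, V2,
V3), solved exactly via eigendecomposition of the linear system. Each
endpoint has its own effect compartment, dCe/dt = ke0·(Cp − Ce).

**BIS.** Sigmoid inhibitory Emax:
E = E0 − Imax·Ce^γ / (IC50^γ + Ce^γ).

**MOAA/S.** Cumulative-logit (proportional odds) model:
logit P(score ≤ k) = B_{k+1} + Imax·Ce^γ/(IC50^γ + Ce^γ), k = 0..4, with
P(score ≤ 5) = 1 and category probabilities by differencing.

**Population structure.** Log-normal inter-individual variability on
every parameter, θᵢ = θ_TV·e^ηᵢ; proportional residual error for
concentrations, multiplicative for BIS. Estimation is by
Laplace-approximate marginal maximum likelihood with empirical Bayes
individual estimates, using the study's two-stage PK→PD workflow;
likelihood-ratio covariate screening (ΔOFV 3.84/6.63/10.83), AIC model
comparison, profile-likelihood confidence intervals, CWRES
goodness-of-fit and (prediction-corrected) visual predictive checks are
included. `remipkpd.published` ships the published final-model estimates
(CL 1.49 L·min⁻¹, V1 2.11 L, BIS IC50 503 ng·mL⁻¹, MOAA/S IC50
436 ng·mL⁻¹, …), which drive the synthetic-trial generator and the
Monte-Carlo regimen simulator.

See `docs/methods.md` for the full model and algorithm description.

## Worked example

`examples/simulate_regimen.py` evaluates the candidate anaesthesia
regimen — 0.4 mg/kg loaded over 1 min, then 1.5 mg/kg/h for 2 h — on
1000 virtual subjects:

```
$ python examples/simulate_regimen.py
subjects reaching modal MOAA/S 0 within 10 min: 93.8%
min population P(MOAA/S < 2) during maintenance: 98.4%
median BIS over 30-120 min: 59.9 - 61.7
target attainment (MOAA/S < 2 for >= 90 min): 99.9%
```

Roughly nine in ten virtual subjects are deeply sedated (modal MOAA/S 0)
within ten minutes of the loading dose; the population probability of
loss of consciousness (MOAA/S < 2) stays above 90% throughout the
maintenance infusion; and the median BIS sits at the lower edge of the
60–65 band targeted for surgical anaesthesia — together the signature of
a regimen that induces quickly and holds a stable, adequate depth.

Other examples, one per capability (each prints what its numbers mean):

- `examples/generate_trial.py` — synthetic 63-subject ascending-dose
  trial (1197 records per endpoint) written as an event-record CSV
- `examples/fit_pk.py` — mixed-effects PK estimation from perturbed
  starting values on a small trial
- `examples/two_stage_pd.py` — the two-stage PK→PD workflow for BIS
- `examples/dose_ranging.py` — ranking candidate maintenance rates
- `examples/vpc_check.py` — visual predictive check calibration

A thin command-line interface wraps the same pipeline:

```bash
remipkpd generate --seed 1 --out trial/
remipkpd fit --data trial/trial.csv --model pk --out fit/
remipkpd simulate --n 1000 --seed 1 --out sim/
remipkpd vpc --data trial/trial.csv --model pk --out vpc/
```

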