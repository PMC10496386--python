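# Methods

This document describes the model implemented in `psmcea`, its inputs, its
numerical choices, the scope of the synthetic-data machinery, and known
limitations. Every empirical claim here is computed by the package itself
(see `tests/` and `scripts/acceptance.py`).

## 1. Decision problem

Three strategies for second-line treatment of advanced intrahepatic
cholangiocarcinoma are compared from the Taiwan single-payer perspective in
2022 NT$: pemigatinib (intervention, *FGFR2*-rearranged patients), mFOLFOX
and 5-FU (comparators). Willingness to pay (WTP) is NT$2,928,570 per QALY.

## 2. Model structure

A partitioned survival model with three states — progression-free (PF),
progressed disease (PD), dead — over a 5-year horizon in monthly cycles
(1/12 year). State occupancy at time `t` (months) is read directly off the
arm's survival curves:

```
PF(t) = min(PFS(t), OS(t));   PD(t) = OS(t) − PF(t);   dead = 1 − OS(t)
```

The `min` clip guarantees non-negative PD occupancy when the extrapolated
PFS tail crosses the OS tail. Occupancy is evaluated at cycle midpoints
(half-cycle correction); costs and QALYs accrue as

```
value = Σ_cycles rate × occupancy(midpoint) × Δt × (1 + r)^(−t_years)
```

with annual discount rate r = 3%. Cost components per arm: annual
medication and non-medication rates over PF time, an annual supportive-care
rate over PD time, and a one-off genetic testing fee of NT$30,000 at t = 0
for arms requiring molecular screening (the intervention arm, by default —
see §7). Utilities: 0.76 (PF), 0.68 (PD); an intravenous-administration
disutility of 0.025 applies to the chemotherapy arms' PF utility; a grade ≥3
adverse-event disutility of 0.16 is applied to the arm-specific AE
proportion for one cycle (configurable to the first six months or the whole
horizon, weighted by alive occupancy).

## 3. Survival inputs

All times in months. Parametrisations:

- Weibull (accelerated-failure-time form): `S(t) = exp(−(t/λ)^k)` —
  pemigatinib OS: λ = 22.065, k = 1.536.
- Log-normal: `S(t) = 1 − Φ((ln t − μ)/σ)` — all other endpoints
  (pemigatinib PFS 1.962/0.971; mFOLFOX OS 1.834/0.873, PFS 1.430/0.754;
  5-FU OS 1.764/0.816, PFS 0.8/1.067).
- Generalized gamma (Prentice μ/σ/Q) is implemented and reduces exactly to
  Weibull at Q = 1 and log-normal at Q = 0; survival is evaluated through
  regularized incomplete gamma functions.

The survival module also provides Kaplan–Meier estimation and right-censored
maximum-likelihood fitting (delegated to `lifelines`, with multiple starts
and an independently recomputed log-likelihood/AIC/BIC), and a hybrid
KM-then-parametric-tail construction with continuity rescaling at the
switch point.

## 4. Decision metrics

ICER = ΔC/ΔE on unrounded totals, with dominance tagged instead of reported
as a ratio when the increment signs disagree. INMB = WTP·ΔE − ΔC. The CEAC
reports the fraction of PSA draws with positive INMB across a WTP grid
(0–6M NT$ in 100k steps, always including the threshold). EVPI (pairwise,
per person) = E[max(NMB_i, NMB_c)] − max(E[NMB_i], E[NMB_c]).

## 5. Uncertainty analysis

**Deterministic (tornado).** Each parameter moves one at a time to its
published range bounds (95% CIs for survival parameters, ±25% for costs,
proportions and the testing fee, 0–5% discounting, 3–15-year horizon);
output is the INMB (or ICER) swing, sorted.

**Probabilistic (PSA).** 1000 draws by default. Distributions: normal for
survival parameters (redrawn until positive where required), beta for
utilities and the AE disutility, gamma for costs moment-matched from the
published mean and SD, uniform for the pemigatinib medication cost (±25%)
and testing fee. Each parameter owns a named random substream derived from
the master seed via a CRC-32 spawn key, so draws are bit-reproducible and
insensitive to adding or removing other parameters. AE proportions and
structural settings stay fixed in the PSA and vary only in the tornado.

## 6. Scenarios

A price grid reduces the pemigatinib medication cost by 0–60% in 10% steps;
the price multiplier also scales the bounds of its uniform PSA distribution
so probabilistic results stay centred on the reduced price. Other scenarios:
life-years as the effectiveness measure, a 0.9 conversion factor on
non-medication costs (with an added Uniform(0.8, 1.0) PSA parameter),
longer adverse-event disutility windows, and structural survival-law
replacement hooks.

## 7. Reproduction of the published analysis, and its limits

The shipped fixture reproduces the full published input table. Two findings
from reconciling against the published results:

1. **Testing fee placement.** The published progression-free cost total for
   the intervention arm equals annual-rate × discounted PF years plus the
   NT$30,000 testing fee exactly, so the default testing-fee policy charges
   the fee to the intervention arm (`intervention_only`); `none` and
   `all_arms` are configurable alternatives.
2. **Hybrid-curve gap.** The published analysis extrapolated hybrid
   Kaplan–Meier + parametric curves fitted to non-public patient-level
   data. Back-solving the published cost components for discounted
   state-years implies an mFOLFOX OS restricted mean of 0.799 discounted
   years, which exceeds the *unrestricted* mean of the published
   log-normal(1.834, 0.873) law (0.765 years). No pure-parametric model of
   that law can therefore reproduce the published occupancy; the hybrid
   trial-window KM carried extra survival mass. Consequences, as computed
   here: QALY-scale increments agree closely (ΔQALY 0.627/0.681 vs
   published 0.59/0.68 — the PF/PD utility weights are similar, so the
   PF/PD split error largely cancels), while cost-scale quantities differ
   by ~4–10% (ICER 6.02M/5.86M vs published 5.81M/5.38M NT$/QALY) because
   the tenfold medication-vs-supportive-care rate gap amplifies the split
   error. The price-reduction INMB zero crossing lands between 50% and 60%
   instead of the published 40–50%. No parameter was adjusted toward the
   published outputs. The 5-FU PFS law follows the published parameter
   table (log-normal) even though the published methods text mentions a
   generalized gamma whose third parameter was never printed.

## 8. Synthetic data

Patient-level data are simulated, not recovered: subjects draw one shared
uniform per subject mapped through the inverse survival functions of OS and
a candidate progression law (comonotonic frailty coupling), with
progression-free time the minimum of the two, so PFS ≤ OS holds subject by
subject and identical laws yield identical times. Administrative censoring
applies at a fixed follow-up horizon. Built on this are a
simulate-and-refit harness (bias, RMSE, 95% Wald coverage, AIC family
selection; at n = 1000 per arm, coverage of the Weibull OS parameters
exceeds 88% over 50 replicates) and an end-to-end check in which the whole
CEA is re-run with refitted laws (at n = 5000 per arm the refitted
incremental QALYs sit within 0.05 of the truth). The simulator makes no
claim to reproduce trial eligibility, enrollment or dependent-censoring
processes.

## 9. Numerical choices

- Cycle sums agree with direct adaptive-quadrature integration of the
  discounted occupancy within 0.2%, and halving the cycle length moves
  (AE-free) totals by under 0.1%.
- The one-off first-cycle AE decrement is proportional to cycle length by
  construction; the six-month and whole-horizon modes are
  discretization-convergent.
- RMST uses adaptive quadrature (`scipy.integrate.quad`); survival
  functions are evaluated in log space where relevant; generalized-gamma
  survival uses `gammainc`/`gammaincc` for both signs of Q.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; every CLI run logs its seed and a SHA-256
  config checksum.
- Monetary values are kept at full precision internally and rounded only at
  output.

## 10. Limitations

- Pure parametric extrapolation (no access to trial KM data) — see §7.
- The PSA treats parameters as independent; no correlation between survival
  parameters within an arm (their joint covariance was not published).
- EVPI is computed pairwise per comparator, not as a three-way decision.
- Utilities are literature-based constants, not time- or age-dependent.
- The AE model applies a single pooled grade ≥3 disutility, not per-event
  costs or durations.
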