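# Methods

## Structural model

Disposition is one-compartment with first-order elimination, rate constant
k = CL/V. Two administration routes are supported:

* **IV infusion** at constant rate R₀ = D/T_inf. During the infusion
  (elapsed τ ≤ T_inf): C(τ) = (R₀/CL)(1 − e^{−kτ}); afterwards the
  end-of-infusion concentration decays mono-exponentially. Infusions enter
  the central compartment directly and bypass absorption.
* **Oral first-order absorption** with rate constant ka and
  bioavailability F fixed at 1:
  C(τ) = F·D·ka / (V(ka − k)) · (e^{−kτ} − e^{−ka·τ}).

Multi-dose profiles are the superposition (plain sum) of single-event
solutions, valid because the model is linear. Times before an event's
start contribute exactly 0, which keeps superposition a sum with no
special cases. AUC over an interval is the analytic integral of the same
closed forms, accumulated per event.

Units are fixed package-wide: mg, L, h, mg/L. tmax is converted to
minutes only at the reporting layer.

**Numerical choices.** When |ka − k| < 10⁻⁸·k the flip-flop denominator
ka − k is catastrophically cancellative, so the limiting form
C = F·D·k·τ·e^{−kτ}/V (and its integral) is used instead; the switch is
invisible at 5 significant figures. Exponential differences use `expm1`.
The closed forms were validated against an independent ODE integration
(LSODA, rtol 10⁻¹¹) and adaptive quadrature to ≤10⁻⁶ relative error over
1000 random parameter/dosing draws.

## Population prior and allometry

Individual parameters are lognormal around weight-scaled typical values:

    CL_i = TVCL·(WT/WT_ref)^0.75·e^{η₁},  V_i = TVV·(WT/WT_ref)^1·e^{η₂},
    ka_i = TVka·e^{η₃}  (only when Ω is 3×3)

with η ~ MVN(0, Ω). The exponents 0.75 and 1 are fixed constants of the
model — module-level constants, never estimable. WT_ref defaults to 70 kg
(the conventional adult reference). Whether ka carries a random effect is
decided by the dimension of Ω in the prior configuration (2×2: CL and V
only; 3×3: also ka), since published pediatric priors differ on this
point. Lognormal random effects are the natural choice for strictly
positive PK parameters and make the GeoMean/GeoCV summary scale exact.

`illustrative_prior()` ships documented default values (TVCL 2.4 L/h,
TVV 58 L, ka 1 h⁻¹ at 70 kg; Ω = diag(0.1, 0.1), ~33% IIV; 10%
proportional residual error). They are chosen so that a ~3 kg neonate
lands at CL ≈ 0.23 L/h, V ≈ 2.6 L — the reported neonatal range — and are
explicitly illustrative: any scientific use requires an explicitly
configured prior, supplied as YAML and validated (Ω symmetric
positive-definite, at least one residual component positive).

## MAP ("Bayesian feedback") estimation

For one subject with observations y_j at times t_j, the estimate of η
minimises the −2 log-posterior

    OFV(η) = Σ_j [ (y_j − f_j(η))²/g_j² + ln(2π g_j²) ] + ηᵀΩ⁻¹η + ln|2πΩ|,

where f_j is the superposed model prediction and
g_j² = σ_add² + σ_prop²·f_j² the combined residual variance. The combined
model is the default superset; pure proportional or pure additive follow
by zeroing one component (both zero is rejected). A prediction of exactly
zero with no additive component is a degenerate likelihood and raises.

**BLQ handling.** Samples below the limit of quantification are discarded
by default; an optional censored-likelihood treatment replaces their
contribution with −2 ln Φ((LLOQ − f_j)/g_j). The discard default reflects
that no principled method is universal for sparse neonatal data; the
censored option is the standard alternative when BLQ samples are
informative.

**Optimization.** L-BFGS-B (numeric gradient) from η = 0 with relative
tolerance 10⁻⁸, with a Nelder-Mead polish pass only if the quasi-Newton
run reports failure; trial points whose prediction underflows under a
proportional-only error model evaluate to +∞ and are backed away from. An
optional multi-start mode adds seeded jittered starts (η ~ N(0, diag Ω))
for posteriors that may be multimodal; the single-start fit is fully
deterministic. Non-convergence is reported in the result
(`converged=False`), never silently ignored. With zero usable
observations the objective reduces to the prior term and the fit returns
the weight-scaled typical values.

Against a dense 41×41 grid of the exact objective over ±3 SD the
optimizer lands within one grid cell; with a wide prior and dense
noise-free data it recovers the generating parameters to 0.1%.

One subtlety worth knowing: with a proportional error model the
ln(2π g_j²) term depends on η, so even noise-free data leave a small
O(σ²) offset between the MAP optimum and the generating parameters. This
is a property of the extended-least-squares objective, not a bug; the
noise-free validation therefore uses an additive error model, whose
ln g² term is flat in η.

## Secondary parameters

Derived from the fitted structural parameters and the first dosing event,
which must be an IV infusion (the reporting convention for IV studies):

* AUC(0–12) — analytic single-dose integral over [0, 12] h;
* AUC(0–∞) = D/CL (F = 1, mass balance);
* Cmax — concentration at end of infusion (the IV profile is
  non-decreasing during and non-increasing after the infusion, so the
  model-implied maximum sits exactly there);
* tmax — the infusion duration, reported in minutes (a subject with a
  30-min infusion reproduces a 30-min tmax through its dosing record);
* Vd = V, CL in L/h and mL/min, t½ = ln2·V/CL (an exact identity, held to
  machine precision).

AUCs are single-dose quantities anchored at the first dose; multi-dose
exposure is available through `auc_interval` but is not part of the
standard report.

## Summary statistics

GeoMean = exp(mean ln x); GeoCV[%] = 100·√(exp(s²) − 1) with s² the n−1
sample variance of ln x. The n−1 convention cannot be discriminated from
n by two-decimal reproduction of published tables; n−1 is the usual
sample-statistics choice and is fixed here. Medians of even-sized cohorts
average the two central order statistics.

A summary cell is valid only when at least two thirds of the cohort
contributed a properly determined value (n_used ≥ ⌈2n/3⌉, i.e. ≥4 of 6);
invalid cells report their n but carry no GeoMean/GeoCV rather than a
misleading zero.

Window-binned concentration summaries assign each observation to the
window containing its elapsed time since the start of the most recent
prior infusion — this maps day-2 absolute windows (24.5–25, 26–28,
32–36 h for a 24-h dose) onto the same per-day windows automatically.
Windows are closed-left; the right edge is included when no adjacent
window begins there, matching the non-contiguous printed windows
(0.5–1, 2–4, 8–12 h). At most one observation per subject per window is
used (first kept, extras logged); pre-dose observations are excluded with
a log entry.

Report serialization rounds half-up to 2 decimals (computation stays at
full precision). The value is first collapsed to 12 significant digits so
that floating-point noise just below a decimal tie — e.g. a median of
(2.28 + 2.75)/2 = 2.5149999999999997 — rounds as the exact decimal tie
would (2.52, not 2.51).

## Synthetic cohorts

The generator emulates the sparse neonatal trial design: n = 6 subjects
by default, weight uniform on 2.55–4.30 kg, 0.5 mg/kg doses as 15-min IV
infusions every 12 h, 1–3 doses per subject, and one sample drawn
uniformly within each of the windows 0.5–1, 2–4 and 8–12 h after the most
recent infusion start — day-2 samples only for subjects that received the
24-h dose, giving 3–6 samples per subject. Postnatal age is uniform on
1–6 days and corrected gestational age on 36–41 weeks (published
demographics give only medians and ranges at n = 6, so uniform is the
least-committal choice); gestational age follows as GA = CGA − PNA with
PNA rounded up to whole weeks. Observations are
f·(1 + σ_prop·ε₁) + σ_add·ε₂, flagged BLQ below the configured LLOQ
(default 0.01 mg/L, below all realistic brivaracetam concentrations at
this dose so default runs have no BLQ). Everything is drawn from a single
seeded generator: identical seeds give bit-identical cohorts.

What the generator does **not** emulate: opportunistic extra samples at
unscheduled times, dose deviations and recording errors, assay drift,
covariate correlation (weight vs gestational age), or any
concentration-dependent dropout. Passing recovery tests on these cohorts
therefore demonstrates correctness of the estimation machinery under the
assumed design, not robustness to real-world data pathologies.

Datasets round-trip losslessly through a NONMEM-style CSV dialect
(ID, TIME, AMT, RATE, EVID, DV, MDV, BLQ, LLOQ, WT, PNA, CGA, ROUTE);
RATE with AMT encodes the infusion duration. Floats are written in
shortest round-trip form and parsed with round-trip precision.

## Validation problem sizes

The test suite validates closed forms against the ODE/quadrature oracle
on 1000 random draws, the optimizer against 20 dense-grid replicates, and
parameter recovery on 200 simulated sparse-sampled subjects (median
relative bias of CL and V under 10% at 10% proportional residual error;
observed ≈ 2%). These sizes keep the full suite under a minute while
leaving the Monte-Carlo margins wide.

## Known limitations

* One-compartment only; no two-compartment or transit-absorption models,
  no covariates beyond weight, no nonlinear elimination.
* Individual (per-subject) estimation only — no population fitting
  (FOCE/SAEM), and no standard errors on individual estimates.
* Non-compartmental analysis is deliberately out of scope: the sparse
  designs this package targets cannot support it.
* The estimator assumes each subject's full dosing history is known and
  fits all of a subject's samples jointly.
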