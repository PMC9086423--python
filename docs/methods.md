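# Methods

## The decision problem

The model compares two first-line strategies for large unresectable
hepatocellular carcinoma (HCC) without macrovascular invasion or
extrahepatic spread, from the perspective of the Chinese healthcare
system: hepatic arterial infusion chemotherapy with infusional
fluorouracil, leucovorin and oxaliplatin (FOLFOX-HAIC) versus
transarterial chemoembolization (TACE). Outcomes are discounted lifetime
costs (2020 USD), quality-adjusted life-years (QALYs), and the
incremental cost-effectiveness ratio (ICER), judged against a
willingness-to-pay (WTP) threshold of $30,552/QALY (three times China's
2020 per-capita GDP).

## Cohort model

A cohort state-transition model with four states — progression-free
disease (PFD), recurrence-free disease after hepatectomy (RFD),
progressed disease (PD) and Death — runs on 21-day cycles over a 30-year
(lifetime) horizon, 522 cycles from a starting age of 55 years.

Survival inputs are parametric fits to the comparator arm of the source
randomized trial, in months (1 month = 30.4375 days):

* OS, log-logistic: S(t) = 1 / (1 + θ t^κ), θ = 0.00272126, κ = 2.184792
  (median ≈ 14.9 months);
* PFS, lognormal: S(t) = 1 − Φ((ln t − μ)/σ), μ = 1.682471, σ = 1.119812
  (median e^μ ≈ 5.4 months).

The FOLFOX-HAIC arm applies trial hazard ratios under proportional
hazards, S(t)^HR, with HR 0.58 (OS) and 0.57 (PFS). Because the two
endpoints are fitted independently, S_PFS is capped at S_OS pointwise.

Age-banded background mortality (annual probabilities per 5-year band,
terminal band 85+ at probability 1) enters the disease curves as a
per-cycle hazard floor: the cycle death probability is
max(disease-implied, background). A multiplicative (independent
competing-risk) combination is available as a config option
(`background_mortality`); the floor is the default because it is the
convention the published totals are consistent with, and it cannot thin
survival below the life table.

Per-cycle transition probabilities are derived from the curves so that,
with no hepatectomy, the chain reproduces a partitioned survival analysis
exactly: PFD = S_PFS, PD = S_OS − S_PFS, Death = 1 − S_OS at every cycle
boundary (a property the test suite asserts at 1e−9). Each cycle's
reference deaths are split between PFD and PD: the PFD share is
background mortality, floored up by whatever an (almost) empty PD pool
cannot supply — the binding case when the PFS ≥ OS cap is active — and
the PD pool absorbs the remainder. This bounded split keeps every flow in
[0, 1] by construction and makes survival monotone in the hazard ratios.

### Hepatectomy and the RFD state

At the end of mean first-line treatment (3.6 sessions every 21 days for
FOLFOX-HAIC, 2 sessions every 42 days for TACE — both reach cycle 4), 24%
(FOLFOX-HAIC) or 12% (TACE) of the still progression-free cohort moves to
RFD. RFD faces a constant recurrence hazard calibrated to a 5-year
cumulative recurrence probability of 19% (annual rate −ln(1−0.19)/5);
recurrence returns patients to PD.

The RFD death hazard is the model's largest structural judgment call,
exposed as `rfd_mortality`:

* `os_hazard` (default): RFD keeps the arm's all-cause OS-implied
  hazard. The trial's intention-to-treat OS curve already contains the
  survival of patients who underwent hepatectomy, so the split re-labels
  occupancy for costs and utilities without manufacturing additional
  survival.
* `background`: RFD faces general-population mortality only until
  recurrence. This credits the hepatectomy subcohort with near-normal
  longevity on top of an ITT OS curve that already includes them, and
  raises lifetime QALYs by roughly 0.3 (TACE) to 0.7 (FOLFOX-HAIC); it is
  retained for structural sensitivity analysis.

Under either option the ICER stays below the WTP threshold (asserted over
all 16 combinations of the exposed structural flags).

## Valuation

Utilities: 0.76 for PFD and RFD, 0.68 for PD; QALYs accrue per cycle as
occupancy × utility × cycle length. Grade ≥3 adverse events (elevated
ALT, elevated AST, vomiting, incidences per arm from the trial) are
applied once at model entry: a cost of Σ incidence × unit cost ($43
ALT/AST, $49 vomiting — $14.12 for FOLFOX-HAIC, $23.09 for TACE) and a
QALY decrement of Σ incidence × disutility × cycle length (only vomiting
carries disutility, 0.05).

Costs per arm:

* First line: per-session drug/procedure costs (FOLFOX-HAIC $2,824 =
  oxaliplatin 426 + fluorouracil 524 + leucovorin 24 + HAIC procedure
  1,850; TACE $1,929) on the calendar schedule, weighted by PFD occupancy
  at each session time; the fractional mean session count (3.6) weights
  the final session.
* Hospitalization: $384 per treatment administration by default
  (`hospitalization: per_session`); a per-21-day-cycle reading over the
  treatment period is available (`per_cycle`).
* Hepatectomy: one-off $9,022 per RFD entrant.
* Progressed disease: best supportive care $363 per cycle for the BSC
  share of PD occupancy (95% after FOLFOX-HAIC, 87% after TACE;
  recurrence-origin PD receives BSC only), and crossover therapy — the
  other arm's regimen at its own schedule and mean session count — as a
  one-off discounted course for the crossover share (5% / 13%) of newly
  progressed main-branch patients. The BSC/crossover shares are
  renormalized to sum to 1 after probabilistic sampling.

Everything is discounted at 3%/year, (1 + r)^(−t), from model entry,
with cycle-start accounting by default; a half-cycle correction
(trapezoidal occupancy, midpoint discounting) is exposed as a flag and
changes QALYs by under 2% at 21-day cycles.

## Sensitivity and subgroup analysis

One-way analysis pushes each of the 30 uncertain input rows to its
published low/high bound (missing ranges default to ±20% of baseline,
clamped to the distribution's support) and records both ICERs; rows that
feed several parameter slots (shared AE costs, the PFD/RFD utility) move
together.

The PSA draws each row independently from its published family: gamma
(costs) and beta (probabilities, utilities) by method of moments with
mean = baseline and SD = (high − low)/3.92, treating the printed range as
a 95% interval; lognormal (hazard ratios) matching the CI on the log
scale with median = baseline; uniform for the discount rate. An
infeasible beta moment match falls back to a clamped uniform draw with a
logged warning. Survival-curve shape parameters carry no published
uncertainty and are held fixed, which may understate the spread of the
acceptability curve. 10,000 iterations are the default; the engine is
vectorized over draws, so a full PSA takes seconds.

Subgroup analysis replaces the pooled hazard ratios with the 16 published
subgroup HRs applied to the pooled baseline TACE curves — an
approximation, since reconstructing subgroup-specific baseline survival
is not possible from the printed data — and reports the deterministic
ICER plus the PSA probability of cost-effectiveness with the subgroup HRs
sampled lognormally from their printed CIs.

## Synthetic patient data

`simulate_ipd` draws event times by inverse transform from the stated
curves (log-logistic: t = ((u^(−1/HR) − 1)/θ)^(1/κ); lognormal via the
normal quantile), with administrative censoring at a trial-like 24-month
cutoff and no dropout. It emulates the marginal survival distributions
only — no covariates, no informative censoring, no enrolment staggering —
so recovery tests demonstrate that the fitting stage is consistent and
calibrated, not that real trial data would be this clean.
`fit_parametric` refits either family by maximum likelihood with right
censoring (lifelines), reporting standard errors on the model's own
parameterization via the delta method. At n = 2000 and 24-month cutoff,
recovered parameters sit well within 3 SE of truth and the sampler's
Kolmogorov–Smirnov distance to the analytic CDF is below 0.01 at n = 1e5.

## Numerical choices and edge cases

* Horizon adequacy is guarded: `run_trace` raises if Death occupancy at
  the horizon is below 0.999 at the evaluated parameters.
* The terminal life-table band (annual probability 1) is clipped to
  1 − 1e−12 to keep its hazard finite; survival decays to ~0 within a
  year of entering it.
* Occupancy rows sum to 1 by construction (flows conserve mass); tests
  assert 1e−9.
* ICER dominance: when incremental QALYs are ~0 (|ΔQ| < 1e−12) or the
  increments have opposite signs, a dominance flag replaces the ratio;
  net monetary benefit ties (NMB = 0) count as cost-effective.
* Problem sizes: 522-cycle traces, 10,000 PSA iterations, n = 2000
  recovery fits — chosen to make every analysis reproducible on a single
  CPU in seconds to minutes.

## Known limitations

* The original model's Markov structure is under-specified in its
  publication; the three structural options above (RFD mortality,
  background-mortality combination, hospitalization accrual) bracket the
  plausible readings, and the defaults are the readings the published
  totals support. Incremental results shift by up to ~30% across these
  options; the cost-effectiveness conclusion does not.
* The ICER is nearly invariant to the OS hazard ratio in this cost
  structure: an extra discounted PD-year costs ≈ $6,000 in best
  supportive care and yields 0.68 QALY, a marginal ratio close to the
  base-case ICER, so pure survival extension moves cost and effect
  almost proportionally.
* Crossover therapy duration after progression is not reported; the
  crossover course mirrors first-line intensity and ignores death during
  the (short) crossover window.
* Utilities are shared between arms and constant within states; no
  time-in-state (tunnel) effects.
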