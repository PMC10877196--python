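# Methods

## Decision problem and model structure

The package evaluates meniscal repair (MR) versus partial meniscectomy (PM)
for horizontal cleavage tears in patients without osteoarthritis (OA) at
treatment, from a US payor perspective. It uses an annual-cycle Markov cohort
model with seven reported health states:

1. **No OA, post-primary** — the whole cohort starts here after the index
   procedure.
2. **No OA, post-revision** — reached when the index procedure fails and is
   revised with a resection (a second PM after a primary PM, or the patient's
   first PM after a primary MR). At most one revision per patient.
3. **OA** — symptomatic knee osteoarthritis; absorbing except for TKR and
   death.
4. **TKR** — a one-cycle tunnel for the year of total knee replacement, so
   the procedure's cost and disutility attach exactly once.
5. **Post-TKR** — at most one TKR revision can occur from here.
6. **Post-revision-TKR** — no further surgery.
7. **Death** — absorbing; reachable from every state.

Internally the engine expands states 2 and 4–5 into year-indexed sub-states
(collapsed for reporting) because three clocks drive time-banded
probabilities; see *Clocks* below. The projection runs from the starting age
(default 35) through age 110.

## Transition probabilities

All probabilities are annual. Multi-year cumulative endpoints from the
clinical literature are converted with
`p = 1 − (1 − cumulative)^(1/horizon)`; e.g. a 17.4% two-year failure rate
gives the all-suture MR annual failure probability of 9.12%.

| quantity | default | notes |
|---|---|---|
| PM failure | 0.002/yr | first 3 cycles only |
| MR failure, all-suture | 0.0912/yr | first 3 cycles only; 0.0284 in the pooled-techniques scenario |
| OA after PM, years 1–5 / 6–10 / ≥11 | 0.1127 / 0.0351 / 0.0089 | banded by the OA clock |
| RR of OA, MR vs PM | 0.55 | applied multiplicatively to the band probability |
| OA → TKR | 0.0227/yr | from the OA state only |
| TKR revision, years 1–4 / 5–9 / 10 / ≥11 | 0.019 / 0.01 / 0.009 / 0.006 | banded by the TKR-revision clock |
| procedure mortality | 0.003 | revision, TKR and revision-TKR; combined with background mortality as 1 − (1−q)(1−0.003) |

Failure (revision) risk applies only during a **failure window** of 3 cycles
(configurable, including unlimited), reflecting that later reoperations are
hard to attribute to the index procedure. The window risk is independent of
OA status: a patient whose knee has progressed to OA can still have the
repair fail and be resected while the window is open. The engine tracks this
through an internal "OA, repair intact" sub-state; without it, OA onset at
11.27%/yr would deplete the at-risk pool and cumulative revisions could not
compound to 1 − (1 − p_fail)^3, which the lifetime revision counts (≈248 per
1,000 MR patients) require.

### Clocks

- **OA bands** (`oa_clock`, default `since_last_procedure`): the band
  probabilities describe years after a meniscectomy, and a failed repair's
  revision *is* that patient's first meniscectomy, so the band clock restarts
  at a revision. `since_primary` keeps a single clock from the index
  procedure.
- **Post-revision OA risk** (`post_revision_oa`, default `"pm"`): once the
  repair has been resected the patient's meniscus is partially removed, so
  they follow PM's OA progression; `"primary"` retains the arm's RR benefit.
- **TKR-revision bands** (`rtkr_clock`, default `since_primary`): banded by
  years since primary treatment; `since_tkr` bands by years since the TKR
  itself, tracked through post-TKR year sub-states. The tunnel cycle counts
  as post-TKR year 1.
- **RR application** (`rr_space`, default `probability`): the relative risk
  multiplies the annual probability directly; `rate` applies it on the
  exponential-rate scale, 1 − (1 − p)^RR. The two differ by <3% at these
  probabilities; direct multiplication reproduces the reference lifetime
  event panel and cost rows best as a set.

Within a cycle, competing risks resolve sequentially — background death
first, then index-procedure failure, then OA onset or TKR conversion among
the survivors of the earlier stages — which keeps every transition-matrix
row exactly stochastic without renormalisation. The cohort enters the model
having survived the index procedure, so the 0.3% procedure mortality applies
to model-generated procedures only.

## Costs, utilities, discounting

2021 USD Medicare reimbursements: index MR $4,996 (hospital) / $3,494 (ASC);
index or revision PM $3,433 / $1,931; TKR $38,916; revision TKR $46,698; and
$3,486 per year of nonoperative OA management, also applied in the post-TKR
and post-revision-TKR states (and in the TKR tunnel year). Per-cycle
utilities: 0.9 (no OA), 0.69 (OA), 0.835 (post-TKR, including the tunnel
year), 0.785 (post-revision-TKR); one-off disutilities 0.0077 per meniscal
procedure, 0.025 per TKR, 0.05 per revision TKR.

Costs and QALYs are accrued with **half-cycle correction**: state membership
is shifted by half a cycle (the classic half-duration cycle added at the
start), implemented by evaluating the piecewise-linear occupancy path at
cycle midpoints. A trapezoidal integration of the same path is kept as an
independent code path; the two agree to 1e−9 relative on lifetime totals,
and end-of-cycle accrual (`none`) is available for comparison. Both streams
are discounted at 3%/yr to mid-cycle; event costs and disutilities are
discounted to the middle of the cycle in which the event occurs. The index
procedure's cost and disutility fall at time zero, undiscounted.

## Baseline mortality

The model needs annual death probabilities for ages 30–110 (age 30 is the
youngest starting age in the age sweep). The packaged default is a
**synthetic Gompertz table**: adult mortality is approximately log-linear in
age, so q(a) = q₃₅·exp(b·(a−35)) with q(35) = 0.21%, and b chosen so
q(110) = 52.29%; the same law extrapolates down to age 30. A piecewise-linear
family exists for sensitivity, and `load_life_table` accepts any real
period life table as a CSV of (age, qx), with fraction/percent auto-detection.

The two-point Gompertz fit is deliberately minimal and is *heavier than a
real Social Security table in midlife* (e.g. q(50) ≈ 0.006 vs ≈ 0.004),
because the single log-linear slope from 35 to 110 cannot reproduce the flat
middle-age plateau of observed mortality. This slightly shortens OA and
post-TKR exposure; see *Replication notes*.

## Sensitivity analyses

**One-way**: each parameter is set to its low/high value (±20% of base, or
the utility ranges below) with everything else at base; two full paired runs
per parameter. The decision (dominant or cost-effective at $100k/QALY) is
insensitive to any single perturbation, including an unlimited failure
window.

**Probabilistic**: 10,000 iterations. Each uncertain parameter has a
distribution — Beta for probabilities and utilities, Gamma for costs,
Log-normal for the RR and disutilities — fitted by method of moments to the
base value and a 95% central interval. The interval is ±20% of base
(sd = 0.2·mean/1.96) except the utilities, which use their stated ranges
(no OA 0.72–1, OA 0.55–0.83, post-TKR 0.68–1, post-revision-TKR 0.63–0.94).
Starting age, discount rates, cycle length, baseline mortality and the
structural switches are never sampled. One draw is shared by both arms
within an iteration (except the two arm-specific failure probabilities,
which have their own distributions), so incremental variance reflects
decision uncertainty rather than arm-independent noise. Iterations are
seeded independently from a root seed — reproducible and order-independent.
A draw violating a parameter invariant is re-sampled and logged.

The cost-effectiveness acceptability curve evaluates the fraction of draws
with positive NMB on a $0–$150,000 WTP grid in $1,000 steps; NMB exactly
zero counts as not cost-effective (strict inequality, conservative).
Threshold searches bisect a parameter (Brent, tolerance 1e−3) to the value
where incremental cost (dominance boundary) or NMB (WTP boundary) crosses
zero. The horizon sweep truncates accumulation at each horizon with no
terminal-value extrapolation — a payor's budget-window reading.

## What the synthetic inputs do and do not show

The synthetic life table makes every analysis runnable with no external
data, and the test suite validates the machinery against closed forms: the
two-state reduction reproduces the analytic discounted life expectancy to
1e−9, cumulative revisions reproduce the compounding formula, cohort event
totals agree with an independent 100,000-patient microsimulation within 3
standard errors, and occupancy is conserved at every cycle for arbitrary
valid parameter sets. Passing these shows the engine is internally correct,
not that the Gompertz table matches any particular national life table:
absolute QALY and cost totals shift by a few percent under a realistic
mortality schedule, while incremental results and every classification
(dominance, thresholds, horizon pattern) are robust to it.

## Replication notes

Against the published headline figures this implementation was built to
reproduce, with the printed inputs and the synthetic table:

- **Reproduced**: probability conversions (exact); lifetime revisions per
  1,000 (248 MR / 6 PM, exact after rounding); OA cases per 1,000 (488/647
  vs 495/660, within 2%); the RR thresholds (0.91 vs 0.92 dominance, 0.96
  vs 0.97 at $100k); the year-1 / year-2 / year-6 horizon classification
  pattern in both settings (exact); dominance at every starting age 30–60
  with incremental QALYs strictly decreasing in age; the pooled-techniques
  scenario savings ($14.5k vs $15.1k, −3.5%).
- **Not fully reproduced**: (i) absolute QALY totals. The published totals
  are a constant 0.797× this package's at *every* starting age and in both
  arms — a ratio independent of horizon length, which excludes mortality or
  discounting explanations and implies a uniform multiplicative utility
  factor; the lower bounds of the published utility ranges are exactly 0.8×
  the published means, and running this package at those lower-bound
  utilities reproduces the published QALY totals to <1% and the published
  per-patient QALY gain to 0.2%. The package keeps the published *base-case*
  utilities as defaults, so its QALY gain (0.54/patient) exceeds the
  published 0.43 by the same factor. (ii) Downstream surgical volume: TKR
  and revision-TKR counts run 7–14% below the published panel and both
  arms' cost totals ~4–5% below, leaving per-patient savings of $11.3k
  (hospital) and $11.6k (ASC) against published $12.2k/$12.6k. A realistic
  SSA-shaped table recovers only ~$0.2k of this, so the remainder reflects
  within-cycle accrual conventions of the original implementation that the
  published description does not pin down. (iii) The PSA fraction
  cost-effective at $100k is 97.6% here versus 99.84% published: with
  independent Beta draws of the no-OA and OA utilities at the published
  ranges, their difference (mean 0.21, sd ≈ 0.10) puts ~2.4% of draws at
  negative incremental QALYs; the published figure implies roughly half
  that spread, i.e. correlated or narrower utility sampling. The
  pooled-techniques PSA fraction exceeds the base-case fraction here as it
  does in the published analysis.

## Problem sizes

A lifetime run is 76 cycles over a 27-state internal space — about a
millisecond — so the full analysis (base case, age sweep, one-way sweep,
threshold bisections, 76-horizon sweep, and a 10,000-iteration PSA run
twice) completes in well under two minutes on one CPU. The microsimulation
cross-check uses 100,000 individuals.
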