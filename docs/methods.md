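# Methods

## Model structure

`copdce` implements a hybrid decision-tree / Markov cohort model for the
cost-effectiveness of single-inhaler triple therapy (FF/UMEC/VI) against two
dual-therapy comparators (FF/VI, UMEC/VI) in symptomatic COPD with an
exacerbation history, from a UK health-service perspective.

**Year 1 (decision tree).** The first model year is costed directly from
52-week per-arm trial outputs: moderate and severe exacerbation rates
(events/patient-year), an annual pneumonia probability (arm-specific,
severity-independent), within-trial mortality, and a treatment
discontinuation proportion. Quality of life in year 1 is the trapezoidal
time-average of the pooled baseline EQ-5D utility plus per-arm
change-from-baseline at scheduled visits.

**Years 2+ (Markov cohort).** Six living states — three FEV₁-defined
severity grades (moderate 50–<80 %, severe 30–<50 %, very severe <30 % of
predicted) crossed with a recent-exacerbation history stratum (≥1
exacerbation in the previous annual cycle) — plus absorbing death. The
cohort starts from the per-arm trial-end distribution scaled by trial
survivors. Each annual cycle applies, in this order:

1. **Death**: state probability `1 − (1 − q)^RR`, where `q` is the
   background annual death probability at `floor(age)` (life table
   pre-adjusted to exclude COPD deaths when a COPD-death fraction is
   supplied) and `RR` is the severity relative risk (1.89 / 3.63 / 8.33).
   The power form multiplies the mortality *rate* (log-survival scale) and
   is clamped to [0, 1].
2. **Progression** among survivors, worsening only
   (moderate→severe, severe→very severe; a direct moderate→very severe
   probability is supported and defaults to 0).
3. **Exacerbation expectation** from the *origin* state's annual risks
   (probability of ≥1 moderate / ≥1 severe event, treated as cohort
   expected counts).
4. **Stratum update**: the exacerbating fraction
   `p_any = 1 − (1 − p_mod)(1 − p_sev)` of each origin state's survivors
   enters the recent-exacerbation stratum of its destination severity.

Deaths are applied first so no event or cost is credited to decedents'
second half-year twice; pneumonia causes cost and disutility only (its
mortality is treated as subsumed in the severity-specific excess mortality).

## Accrual and discounting conventions

* Cycle length is fixed at one year with no occupancy half-cycle
  correction; instead within-cycle deaths accrue **0.5 cycle** of
  life-years, QALYs and maintenance cost (midpoint-death convention). The
  same convention gives decedents half a year of person-time for year-1
  event expectations.
* The trial year is discount period 0 (undiscounted); post-trial cycle *k*
  is discounted by `(1+r)^−k`, default r = 3.5 %/yr for both costs and
  benefits. Horizon 35 years (1 trial year + 34 cycles), cohort age 65.3 at
  entry.
* Drug cost: 30-day price × 365.25/30 per year of person-time. Discontinuers
  (a trial-observed proportion, fixed at trial end) switch at the trial
  midpoint — 26 weeks of assigned therapy then 26 weeks of class-mix-weighted
  replacement therapy — and stay on replacement for the rest of the horizon.
* Event counts reported in results are lifetime expectations per patient,
  undiscounted, including the trial year.
* ICERs are computed from unrounded internal deltas. A strategy with more
  effect at lower cost is reported *dominant*, less effect at higher cost
  *dominated*; negative ratios are never printed. Zero effect difference
  with a cost difference is reported as an undefined ratio with the cost
  sign.

## Sensitivity analyses

**One-way (tornado).** Each registered parameter (state utilities for
moderate and very severe disease, exacerbation rates, mortality relative
risks, per-arm drug prices, maintenance costs) is scaled ±20 % one at a
time with a full model re-run; perturbations that would breach a bound are
clamped with a warning. The table is sorted by ICER span, ties broken by
parameter name, so output is independent of input ordering.

**Probabilistic.** Standard health-technology-assessment families: beta for
utilities/disutilities (moment-matched to 95 % CIs where available, else a
10 % coefficient of variation), gamma for costs (CV 20 %) and trial rates
(CV 10 %), log-normal for mortality relative risks (CV 20 %). The
transition/exacerbation probabilities are sampled jointly on the logit
scale as `mean + L·z` where `L` is the Cholesky factor of a configured
covariance (the synthetic generator supplies an AR(1)-correlated covariance,
sd 0.05, ρ 0.3). Each draw re-runs the full pipeline; draw *k* uses an
independent substream keyed by `(master seed, k)`, so results are
reproducible and order-independent. Out-of-range univariate draws are
redrawn (max 100); cross-parameter ordering invariants are not re-imposed on
individual draws. CEACs use the net-monetary-benefit rule
`P(λ·ΔQALY − Δcost > 0)` on a £0–50 000 grid (£1 000 steps, £20 000
included). Default draw count 10 000.

**Scenarios.** Declarative overrides on a copy of the base bundle: discount
rates 0 %/5 %; within-trial mortality excluded; direct post-trial
exacerbation effect for 1/3/5 years, constant or linearly waning (the
reduction defaults to the trial-observed relative reduction in total
exacerbation rate versus each comparator, applied to the intervention arm's
exacerbation probabilities); discontinuation disabled; horizon restricted to
trial follow-up; replacement mix pooled across arms; societal perspective
(adds user-supplied productivity costs per event and per severity-year,
human-capital interpretation); year-1 utility from occupancy-weighted state
utilities instead of trial EQ-5D.

## Synthetic inputs and what they do and do not show

The published main text prints the unit costs, state utilities, event
disutilities and mortality relative risks, which the canonical bundle uses
verbatim. Four input blocks are **not** published in the main text and ship
as clearly-marked synthetic stand-ins chosen once as realistic values for
this population:

* *Transition/exacerbation table*: moderate→severe 0.128/yr, severe→very
  severe 0.102/yr; annual risk of ≥1 moderate exacerbation 0.385–0.700 and
  of ≥1 severe exacerbation 0.075–0.290, increasing with severity and with
  recent-exacerbation history.
* *Per-arm 52-week outputs*: total exacerbation rates 0.91 / 1.07 / 1.21
  per patient-year (FF/UMEC/VI, FF/VI, UMEC/VI), pneumonia probabilities
  0.076 / 0.069 / 0.047 (higher in the ICS-containing arms), trial
  mortality 2.0–2.5 %, discontinuation 26–32 %, trial-end distributions
  shifted toward milder states for triple therapy, and EQ-5D trajectories
  with larger gains on triple therapy.
* *Pneumonia unit costs*: ambulatory £140.00, inpatient £1863.60 — chosen so
  the published 55 % hospitalised weighting reproduces the published
  £1087.98 per event. Replacement-therapy class mixes are likewise chosen to
  reproduce the published weighted 30-day costs (£48.01/£48.54/£49.34) from
  the published class prices.
* *Life table*: Gompertz `q(a) = 1 − exp(−A e^{Ba})` with A = 6×10⁻⁵,
  B = 0.082/yr (q(65) ≈ 1.2 %, doubling every ~8.5 years), q(110) = 1, and a
  flat 5.4 % COPD-death fraction removed before the relative risks apply.

Consequently the structural and unit-level tests are exact, but the
full-pipeline totals quantify the stand-ins, not the original analysis: the
bundled base case yields ΔQALY ≈ 0.13 and an ICER ≈ £9.6k/QALY versus FF/VI
(published: 0.275 and £4104), and its acceptance test is expected to fail
until the original supplementary inputs are transcribed into the config.
The stand-in PSA also understates between-arm uncertainty (trial-end
distributions are not sampled and utility draws are shared across arms), so
CEAC probabilities run higher than the published 96 %/74 %.

## Numerical choices and edge cases

* Occupancy vectors must be non-negative and sum to 1 within 1e-9; the
  engine validates every cycle.
* Logit transforms clip probabilities to [1e-9, 1−1e-9] so a structurally
  zero probability (e.g. moderate→very severe) survives the coefficient
  round trip as ~1e-9.
* `cholesky_factor` accepts exactly singular PSD matrices via a 1e-12
  diagonal jitter and names the first negative leading principal minor
  otherwise.
* Degenerate inputs: an all-death cohort propagates unchanged with zero
  events; `q = 1` yields exactly the half-cycle credit; horizon 1 runs no
  Markov cycles, so results equal the decision tree alone.
* Ages are continuous; the life table is looked up at `floor(age)` and
  clamped to [40, 110].

## Known limitations

* Expected-value cohort model: no patient-level heterogeneity, no tunnel
  states beyond the single-cycle exacerbation history.
* Time-homogeneous progression and exacerbation risks (age enters only
  through background mortality).
* Exacerbation probabilities of ≥1 event are used as expected counts, which
  undercounts multiple events within a cycle.
* Year-1 maintenance cost uses the trial-end severity mix as the occupancy
  proxy, the only per-arm severity datum available.
* The cost-effectiveness frontier across all three arms simultaneously is
  out of scope; comparisons are pairwise.
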