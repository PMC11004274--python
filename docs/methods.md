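# Methods

## Design

Prescription sequence symmetry analysis (PSSA) is a self-controlled
design: each admission serves as its own control, which removes
time-invariant confounding (sex, age, diagnosis, hospital). Its one
strong assumption is that, absent a causal effect, the chance that the
marker drug is first ordered shortly *after* the index drug equals the
chance it is first ordered shortly *before*, once background prescribing
trends are accounted for. Inside a hospital stay that background is far
from flat — order intensity is highest in the first days of the stay and
decays with day-of-stay (admission work-up, first-occurrence depletion,
discharge censoring) — so the crude ratio is biased even under the null,
and the null-effect correction below is essential.

All timing is in whole calendar days (order timestamps in the source
systems are only reliable at day precision) on a 1-based day-of-stay
axis: the admission day is day 1. Ties (index and marker ordered the
same day) are excluded from both cohorts and reported; a
`tie_policy="causal"` sensitivity option reassigns them to the causal
cohort.

## Screening (new-user design)

Every admission is treated as a new drug user. Excluded are admissions
with (a) the first index order on stay-day 1 or 2 (`index_min_day=3`) —
such orders cannot reflect in-hospital initiation after work-up and
leave no room for a backward window; (b) total stay ≤ 3 days
(`min_stay_days=3`, strict: a 4-day stay is the shortest included); and
(c) no marker order inside the observation window
[index − washout, index + μ] with washout = μ = 30 days. The screening
flow object enforces accounting closure (users = included + each
exclusion bucket) on every run. Within-admission repeat index orders
keep only the first; `exclude_repeat_index=True` instead drops those
admissions. A `cross_admission_washout` flag exists for linking repeat
admissions of one patient but is off by default: each admission is an
independent new user.

## The statistic chain

With first-order days i (index) and m (marker), and interval d ∈ {3, 7,
28}: causal iff 0 < m − i ≤ d, non-causal iff 0 < i − m ≤ d; cSR =
n_causal / n_noncausal.

The null-effect probability weights the background marker-initiation
trend by the observed index-day distribution:

    P = Σ_{m=1}^{μ} I_m F_m / Σ_{m=1}^{μ} I_m (B_m + F_m)
    F_m = Σ_{n=m+1}^{m+d} M_n ,  B_m = Σ_{n=m-d}^{m-1} M_n

with out-of-range terms zero. neSR = P/(1−P); aSR = cSR/neSR;
a lower 95% bound of aSR above 1 flags a signal. The excess risk among
exposed adjusted is ERAEA = n_causal·(aSR−1)/aSR, rounded to an integer
(floored at 0 when aSR < 1), and as a percentage of all index users
rounded to two decimals.

**Source of the M series.** The package computes M_n from the *entire*
admission population (`marker_day_series`), not only from the analysed
index-user cohort. This is the decisive design choice: the
null-effect ratio is meant to capture what marker initiation looks like
*without* the index drug's influence, which is exactly what the
background (largely index-free) population provides. Deriving M from
the exposed cohort alone contaminates the forward windows with the very
effect being estimated; in our calibration runs that variant
under-recovered an injected excess by roughly a third, while the
background series recovers it to within a few percent.
`run_pssa(..., m_series=None)` still falls back to the cohort-derived
series for callers who only have the sequence table, with this caveat
documented.

**Uncertainty.** The 95% bounds are Wald binomial bounds on P
(z√(P(1−P)/n), guards n > 200 and P·n > 15 warn when violated), mapped
through the odds transform, with aSR bounds = cSR/neSR_upper …
cSR/neSR_lower. The effective n is the number of classified (non-tie)
sequences for that marker — the count actually compared against the
forward/backward split. An alternative `ci_method="binomial"` attaches
an exact Clopper–Pearson interval to the causal proportion instead and
divides by the point neSR; the two methods agree closely at the sample
sizes where either is trustworthy. A zero non-causal count raises by
default; `continuity=True` applies a Haldane-style +0.5. The minimum
cohort size ceil(z²π(1−π)/E²) uses an assumed incidence π = 0.85% and
tolerance E = (0.36% + 1.95%)/2 by default.

Display rounding in emitted tables: ratios to two decimals (three
significant figures from 10 upward), percentages to two decimals.

## Synthetic data generator

The generator emulates the features of inpatient order data that PSSA
is sensitive to; defaults:

| parameter | default | rationale |
|---|---|---|
| stay length | 1 + NegBin, mean 12 d, dispersion 4, cap 90 | right-skewed stays typical of tertiary cardio/oncology admissions |
| index-user share | 5.64% | observed share of contrast-agent users |
| index day | 1 + Poisson(3), capped at stay | contrast given after initial work-up, mostly week 1 |
| marker hazards | 0.002–0.030 /day across 5 drugs | ordered so usage shares track the observed ranking (dexamethasone ≫ dopamine > promethazine > calcium gluconate > loratadine) |
| same-day co-order | p = 0.25 | premedication/acute treatment given with the contrast order |
| effect multiplier | 5 | detectable causal excess of marker initiation |
| reaction lags | days 1–7, weights 0.35/0.25/0.15/0.10/0.05/0.05/0.05 | delayed reactions dominate days 1–3 and taper to day 7 |

Marker orders are per-day Bernoulli draws; the causal effect adds an
independent excess draw on days index+lag with per-day probability
(multiplier − 1) × hazard scaled by the lag weight, so a uniform lag
distribution multiplies the window hazard exactly by the multiplier.
Every order carries a ground-truth provenance tag (`baseline`,
`effect`, `same_day`, `index`) persisted in a `provenance.csv` sidecar,
which enables exact counterfactual checks (re-running the pipeline with
effect orders removed). Demographics (sex, age bands, top diagnoses,
surgery and allergy flags) reproduce the observed constituent ratios
but are decorative: they never enter the statistics.

What the generator does **not** model — and what passing tests
therefore do not establish for real data: indication-driven
co-prescription (marker ordered because of the condition that prompted
the contrast scan), hospital-level heterogeneity beyond an id column,
calendar trends across admissions, dose/route switching, or
outcome-coded diagnoses. Null calibration on this generator shows the
estimator handles *stay-structure* confounding; it cannot show
robustness to confounding by indication.

## Calibration study (what the acceptance tests run)

Exact-null cohorts: 50,000 admissions per seed, one marker (hazard
0.03/day), no effect, no same-day co-orders, 200 seeds. The 95%
interval covers aSR = 1 in 90–99% of seeds and the median aSR is within
5% of 1 (observed ≈ 95.5% coverage, median ≈ 1.02). Effect recovery:
100 paired seeds with a 5× hazard effect uniform on days 1–3; the
3-day aSR exceeds the same seed's null aSR in ≥ 95% of pairs and the
pooled ERAEA count matches the counterfactual ground-truth excess
within 15% (observed ≈ 1–2%). These sizes keep the whole suite within
a few minutes on one core; the estimator's behaviour was stable when
spot-checked at larger sizes.

## Numerical notes

- The weighted-probability windows are evaluated by cumulative sums;
  day 0 does not exist and position 0 of both series is ignored. An
  independent double-loop implementation guards the vectorised one in
  the tests.
- Degenerate inputs raise typed errors: all-zero index mass or marker
  windows (`DegenerateDistributionError`), zero non-causal count
  (`UndefinedRatioError`), out-of-domain parameters (`ParameterError`);
  the batch runner logs and skips such marker-interval cells instead of
  aborting.
- P bounds are clamped to the open unit interval before the odds
  transform.
- Generated tables and the pipeline outputs are byte-deterministic for
  a fixed seed (stable sorts, hash-free grouping).

## Known limitations

- The published per-drug ratios of the motivating study come from a
  private 20-hospital database and cannot be reproduced here; the
  package reproduces the method, the printed worked examples, and the
  estimator's operating characteristics on synthetic cohorts.
- The excess-risk percentage inherits every bias of aSR; with strong
  same-day premedication the tie exclusion discards genuinely acute
  reactions, so acute-reaction signals are understated by design.
- Wald bounds on P understate uncertainty when the marker is rare
  (guards warn); prefer `ci_method="binomial"` there.
- The table-4-style "adjusted percentage of additional risk exposure"
  column of the motivating study has no reproducible denominator and is
  deliberately not emitted.
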