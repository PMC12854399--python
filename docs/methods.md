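# Methods

This note records the models, parameter conventions and numerical choices
behind `glycea`, and what the synthetic data can and cannot demonstrate.

## Setting and outcome model

Two care models for initiating closed-loop insulin delivery in type 1
diabetes are compared over a one-year horizon from the payer perspective:
an out-of-hospital initiation centre (intervention, "CIRDIA", n=128) and
hospital-based care (comparator, "HC", n=73). Because a one-year horizon
does not move mortality, effectiveness is the CGM time in range (TIR,
70–180 mg/dL, percent) and safety is the Glycemia Risk Index (GRI), a
composite 0–100 score of hypo- and hyperglycemia exposure:

```
hypo  = %(<54) + 0.8·%(54–69)
hyper = %(>250) + 0.5·%(181–250)
GRI   = min(100, 3.0·hypo + 1.6·hyper)
```

The weighting constants and the [0,100] clip come from the index's defining
publication; the clinical display groups GRI into zones A–E at 20-point
boundaries. Zones are implemented as upper-closed intervals (A = [0,20],
B = (20,40], …, E = (80,100]), giving a total, gap-free classification.

Band edges on the continuous glucose axis are vlow g<54; low 54≤g<70;
tir 70≤g≤180; high 180<g≤250; vhigh g>250, which matches the printed
integer band labels without gaps. Readings are weighted equally under
uniform sampling (whether the original band percentages were time- or
reading-weighted is not documented; the two coincide for regular 5-minute
CGM sampling). Irregularly sampled traces are weighted by the interval to
the next reading, capped at twice the median interval so a data gap cannot
dominate a summary. Raw glucose outside [20,600] mg/dL is rejected;
values are then clamped to the sensor reporting range [40,400].

## Micro-costing

Costs are built bottom-up: each care-pathway event is a cost item
(quantity × unit tariff) keyed into a tariff catalog by nomenclature source
(NGAP professional acts, CCAM procedures, NABM laboratory acts, LPP
devices, GHS day-hospitalization groups). No discount rate is applied (the
horizon is one year) and no out-of-pocket share exists (full coverage).
The shipped catalog carries **plausible placeholder tariffs** — the
published analysis prints no unit tariffs, and official 2024 French values
are out of scope; any real-world use must supply a genuine catalog file.
Arm summaries report the sample SD (n−1); a singleton arm reports SD 0 with
a warning. The package enforces mean × n = total in its own outputs.

## Incremental analysis and dominance

With increments ΔC (cost), ΔE (TIR, positive = better) and ΔS (GRI,
negative = better), ICER = ΔC/ΔE and ICSR is reported as the positive
magnitude |ΔC|/|ΔS| per GRI point reduced. Ratios are never reported bare
when negative: every ratio carries the dominance/quadrant label of its
plane. The dominance classification treats increments within a tolerance
(default 1e-9; configurable — "equally effective" has no published numeric
definition) as zero: cheaper with an equal-or-better outcome is dominant,
costlier with an equal-or-worse outcome is dominated, and equal cost with a
strictly better (worse) outcome is classified dominant (dominated) — weak
dominance — so that the forward and reverse comparisons remain exact
mirrors. Indifference requires both increments to be within tolerance.

From the printed base-case means (costs 8373.12/8814.32 EUR, TIR
72.65/71.95, GRI 30.11/30.33) the increments are −441.20 / +0.70 / −0.22
and the recomputed ratios are −630.29 and 2005.45. The published ratios
(−625.83, 2011.02) were computed upstream from unrounded patient-level
inputs that are not public; the two differ by under 1% and both values are
asserted in the tests at that documented tolerance.

## Probabilistic sensitivity analysis

All six parameters (two arms × cost, TIR, GRI) are redrawn independently
in each of 10,000 Monte Carlo simulations: costs from gamma distributions
moment-matched to the arm mean/SD (shape = (mean/SD)², scale = SD²/mean),
TIR and GRI from normals truncated to [0,100] parameterised by the arm
mean/SD **as the parent distribution's moments** (the common convention;
no truncation-moment correction — deliberately different from the cohort
generator below). Draws are classified by strict sign into the four
quadrants of the cost–TIR and cost–GRI planes; on the GRI plane "more
effective" means a lower GRI. Exact-zero increments (probability zero
under continuous sampling) are assigned the side of the base-case
increment's sign.

Two documented ambiguities:

* **SD vs standard error.** The published PSA does not state its
  uncertainty scale. Using the printed SDs reproduces the printed 86%
  less-costly proportion to within a few points; standard errors would
  drive it to ≈100%. SDs are the default; `uncertainty_scale="se"` is a
  config switch.
* **Which plane the printed quadrant split uses.** The printed
  43.4/42.7/7.0/6.9 partition is attributed to the cost–TIR plane: the
  base-case GRI increment is adverse in sign convention terms, which is
  inconsistent with "strong dominance" near 43% on the GRI plane.

With the printed parameters the engine yields ≈82–83% less costly and
≈42–43% strong dominance; the independent bivariate-normal closed form
Φ(−ΔC/√(SD₁²+SD₂²)) = 0.827 confirms the engine, indicating that the
remaining gap to the printed 86% stems from the unpublished exact inputs,
not from the sampling machinery.

## Synthetic cohort generator

The generator exists so the pipeline is testable without the (non-public)
patient records. It emulates the study conditions: arm sizes 128/73, the
printed per-arm, per-timepoint TIR/GRI means and SDs, per-arm cost mean/SD,
age-class mix (from the printed class counts; the comparator's printed
counts sum to 72 of n=73, so proportions are normalised over the printed
total), 52% women, the printed BMI distributions, and the care pathway
(initiation visit — day hospitalization for 13% of the intervention arm
and all of the comparator arm — three teleconsultations, three
consultations, an optional 3-month telemonitoring period, and 12 months of
device/consumable charges).

Choices where the publication is silent:

* **Truncated-normal marginals with moment matching.** Patient-level TIR
  and GRI are truncated-normal on [0,100], mirroring the PSA's
  distributional choice — but here the parent parameters are *solved* so
  the truncated distribution has exactly the target mean/SD. Without this
  correction the intervention baseline GRI (56.4, SD 21) would come out
  with an SD biased low by ~1.4 points, defeating moment-recovery checks.
* **Within-patient correlation.** M0 and M12 values are coupled through a
  Gaussian copula with correlation 0.4 (not reported; exposed as
  `longitudinal_corr`), and TIR and GRI at the same timepoint with
  correlation −0.85 (both summarise the same glucose profile; exposed as
  `tir_gri_corr`). The 4-variable copula correlation is the Kronecker
  product of the two 2×2 blocks, which is positive definite whenever both
  are.
* **Cost decomposition.** The per-event cost breakdown is not printed, so
  the fixed pathway events are priced from the catalog and the
  device/consumable item absorbs the calibration residual: its annual
  amount is gamma-distributed with mean (target − fixed pathway cost) and
  SD equal to the full target SD, making each arm's per-patient total match
  the target mean and SD exactly in expectation. The amount is expressed
  as a fractional number of monthly-rental units (utilisation varies by
  patient).
* **Telemonitoring fraction.** Telemonitoring applied only to patients
  initiated after a fixed date; the fraction is unknown and defaults
  to 0.5 (`telemonitoring_fraction`).
* **Ages** are drawn uniformly within the sampled age class, bounded to
  [16,80]; age means/SDs are therefore only approximately reproduced
  (age moments are not part of the calibration targets).
* **CGM traces** have correct band occupancy by construction
  (largest-remainder allocation of reading counts per band, uniform values
  within bands, seeded shuffle) and *no physiological dynamics* — no meal
  excursions, no autocorrelation. They validate the metrics code, not
  CGM realism.

What passing tests show — and do not show. Moment-recovery and
round-trip tests demonstrate that the pipeline's arithmetic is correct
under the study's summary statistics. They cannot validate patient-level
results that depend on the unpublished records: the printed per-subgroup
p-values, the 79%/21% zone-grid fractions, or the printed total-cost sums
(which are internally inconsistent with mean × n and are deliberately not
targeted) are covered only by structural and property checks.

## Group statistics

Comparisons are gated on the Shapiro–Wilk test at α=.05 per sample (the
gate's α is not published): both samples normal → two-tailed pooled-
variance Student t test; otherwise Wilcoxon rank-sum (Mann–Whitney U).
The rank-sum test is used for the non-normal branch — the methods wording
"signed-rank" is a paired test and the groups are independent; the outcome
tables' own footnote says rank sum. Constant samples are treated as
non-normal with a warning. Age classes are half-open: [16,25), [25,45),
[45,65), [65,∞) (the baseline table prints ">65" while the outcome table
prints "≥65"; the half-open convention keeps the partition total).

IPTW fits a logistic propensity model of arm membership on the chosen
covariates (zero-variance covariates dropped with a warning, which also
makes the no-confounding case an exact identity: all weights 1), forms
stabilised weights (arm prevalence over propensity, and the complement),
truncates them at the 1st/99th weight percentiles, and reports weighted
outcome means/SDs plus standardized mean differences before/after
weighting. The published analysis gives no weighting details ("data not
shown"); covariate list, truncation and scale are parameters. Percentile
truncation trades balance for variance: under confounding of the strength
actually observed at baseline it leaves residual SMDs well below 0.1, but
under much stronger simulated confounding it can leave ~0.1–0.2.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical cohorts,
traces, cost items, PSA draws and pipeline manifests. Test simulations use
the smallest sizes that make the checks sharp: moment recovery at n=5000
per arm (3-standard-error bands), PSA checks at 10,000–100,000 draws
(binomial noise bounds), type-I-error simulations at 2000 replicates, and
trace round-trips at 3–14 days of 5-minute sampling. The acceptance script
runs the PSA at the published 10,000 draws.
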