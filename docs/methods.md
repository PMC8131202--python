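# Methods

## Study design being implemented

`coolmatch` implements a matched observational comparison of babies who did
versus did not receive enteral milk feeds during 72-hour therapeutic
hypothermia, as run on routinely collected neonatal unit records. A baby is
**eligible** when recorded gestational age at birth is ≥ 36 weeks and the
baby either was cooled on three days or died while cooling was being given
before three days were complete (day 1 = day of birth). A baby is **fed**
when enteral feeds of any type, route and quantity are recorded on at least
one day of the cooling period.

Outcomes are pragmatic EHR phenotypes: pragmatic NEC (recorded NEC
diagnosis plus ≥ 5 consecutive days of antibiotics while nil by mouth,
anywhere in the stay), pragmatic late-onset infection (an antibiotic run of
≥ 5 consecutive days commencing on day ≥ 4), culture-positive late-onset
infection (pure pathogen growth from blood on day ≥ 4), survival to
discharge, hypoglycaemia, breastfeeding measures, parenteral-nutrition and
central-line day counts, length of stay, and weight-for-age SD score at
discharge against a pluggable growth reference. Twelve outcomes in all,
which is also the default Bonferroni family size.

## Matching and estimation

The propensity of being fed is estimated by maximum-likelihood logistic
regression on every background covariate (Newton, relative log-likelihood
tolerance 1e-8, ≤ 100 iterations; a ridge-stabilised fit with penalty 1e-6
replaces the MLE under perfect separation). Babies outside the common
support of the two groups' score ranges, then outside caps [0.01, 0.99],
are excluded; both rules are configurable because the exact published
trimming rule is not stated in the main text of the source study.

Retained babies are cross-classified into exact strata of birth-year band
(2010–11, 2012–13, 2014–15, 2016–17) × cord-pH band (<6.9, 6.9–7.0, >7.0).
Missing cord pH forms a fourth exact band by default (published matched
counts show missing matched to missing); a `strict12` option instead drops
missing-pH babies, mimicking a literal 12-group reading. Within each
stratum, propensity deciles use the stratum's own empirical type-7
quantiles, with boundary scores assigned to the lower bin; strata with few
distinct scores collapse to one bin per distinct edge. Within each
stratum × decile cell, fed and unfed babies are independently permuted with
a seeded generator and paired off; the pair count per cell is
min(#fed, #unfed), so the total pair count is fixed by the table and only
pair composition varies with the seed. The whole pairing is replicated
R = 25 times with child seeds derived deterministically from the master
seed (recorded in the outputs for audit). Nearest-neighbour distance within
cells is deliberately *not* used: the design matches within deciles and
relies on randomisation plus replication.

Each replicate yields a fed-minus-unfed contrast: risk difference with
binomial SE and, alongside it, the odds ratio `ad/bc` with log-scale SE
`√(1/a+1/b+1/c+1/d)` (Haldane–Anscombe 0.5 added to all cells when one is
zero, logged); continuous outcomes use the two-sample (Welch) mean
difference. Replicates are combined by averaging the points (log scale for
odds ratios) with variance `W̄ + (1 + 1/R)·B`, where `W̄` is the mean
within-replication variance and `B` the between-replication sample
variance — the same combination rule used for multiply-imputed data. The
source description says only that within- and between-replication SEs were
combined; the exact rule is therefore this package's documented choice and
is recorded in the report metadata. p-values use the standard normal
reference (the matched samples are large); significance after multiplicity
is `p < 0.05/m` with m = 12. At R = 1 the combination reduces exactly to
the single replicate's estimate.

Covariate balance is reported as standardised differences — for
proportions `(p1 − p2)/√((p1(1−p1) + p2(1−p2))/2)`, for continuous
variables `(x̄1 − x̄2)/√((s1² + s2²)/2)` — before matching (full trimmed
table) and after matching (mean ± SD over replicates), with 0/0 defined
as 0 and |SMD| < 0.1 as the conventional adequacy threshold.

Missing covariate values are set to the observed mean (continuous) or the
reference category (binary/categorical) and flagged by a per-covariate
missing indicator that itself enters the model. This single-model policy
follows from matching missing-pH babies to missing-pH babies; multiple
imputation is out of scope.

The a-priori planning calculation is the classical normal-approximation
two-proportion sample size `n = (z_{α/2}+z_β)²·(p1q1+p0q0)/(p1−p0)²` per
group, returned plain and with the continuity correction
`n/4·(1+√(1+4/(n|p1−p0|)))²`.

## The synthetic cohort generator

Real source data are access-controlled, so the generator stands in for
them. Conditions emulated by default: 6 030 babies born 2010–2017; ~31%
fed during cooling; pragmatic NEC ≈ 1.1%, pragmatic late-onset infection
≈ 26%, culture-positive late-onset infection ≈ 0.5%, survival ≈ 90%,
breastfeeding at discharge ≈ 46%, hypoglycaemia ≈ 20%; cord pH missing in
28% of babies and maternal items missing in 5–20%, completely at random;
length of stay and line/parenteral-nutrition durations log-normal (median
stay ≈ 11 days).

A single latent severity scalar `z ~ N(0,1)` per baby drives the recorded
illness markers through monotone links (lower Apgar scores and cord pH,
more chest compressions, intubation, ventilation, inotropes, lower blood
pressure and saturation) and drives every outcome risk on the log-odds
scale with coefficient `confounding_strength` (binary outcomes:
`logit p = intercept ± c·z + effect·fed`, intercepts solved numerically so
realised marginal rates hit their targets; continuous outcomes shifted on
the log scale). The **feeding decision** depends on severity as seen
through the *recorded* covariates: a fixed linear index of the
post-missingness, mean-imputed covariate values, standardised, with the
intercept solved so the fed proportion hits its target. This makes sicker
babies less likely to be fed while keeping the exposure ignorable given
the recorded background variables — the identifying assumption of the
matched design — and makes the logistic propensity model exactly
well-specified. It is a deliberate design choice: wiring the exposure to
the latent `z` directly would build unmeasured confounding into the
generator and no covariate-based method could then be calibrated against
it.

Outcome flags are realised in the day-level data so the derived phenotypes
equal the generator's ground truth exactly: a flagged infection gets an
antibiotic run of 5–8 days starting on day 5–7 (leaving a clear gap after
any early 2–3-day course, so run starts are unambiguous); a flagged NEC
baby gets a nil-by-mouth antibiotic run plus a recorded diagnosis — such a
run also satisfies the late-onset definition, and the infection intercept
is calibrated on that union; flagged positive cultures get a culture on
day 4–8. Stays (and death days) are extended to contain every realised
event; consequently all synthetic deaths occur on day ≥ 3, and every baby
has at least three day rows. Day-2 cooling is blanked at random in 5% of
survivors to exercise the imputation rule. Because odds ratios are
non-collapsible, an injected conditional log-OR is accompanied by the
implied *marginal* log-OR in any given population, computable from the
ground-truth severities; the marginal value is the estimand the matched
analysis targets and is what the recovery checks compare against (for
ln 0.5 at the default infection rate the marginal truth is ≈ −0.60 rather
than −0.693).

What the generator does **not** emulate: informative missingness,
multi-hospital transfers, physiological time series, calendar-time trends
beyond the year field, and any correlation structure between covariates
beyond the single severity factor. Passing tests therefore demonstrate the
statistical machinery under a known, single-factor confounding structure —
not robustness to the messier dependence of real records.

## Numerical and degenerate-input choices

- Antibiotic runs break on a day that is absent, false or missing;
  "commencing after day 3" means run start day ≥ 4 with day 1 = birth.
- Missing `enteral_fed` on a cooling day counts as not fed by default; the
  `drop_missing` policy instead excludes babies with missing nutrition data
  in the first 4 days (the published sensitivity analysis).
- Constant or linearly dependent covariate columns are dropped before the
  propensity fit (pivoted QR), with a logged warning.
- Zero cells in a 2×2 table get +0.5 on all four cells (logged); a zero
  margin leaves the odds ratio undefined and is reported as such.
- Standardised differences with zero pooled spread are 0 when the means
  agree and ±inf otherwise.
- Degenerate strata (< 10 distinct scores) collapse to fewer decile bins;
  at n ≈ 10 the method legitimately produces very few pairs.
- All randomness flows from one master seed: replicate seeds are derived
  via `SeedSequence(master, spawn_key=r)` masked to 31 bits; identical
  inputs, configuration and seed give byte-identical reports.

## Simulation study sizes

The packaged operating-characteristic checks use cohorts of 2 000 babies,
25 matching replications and 200 simulation repetitions (coverage and
recovery), and a single 6 000-baby cohort for the balance check — sizes at
which the Monte-Carlo error of a coverage proportion is ≈ 1.5 percentage
points and each study completes in a few minutes on one core. The combined
CI for the matched contrast is mildly conservative by construction
(matched pairs are positively correlated but the within-replication
variance treats groups as independent), so observed null coverage sits
slightly above the nominal 95%.

## Known limitations

- Conditional (pair-matched) logistic regression, caliper or optimal
  matching, k:1 designs, inverse-probability weighting and multiple
  imputation are out of scope by design.
- The growth reference shipped for weight-for-age SD scores is a synthetic
  table (labelled as such), not a published national standard; substitute a
  real reference through `GrowthReference` for applied use.
- Percentages in published outcome tables with reduced denominators cannot
  be reproduced exactly from the printed counts; only count-derived
  quantities are asserted.
- The normal reference for p-values ignores the small-sample t correction;
  at the matched sample sizes involved the difference is negligible.
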