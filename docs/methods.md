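# Methods

This note documents the models implemented in `psycourse`, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not establish.

## Diagnostic hierarchy and progression

The four major psychotic diagnoses are ranked by clinical severity:
schizophrenia (SZ, rank 1), schizoaffective disorder (SAD, 2), bipolar
disorder (BD, 3), and major depressive disorder with psychotic features
(pMDD, 4). Code sets (ICD-10, dotted prefix matching): SZ = F20, SAD = F25,
BD = F30.2 ∪ F31, pMDD = F32.3 ∪ F33.3; the psychosis set is F20–F29 plus
the BD and pMDD codes; the SUD endpoint is F10–F16 ∪ F18–F19 (nicotine
dependence F17 deliberately excluded). Undotted concatenations ("F200") are
rejected rather than guessed at, and ICD-8/9 codes require a user-supplied
mapping to ICD-10 — the historical equivalence lists are not public in a
form we would trust to reconstruct, so the package refuses to invent them.

Per person: *onset* is the earliest psychosis-flag diagnosis; *first major*
is the earliest ranked diagnosis, with same-day ties resolved toward the
more severe class (deterministic, mirrors the hierarchy); *main lifetime*
is the most severe class ever recorded. Progression is defined only toward
schizophrenia and is unidirectional: it requires a first SZ diagnosis
strictly after a lower-ranked first major diagnosis. Because of the
same-day tie rule, `first_major ≠ SZ` plus any SZ event implies the strict
ordering automatically.

The Cox time-at-risk clock starts at the first lower-ranked major diagnosis
(not at psychosis onset); the choice is genuinely open and configurable
(`time_origin="onset"`), but the first-major origin matches the estimand "time
to conversion from the lower diagnosis". Ages are `(date − birth)/365.25`.

## Hospitalization burden

Each person's timeline is shifted so onset is day 0. Aligned year *k* is the
day interval `[k·365.25, (k+1)·365.25)`; fixed-width bins (not calendar
years) keep year 0 the same length regardless of onset month. An episode
with a psychiatric primary discharge code marks every aligned year it
overlaps. The observed-year denominator is
`min(15, ceil((study_end − onset)/365.25))`, and the burden fraction is
marked-observed-years / observed-years. Length of stay counts admission and
discharge days inclusively, so same-day admissions count one day. Usage
profiles clip episodes to the 15-year window before counting.

Persons with fewer than three observed years are excluded from burden
regressions by default (`min_observed_years`, configurable); very short
follow-up makes a fraction of observed years uninformative. Deaths and
emigration are not modelled.

Before regression the burden fraction passes through a rank-based
inverse-normal transform, Blom offset: value of rank *r* among *n* maps to
`Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks for ties. This puts the outcome on
an SD scale robust to the skew and 16-level coarseness of the fraction, at
the price of a small attenuation discussed below. A raw-fraction analysis
remains available (`transform_burden=False`).

## Regression family

All genetic models adjust for sex (female = 1), year of birth, and the first
ten principal components; predictors are standardized in-sample with the
population-SD convention (divisor √(Σ(x−x̄)²/n)), so linear coefficients are
SD-per-SD, logistic coefficients exponentiate to ORs per SD, Cox
coefficients to HRs per SD. Fits are maximum likelihood via statsmodels
(OLS/Logit) and lifelines (Cox, Efron tie handling); Wald 95% intervals and
two-sided p-values throughout. No multiple-testing correction is applied
inside the package — thresholds are an analysis-level concern. Perfect or
quasi-separation in logistic fits raises an explicit error rather than
returning an unbounded coefficient. PGS strata cut at the 20th and 80th
percentiles (low / middle / high), a partition of the sample.

## Mediation

The SUD mediation of the EA-PGS burden effect uses an explicit two-equation
path model rather than a latent-variable SEM: the reported quantities (the
a·b indirect effect, the mediator-adjusted direct effect) are fully
determined by the two regressions, and a SEM would add estimator choices
without adding identification. Equation (i) is a linear-probability model so
the indirect effect keeps an additive SD-scale interpretation; the
logistic-scale EA-PGS↔SUD association is reported separately and never
composed into a·b. Uncertainty comes from a person-level nonparametric
bootstrap (default 1000 replicates, percentile intervals, seeded); the
outcome is re-rank-transformed inside every resample so it stays on the
resample's SD scale. Education can enter as a numeric second mediator; its
paths are reported on the side and never summed into the SUD indirect
effect. The package's temporal checks are purely descriptive
(mediator-before-outcome date-ordering rates); no causal-discovery search is
attempted.

## Synthetic registry generator

The generator emulates the cohort structure the analyses assume: birth years
1927–2000 (truncated when a preset requires 15 observed years, i.e. births
after ~1992 are clamped); log-normal onset ages with class medians 24.4 (SZ),
26.9 (SAD), 34.0 (BD), 35.9 (pMDD), 24.3 (progressed) and log-SDs derived
from the corresponding interquartile ranges (0.286–0.532); onset dates
left-truncated at the 1969 registry start; lower-class mixture 0.33/0.43/0.24
(SAD/BD/pMDD) and main-class mixture 0.655/0.105/0.179/0.061; SUD base rate
0.32 among schizophrenia persons; progression base rates 0.244 (progressed
vs remained) and 0.169 (progressed vs schizophrenia-first). Episode
durations are log-normal (default median 28 d, log-SD 0.8, capped at 300 d;
the usage preset uses 21 d for SUD vs 41 d for non-SUD persons), one episode
per hospitalized year placed uniformly inside its aligned year, optionally
1 + Poisson extra episodes per year for the revolving-door pattern.

The burden process is a latent score z = Σβ·x + ε with the residual scaled
so Var(z) ≈ 1, mapped monotonically to an expected hospitalized-year
fraction p = 0.02 + 0.93·Φ(z). The default *deterministic* realization sets
hospitalized-years = round(15·p) (a random subset of years), making the
recomputed burden an exact monotone function of z; a *stochastic* mode draws
15 Bernoulli(p) years instead. The two modes bracket the unknown
within-person year-to-year correlation. All probabilities are clipped to
[0.01, 0.99] with the clip rate logged; a preset whose probability clip rate
exceeds 20% is rejected as infeasible.

Each named preset activates exactly one effect family at its published
value, so one estimator is validated per preset; the `full` preset combines
all mechanisms for integration testing. Randomness uses one root seed with
per-quantity Philox streams (key = hash of seed and quantity name); every
array is indexed by person, so results are order-independent and growing
n only appends persons. Replicate-cohort seeds are spread with numpy's
SeedSequence.

**Known distortions, accepted deliberately.** (1) Rank-INT of the 15-level
deterministic burden compresses strong group contrasts slightly: the SZ-vs-
lower contrast (true 0.65) recovers ≈ 0.63 (−2 to −4%), inside the 5%
attenuation budget; per-SD PGS effects show no measurable bias at n = 10⁴.
(2) In the logistic progression preset the SZ-diagnosis delay is clipped
into the observed window so the progression indicator is fully recoverable
from events — only the delay tail is distorted; the Cox preset instead uses
genuine administrative censoring. (3) Regressing burden on SUD without the
EA-PGS inherits a small omitted-variable term (≈ +0.007 at the preset
values). (4) The generator draws independent standard-normal PGSs and PCs;
real scores are correlated across traits and with ancestry, so passing
recovery here shows estimator correctness under the assumed model, not
robustness to confounding in real registries.

## Validation design and problem sizes

Correctness is established two ways. *Oracle equivalence*: code
classification against the enumerated endpoint sets; burden and usage
against a per-day occupancy enumeration (property-tested over random episode
layouts); OLS/logistic/Cox against normal equations, direct
likelihood maximization and a partial-likelihood grid on ≤10-row instances;
partition and unidirectionality invariants; null calibration over 200 seeded
zero-effect cohorts (n = 2000). *Parameter recovery*: each preset's true
effect must be recovered within the looser of 3 Monte-Carlo SEs (8 replicate
cohorts in the test suite, 5 in the acceptance script) and 5% relative
error, at n = 10 000 per cohort — sizes chosen so the whole validation runs
on a laptop-class single core in minutes. The bootstrap mediation check uses
400–1000 resamples; the severed-path coverage check uses 200 seeds at
n = 1000 with 150 resamples.

## Limitations

No ICD-8/9 era semantics, mortality, emigration, outpatient or primary-care
sources; no remission modelling; no frailty, competing risks or mixed
models; mediation assumes the linear-probability approximation and no
unmeasured mediator-outcome confounding. The synthetic cohorts are a
validation surface, not an epidemiological forecast.
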