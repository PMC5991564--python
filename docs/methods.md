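# Methods

This note documents the models implemented in `hetkit`, the assumptions they
make, the defaults they ship with, and what the synthetic-cohort validation
does and does not demonstrate.

## Heteroplasmy scales and transforms

Heteroplasmy is the mutant fraction of mtDNA, held internally as a proportion
in [0, 1] and reported as % at the I/O boundary.  The assay model assumes a
sensitivity floor of 3% mutant mtDNA; levels below it are flagged
`below_detection` but retained (they carry information about decline).

**Age-adjusted blood.**  `adjusted = blood / b^(age + k)` with defaults
b = 0.977 (per-year multiplicative retention, i.e. a ~2.3%/yr compound
decline) and k = 12 years (an offset absorbing a more rapid early-life
reduction, under the assumption that the compound regime extrapolates back
through childhood).  Adjusted values can exceed 1 for high levels at high
ages; they are truncated to 1 with a `capped` flag rather than reported
above 100%, since heteroplasmy is a proportion — the flag preserves the
information that truncation occurred.

**Sex-adjusted urine.**  Urine is modelled as a logit-scale distortion of the
whole-body (muscle-like) level: `logit(urine) = s·(logit(true) + o_sex)` with
s = 0.791, o_male = +0.625, o_female = −0.608.  The published inverse
formulas then recover `true` exactly, which is the round-trip contract the
generator and the adjuster are tested against.  Proportions of exactly 0
or 1 are clamped into [ε, 1−ε] before the logit (ε = 0.005 by default,
configurable; well below the assay floor) and flagged.

**Composite measure.**  The unweighted arithmetic mean of age-adjusted blood
and sex-adjusted urine; subjects missing either value are dropped from
composite analyses (weighting is not specified anywhere authoritative, so
the simplest choice is made explicit here).

## Decline estimators

*Trajectory classification* uses the crude annual change
`(last − first)/span`; spans under 4 years are labelled `short-span` because
assay noise (±2–3 percentage points) swamps a ~2%/yr relative decline over
short windows.

*Rate-vs-initial-level regression.*  Exponential loss `dp/dt = −r·p` implies
the annual change is proportional to the starting level, so `r` is estimated
by OLS of annual change on first level **through the origin** (the
proportionality has no intercept under the model).  The extended variant
adds an age modulation, `change = −(r0 + r1·age_first)·first_level`.  Note a
known first-order bias: with finite spans the discrete change underestimates
the instantaneous rate by a factor `(1 − e^(−r·span))/(r·span)` (~7% at
8-year spans); the recovery experiments show the estimator lands within that
expectation of the generating rate.

*Compound-decline fit* minimises `Σ(blood − init·b^(age+k))²` on the raw
proportion scale (the simplest defensible objective; a logit-scale variant
would down-weight the high-level observations that identify b) over
b ∈ [0.90, 1.00], k ∈ [0, 30] — a box bracketing the defaults with wide
margin — by a 41×31 coarse grid scan followed by bounded L-BFGS-B.  The
objective is ridge-shaped: multiplicative error in the initial-level
estimate trades off against k, not b, which is why sex-adjusted urine (a
noisy proxy for the early-life level) still yields an unbiased b while k
absorbs the attenuation.  Both b and k are fitted; a brute-force fine-grid
oracle in the tests confirms the grid+refine optimum to 3 decimals in b.

## Variability

Per-subject SDs over ≥3 repeated measurements are divided by
`c4(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2)` to remove the small-sample downward
bias of the sample SD under normality (≈11% at n = 3).  CVs divide by the
population mean of **per-subject means**, not raw observations, so heavily
re-sampled subjects do not dominate — consistent with the one-point-per-
individual convention used in the cross-sectional models.  The cohort mean
CV gets a t-based 95% CI (the construction behind the symmetric intervals
conventionally reported for mean CVs); measures are compared by two-tailed
continuity-corrected Wilcoxon rank-sum tests (scipy's asymptotic
Mann-Whitney, matching R's `wilcox.test` defaults).

## qPCR copy number

Copies per nucleus = `2 · (q_ND1 · dilution_ratio) / q_B2M`, with quantities
read off per-plate standard curves (OLS of mean Ct on log10 relative
quantity over six ten-fold dilutions).  The diploid factor 2 (B2M is a
single-copy nuclear gene) and the dilution ratio 100 (working concentrations
~10 ng/µl for B2M vs ~0.1 ng/µl for ND1) are explicit, configurable
parameters.  QC: curves need R² > 0.999 and slope in [−3.6, −3.3]
(−3.32 = perfect doubling); samples fail on Ct SD > 0.3 or mean Ct > 33
after removing wells more than 0.5 Ct from the within-sample median (the
outlier rule operationalises "within-sample outliers" with a common
laboratory threshold; configurable).  Inter-plate variation is removed by
`standardised = (value / on-plate control) × grand-mean control`; plates
whose control fails QC are excluded from standardisation and logged.

## Burden and progression

NMDAS assessments (29 items, 0–5) are scaled as
`(sum of answered, respiratory item excluded) / n_answered × 29`, where
`n_answered` counts all 29 responses; assessments with fewer than 25
responses are excluded.  Which item index is respiratory is a named,
configurable setting (default item 8).  One burden point per subject: the
maximum scaled score and the earliest age reaching it; `symptomatic` means
scaled NMDAS ≥ 5.

*Burden models* are OLS of √(scaled NMDAS) on age + one heteroplasmy measure
(+ muscle copy number for the muscle model); the square root is what makes
residuals approximately normal, and a Shapiro-Wilk P on the residuals is
reported as a diagnostic.  Competing measures are compared by resampling
**subjects** (the independent unit — one burden point each) with
replacement, refitting both models, and summarising the adjusted-R²
difference: percentile 95% CI, and P = bootstrap probability that the
second model is the better one, with ties counted half so a self-comparison
gives exactly 0.5.

*Progression* is a linear mixed model on √(scaled NMDAS) with **no intercept
anywhere** (carriers assumed asymptomatic at birth, so every fitted
trajectory passes through the origin): fixed effects for age and
age×heteroplasmy, by-subject random slopes on the same two terms with an
unstructured 2×2 covariance, Gaussian residuals.  The heteroplasmy main
effect is available behind a flag to reproduce the selection step that drops
it.  Models are fitted by **maximum likelihood** (not REML) because AICs are
compared across specifications; `AIC = −2ℓ + 2p` exactly, with p = fixed
effects + free covariance parameters + 1 residual variance.  Fixed-effect P
values use the t-distribution with n_obs − n_fixed degrees of freedom (a
simple convention; with hundreds of observations the choice of df is
immaterial).  statsmodels' `MixedLM` is the fitting engine, optimised by
Nelder-Mead with a Powell fallback (the most reliable pair for this
profiled likelihood near variance boundaries); the likelihood is
cross-checked in the tests against an independently assembled marginal
Gaussian likelihood `V_i = Z_i G Z_i' + σ²I`.  Note age and age×heteroplasmy
are strongly collinear when heteroplasmy is subject-constant, so individual
fixed effects carry wide uncertainty even when the combined progression
slope is precise.  Measure comparison bootstraps subjects and summarises the
ΔAIC distribution with the same tie-split P convention (second model better
= lower AIC).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every estimator is validated.  Cohort-level defaults are fixed
to the source cohort's printed marginals — 242 subjects, female fraction
147/242, ages uniform on [19.7, 79.9] — and the forward observation models
invert the adjustment formulas exactly (see above), so zero-noise round
trips are exact by construction.

Free parameters the study does not print, chosen once on realism grounds:

| parameter | default | rationale |
|---|---|---|
| latent heteroplasmy | uniform [0.05, 0.95] | cohort latent distribution unknown; uniform maximises identifiability of regression recovery |
| muscle logit noise SD | 0.15 | keeps muscle a tight whole-body reference |
| urine logit noise SD | 0.35 | urine is the most variable measure |
| blood level noise SD | 0.02 | pyrosequencing-level repeatability (~2 points) |
| linear urine mode: female baseline 5%, residual SD 10% | — | centres the percentage-linear model away from the [0,100] boundaries so censoring bias stays small, with scatter keeping urine–muscle R² in the high-0.6/0.7 regime |
| burden: intercept 3.4, age 0.04, residual SD 1.5 (√NMDAS) | — | yields median burden near the cohort's (~20 scaled) and ~40% explained variance in the muscle model |
| progression: β_age 0.05, β_int 0.08, slope SDs 0.05/0.02, residual 0.5 | — | median trajectories reaching scaled NMDAS ~16 by the mid-40s with large inter-individual spread |
| qPCR: efficiency 0.94, Ct SD 0.1, plate log-SD 0.167, control 500 copies | — | slope −3.48 inside QC range; plate SD reproduces a ~17% control CV across plates |

Copy-number lognormal σ's are derived analytically from the printed
median/IQR pairs (muscle 3523/1708 → σ = 0.356; blood 144/81 → 0.412; urine
1181/2870 → 1.489); urine additionally carries a male log-offset of 1.44
(female median 881, male ≈ 3.7k) and blood a small positive heteroplasmy
slope on the log scale.

NMDAS totals are decomposed into item scores by an even integer split over
the 28 scored items (deterministic; sums reconstruct the rounded total
exactly; totals above 140 are not representable with 0–5 items and are
capped).  qPCR samples are loaded at ~1% of the top standard so their Cts
interpolate inside the calibrated dilution range; the per-plate effect
multiplies the ND1 template of samples and the control (not the plasmid
standards), which is exactly the structure the control-based
standardisation removes.

**What passing recovery tests show — and don't.**  The replicate-cohort
experiments (200 cohorts for the regression recoveries, 500 for the CV; run
sizes chosen so the whole validation completes in seconds while Monte-Carlo
error stays well below the assertion tolerances) demonstrate that each
estimator recovers the constants its own forward model generated, i.e. the
pipeline is self-consistent and approximately unbiased under its stated
assumptions.  They do not validate those assumptions against real tissue
biology: real cohorts have non-uniform latent distributions, a terminal
nonzero blood plateau in some individuals (not modelled), assay artefacts
beyond Gaussian noise, and informative sampling (sicker patients sampled
more).  Known small deviations visible in the recovery numbers are expected
and documented: the discrete-span bias of the rate estimator (~6% low), the
[0, 1] censoring of the CV simulation (~3% low), and boundary censoring in
the percentage-linear urine mode (~1–3% low on slope and sex gap).

## Degenerate inputs and numerical choices

Logit clamping ε = 0.005; compound-fit search box b ∈ [0.90, 1.00],
k ∈ [0, 30]; grid 41×31 then L-BFGS-B with ftol 1e-15.  All-tied CV sets
give P = 1 with a warning; empty sets raise.  Bootstrap replicates that fail
to fit are dropped and counted, with a warning above 5%.  Random-effect
covariances with a slope SD below 1e-3 are reported as singular (boundary)
fits with a warning rather than an error.  All stochastic operations take an
explicit seed; replicate experiments derive child seeds via
`numpy.random.SeedSequence.spawn`.

## Limitations

No terminal-plateau decline model; no NMDAS subscale analysis; no
baseline-population symptom correction; muscle CV is out of scope (single
measurements); absolute qPCR quantification (copies/µl) and raw
amplification-curve processing are out of scope — inputs are Ct values.
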