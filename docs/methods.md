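# Methods

## Scoring model

A kick trial is six 5-s sets of maximal roundhouse kicks with 10-s active
recovery. Set power is `P = LLM·(d·N)²/t³`: the single lower-limb mass
`LLM` (kg) moving the total kick distance `d·N` (m) in `t` seconds. This is
a field-test construct, not an inverse-dynamics estimate — its value is
comparative (within athlete across sessions, across athletes within a
protocol), which is why the reliability battery matters.

* `LLM` uses per-sex thigh/shank/foot segment-mass percentages of body
  mass. These are configuration (`ProtocolConfig.segment_percentages`),
  not constants: the shipped defaults are the widely used single-limb
  photogrammetric values (male 10.5 + 4.75 + 1.43 = 16.68 %BM, female
  11.75 + 5.35 + 1.33 = 18.43 %BM). Any comparison against published
  absolute wattages is only meaningful if the same percentages were used;
  published tables typically do not state them, so absolute W agreement is
  not a check this package claims.
* Geometry: `d = √(x² + y²)` from the stand-off distance and contact
  height; `d` may also be supplied directly. If both are supplied and
  disagree by more than 1e-9 m the record is rejected rather than silently
  preferring one.
* Two fatigue indices exist on purpose: the kick test divides the
  peak-minus-minimum drop by the **minimum** set power, the jump test
  divides the first-four-minus-last-four drop by the **first-four** mean.
  Both are implemented verbatim and exposed under distinct names; the two
  forms give very different scales (≈25% vs ≈60% on typical kick data) and
  must not be interchanged.
* Degenerate trials: a set with zero valid kicks has zero power; the kick
  fatigue index is then undefined and reported missing with a warning
  instead of infinite.

Relative power divides by `BM^0.67` (allometric surface-law exponent,
configurable), removing most of the body-size dependence of power.

## Reliability

Relative reliability is a two-way single-measure ICC. The absolute-
agreement form (systematic session shift counts as error) is the default;
the consistency form is available by configuration, and both are reported
with F-based 95% CIs (Satterthwaite df for the agreement form). The
implementation was verified against an independent reference
implementation to 1e-10 on the point estimates. Interpretation bands:
< 0.40 low, 0.40–0.70 acceptable, 0.70–0.90 good, > 0.90 excellent, with
boundaries resolved downward (0.90 is "good") so that e.g. an ICC of 0.87
is "good".

`SEM = SD·√(1−ICC)` is ambiguous about which SD enters. The default here
is the SD of the test–retest **difference scores**; the between-subject SD
is available via `sem_sd_source="between_subject"`. The difference-score
convention is the one whose outputs line up with the reference reliability
tables this battery was validated against (e.g. SD_diff 0.817 with ICC
0.99 gives SEM 0.08, where the between-subject route would give ≈0.43);
the choice is reported in every output row. SWC multiplies the
between-subject SD — operationalised as the mean of the test and retest
SDs — by 0.2/0.6/1.2; MDC95 is `1.96·SEM·√2`. Usefulness compares SEM
against each SWC with a ±0.005 tie tolerance (half of the last displayed
decimal at 2-dp reporting): below → "good", comparable → "satisfactory",
above → "marginal".

The normality screen is a one-sample Kolmogorov–Smirnov test against a
normal with the sample's own mean and SD; a constant vector is flagged
non-parametric without error. With n < 3 paired athletes the ICC point
estimate is still computed but its CI is reported missing.

## Validity

Pearson r carries a t-based p and a Fisher-z CI; magnitude labels are
left-closed buckets on |r| (0.1/0.3/0.5/0.7/0.9, with exactly 1 labelled
"perfect") and the sign is reported separately, so r = −0.15 is "small".
Shared variance `R² (%)` is always computed from the unrounded r —
re-squaring a 2-dp printed r does not round-trip (0.88² = 77.44 vs a true
76.88), so when reconstructing a regression from a published table the
package takes `r = √(R²/100)` rather than the printed r.

Cross-prediction OLS is available from raw vectors and from summary
statistics (`slope = r·sd_y/sd_x`, etc.); the two routes agree to 1e-10
and both report the standard error of estimate and the standard error of
the intercept. The latter is included because published regression tables
in this literature sometimes print it as the "±" term next to the
equation; for the reference mean-power equation the intercept SE (1.14)
matches the printed term where the SEE (2.98) does not.

## Discrimination

The empirical ROC sweeps all observed values; AUC is computed from pooled
midranks and equals the all-pairs Mann–Whitney probability with ties
counted one half (property-tested against a brute-force pair count). SE is
Hanley–McNeil by default with DeLong as an option; the CI is the normal
approximation clipped to [0, 1]; AUC ≥ 0.70 is flagged "discriminative".
The reported cutoff maximises Youden's J over observed values and is
direction-aware: "> v" for higher-is-better variables, "≤ v" for
lower-is-better ones (fatigue index), with the cutoff value itself
classified on the favourable side.

The two-sample comparison defaults to the unpooled (Welch) standard error:
on the reference group summaries (15 vs 12 athletes) the Welch SE (1.484)
and p (0.003) reproduce the published comparison where the pooled form
(SE 1.563, p 0.005) does not; the pooled form with df = n1+n2−2 is
available via `equal_var=True`. Cohen's d always uses the pooled SD, with
the (sub-elite − elite) numerator, so negative d means elite athletes
score higher; bands at 0.2/0.5/0.8/1.2/2.0 on |d|.

## Sample size for a correlation

The exact method integrates the sampling density of r under bivariate
normality (hypergeometric-series form, validated against Monte-Carlo and
by unit-mass integration) over the rejection region of the t-test on r,
and scans n upward. For ρ = 0.6, α = 0.05 two-tailed, power 0.80 the exact
route gives n = 19 (achieved power 0.814) and the Fisher-z closed form
gives 20 — the request sits exactly on the boundary between the two
approximations. Two-tailed is the default since a stated "α = 5%" without
direction conventionally means two-sided.

## Synthetic cohorts

The generator's defaults are the study conditions of the cohort this
battery targets: 27 athletes (15 elite / 12 sub-elite, 21 male / 6 female),
per-group index means and SDs taken from the published summary tables,
target ICCs 0.87–0.99 by variable, and factor loadings chosen so implied
cross-test correlations match the published magnitudes (head–chest mean
power r ≈ 0.74, head–jump r ≈ 0.84, fatigue indices r ≈ 0.5–0.64).

Structure: one latent factor per variable family (power, fatigue, HR,
lactate, RPE), families independent; variable latents are factor draws
scaled to group means/SDs; session observations add Gaussian noise with
variance `V·(1−ICC)/ICC` where `V` is the cohort-level latent variance
(group mixture included), so the expected cohort ICC equals the target
exactly. Raw records are back-solved so scoring reproduces the intended
session indices: set powers lie on a monotone decay profile (per-athlete
log-normal curvature) pinned to the session's mean power and fatigue
index; kick counts are integers (total distance over the athlete's
preferred kick distance, itself scaled from height) and the per-set
projection distance is re-fit within [0.8, 2.0] m, which regenerates the
target power exactly in the normal range (any residual > 0.5% would be
warned about). Jump trials pin the first-four/last-four plateaus and
interpolate linearly over 30 jumps.

What it does **not** emulate: within-set kick-count stochasticity beyond
rounding, set-order effects other than monotone decay, heteroscedastic or
non-Gaussian measurement error, missing sessions, or any biomechanics of
kicking. Physiological variables are truncated (HR ≤ 220 bpm and rounded
to integers, RPE ∈ [0, 10], lactate ≥ 1 mmol/l) and low-power latents are
floored at small positive values; truncation slightly perturbs the
calibrated moments, which is why round-trip recovery is asserted at ±0.05
rather than exactly. Passing round-trip tests therefore shows the
estimators are correct under the calibrated Gaussian model, not that real
cohorts satisfy that model.

## Problem sizes and numerical choices

The test suite and the acceptance script use: ICC parameter recovery at
n = 2000 athletes × 200 replicates; empirical-vs-closed-form AUC over 500
replicates of 100-per-group normal samples; a generator round trip at
1000 + 800 athletes — sizes at which Monte-Carlo error is comfortably
inside the asserted tolerances while the whole battery runs in seconds.
All randomness flows from explicit seeds (`numpy.random.default_rng`);
the cohort generator is byte-deterministic for a fixed spec and seed.
Ties in the Youden search break toward the first cutoff reaching the
maximal J; ICC CIs fall back to the point estimate when the error mean
square is zero; correlations and regressions on degenerate inputs
(constant vectors, n below the minimum) are reported missing with a
logged warning rather than raised, at the report level.

## Known limitations

* Absolute wattages depend on unpublished segment-percentage choices and
  per-athlete geometry; only formula-level and simulation-level checks are
  possible for them.
* ICC CIs from n = 27 are wide and model-dependent; the package reports
  the model alongside every estimate rather than pretending the choice is
  neutral.
* ROC cutoffs from small two-group samples are highly variable; no
  cross-validation or covariate adjustment is attempted.
* No multiple-testing correction is applied anywhere, matching the
  battery's descriptive, per-variable reporting style.
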