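# Methods

`drlifespan` implements the statistical core of a multi-laboratory dietary
restriction (DR) lifespan analysis in *Drosophila melanogaster*: survival
estimation and testing, Cox proportional-hazards regression, a
likelihood-based variance partition across design covariates, per-replicate
DR/AL significance counting, and a synthetic-data generator emulating the
two-lab factorial design so every stage can be exercised and calibrated at
desk scale. This note records the models, conventions, default parameters and
the reasoning behind design choices that were genuinely open.

## The synthetic experiment

### Mortality model

Each fly's lifetime follows a Gompertz law, the canonical adult-insect aging
model, with hazard

    h(t | x) = a · exp(η(x)) · exp(b t),

i.e. covariates act multiplicatively on the baseline scale *a* (additively on
the log hazard). Sampling uses the closed-form inverse CDF: with survival
S(t) = exp(−(a/b)(e^{bt} − 1)) and u ~ Uniform(0, 1),

    t = (1/b) · ln(1 − (b/a) · ln u).

The linear predictor is

    η = β_genotype + β_sex + β_lab + β_diet + frailty(lab, cohort).

The real study fits no parametric model; Gompertz is the generator's choice
and only the downstream *nonparametric/semiparametric* machinery is under
test.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| design | 2 labs × 4 cohorts × 4 genotypes × 2 sexes × 2 diets | the two-lab factorial blueprint: 64 DR/AL pairs, 128 curves |
| `flies_per_cell` | 125 (16,000 flies) | ≈ the published 15,935 flies over 128 curves (~125/curve); the per-cell split after sexing losses is not published, so the even split is a convenience |
| `gompertz_a`, `gompertz_b` | 3·10⁻⁴ /day, 0.1 /day | baseline median ≈ 54.5 d; with covariate effects all 128 stratum medians stay in a 40–70 d envelope around the published ≈ 53 d |
| genotype β | Canton-S −0.30, Oregon-R −0.40, w1118 +0.35, wDahomey +0.45 | spans ≈ 0.85 on the log hazard; genotype is the dominant factor (population variance 0.143) |
| sex β (M) | +0.25 | males shorter-lived; variance 0.0156, the second tier |
| lab β (lab2) | +0.14 | small systematic lab offset (variance 0.005) |
| diet β (DR) | −0.07 | smallest effect; shifts the median by ~1.3%. The pooled published DR gain (7.1% of median) reflects protocol/genotype mixing that the single log-hazard constant does not target |
| `cohort_frailty_sd` | 0.25 | see below |
| `lab_cohort_frailty_sd` | 0 | optional within-lab run effect |
| `censor_rate` | 0.02 | sporadic food-quality losses; censoring is drawn independently of covariates, and a censored fly's time is uniform on (0, its latent death time) |

Deaths are recorded in continuous time. Real transfer schedules (three times
a week) grid the times and create ties; the Cox machinery handles ties
(Efron/Breslow) and is tested on tied fixtures, but the generator does not
round by default so that tie-free identities (Efron = Breslow, log-rank =
Cox score test) stay exact.

### Cohort "stochasticity" and why it is shared between labs

Cohort-to-cohort variation is modelled as a normal intercept u_c ~ N(0, σ_c²)
drawn once per cohort and **shared by both labs**, plus an optional
independent per-(lab, cohort) run effect v_lc (default off). Two reasons:

1. *Fidelity.* In the emulated design, cohorts differ by concrete protocol
   attributes common to both labs (DR formulation, mating diet). A study can
   only observe large cohort variance alongside very small lab variance if
   most cohort variation is shared between labs: an independent
   per-(lab, cohort) intercept of the size needed for the cohort tier leaks
   its lab-mean difference (sd σ/√2) into the lab contrast and would make
   the "lab" contribution itself wildly stochastic.
2. *Identifiability.* With only 4 cohorts the realised cohort variance is a
   σ_c²·χ²₃/4 draw. Any lab-mean contamination on top of that makes the
   cohort-vs-lab ordering unrecoverable at useful per-seed rates, by any
   estimator.

σ_c = 0.25 places the expected cohort component between sex and genotype
(E ≈ 0.047) with its lower tail safely above the lab component and its upper
tail usually below genotype. Because a 3-df χ² is heavy-tailed, the *realised*
ordering of cohort against its neighbours varies across seeds; recovery tests
therefore compare the fitted contribution ranking against the **realised**
generating ordering. The simulator exposes this ground truth:
`realized_frailty()` returns the intercepts actually drawn and
`realized_variance_components()` the population log-hazard variance per
covariate (for lab, including the lab-mean of the realised frailty). Cohort
and sex are calibrated to comparable magnitudes, so their mutual order
carries no signal and `orderings_match()` treats them as interchangeable by
default.

### RNG discipline

One root seed; every design cell and every frailty draw uses a deterministic
`SeedSequence` substream keyed by cell indices, so identical parameters give
bit-identical datasets and changing one cell's count does not reshuffle the
others.

## Survival machinery

**Kaplan–Meier.** Product-limit estimator over distinct death times;
Greenwood variance S(t)²·Σ d/(n(n−d)); median = smallest event time with
S ≤ 0.5. The 95% CI of the median inverts the pointwise log(−log)
(Brookmeyer–Crowley-style) band at 0.5 — the convention of mainstream
survival software. Censored subjects tied with deaths remain in the risk set
(deaths precede censorings). All-censored input yields a flagged flat curve,
not an exception.

**Log-rank.** Standard two-group test: at each distinct death time the
observed deaths in group 1 are compared with the hypergeometric expectation
and variance given the margins; (ΣO − ΣE)²/ΣV is referred to χ²₁. A
zero-variance configuration returns statistic 0, p 1, flagged degenerate.

**Cox regression.** Log partial likelihood maximised by Newton–Raphson with
step-halving; Efron tie handling by default (Breslow available; they
coincide exactly on tie-free data). Categorical terms are treatment-coded
against the alphabetically first level unless overridden; the maximised
likelihood is invariant to the reference choice. Convergence: gradient
max-norm < 10⁻⁹ or relative log-likelihood change < 10⁻¹², max 50
iterations. Monotone likelihood (perfect separation) is detected via
diverging coefficients (|β| > 10, hazard ratio e¹⁰) and reported as
`converged=False` with a diagnostic, never silently. A rank-deficient design
raises an error naming the collinear terms (pivoted QR). Standard errors
come from the inverse observed information.

**Proportional-hazards diagnostic.** Grambsch–Therneau score tests on
Schoenfeld residuals r_k = x_(k) − x̄(t_k) (risk-set-weighted mean at each
death; the Breslow mean is used for residuals so they are well-defined under
ties). With centred time transform g(t_k), d events and observed information
I:

    global:   χ²_p = d · uᵀ I⁻¹ u / Σ g²,   u = Σ g_k r_k
    per-term: χ²₁ = d · (I⁻¹u)_j² / ((I⁻¹)_jj · Σ g²)

The default transform is the Kaplan–Meier transform g = 1 − S_KM(t)
(identity and rank available). The test requires more events than model
columns. Under exact proportional hazards the global test's measured size is
≈ 4–5% at n = 400 — slightly conservative, as expected for the score-test
approximation.

## Variance partition

"Log-likelihood" means the maximised log **partial** likelihood of the Cox
fit. The full model has all declared covariates (main effects only, mirroring
the emulated analysis); each reduced model drops one covariate. Then

    contribution(X_j) = (ℓ_full − ℓ_reduced,j) / Σ_i (ℓ_full − ℓ_reduced,i)

and Cox–Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ)), with ℓ₀ the β = 0 likelihood of
the full design (identical across nested fits so R² values are comparable)
and n the number of *subjects* (not events) — the common convention; both
are configurable because neither is universal. Negative drops within 10⁻⁶
are clamped to zero with a warning (floating-point slack); anything larger
is a hard error. The pipeline also attaches the PH diagnostic of the full
fit: with genotype-dependent aging the PH assumption is genuinely violated
in data of this shape, and the diagnostic is reported, not enforced.

## DR/AL pair grid

One log-rank test per (lab, cohort, genotype, sex) stratum. The longer-lived
arm is called by comparing KM medians; exact median ties fall back to the
restricted mean (area under the KM curve to the shorter arm's last event);
a still-tied or not-computable pair gets direction "none". ΔL = median(DR) −
median(AL). Familywise error over m pairs uses the Bonferroni threshold
α/m, with significance at p ≤ α/m; nominal tallies use p < 0.05.
Cross-laboratory reproducibility is summarised by Spearman rank correlations
(average ranks, two-sided t-approximation p) of per-stratum median — or,
optionally, restricted-mean — longevities, and of ΔL across matched strata.
The packaged 64-pair published grid exercises the counting machinery without
raw data; its medians are unknown, so direction comes from the published
longer-lived labels.

## Calibration scales used by the tests

Chosen so each check is statistically meaningful on one CPU and the
asymptotic references actually apply at the scale tested:

* **Ordering recovery:** 20 seeds at the full default scale (16,000 flies);
  a seed counts as recovered when the fitted ranking matches the realised
  generating ordering (cohort/sex interchangeable). An a-priori
  flip-probability analysis of estimation noise against component gaps puts
  the per-seed mismatch probability near 2%.
* **Pure-effect recovery:** genotype-only generator at ~8,000 flies,
  20 seeds; median genotype contribution must exceed 0.9 and every other
  covariate's median stay below 0.05.
* **Pair-grid null calibration:** 200 seeds × 64 strata with 200 flies per
  arm and the diet effect set to zero; the nominal rejection rate must be
  5% within twice its Monte-Carlo standard error. The arm size matters: the
  log-rank χ²₁ reference is anti-conservative in small samples (measured
  size ≈ 6.6% at 8 flies/arm, ≈ 5.4% at 50/arm, ≈ 5.2% at 200/arm), so
  calibrating at small arms would measure the approximation, not the
  implementation; a small residual inflation remains visible even at the
  tested scale.
* **PH-test null calibration:** 200 replicates of a 400-subject, one-binary-
  covariate Gompertz design with a constant log-hazard effect (exact
  proportional hazards).

## What the generator does and does not emulate

It reproduces the factorial structure, the effect-size hierarchy, shared
cohort stochasticity, vial bookkeeping and sporadic censoring. It does not
simulate genotype-by-diet interactions (the real grid's strongest feature —
Oregon-R responding, wDahomey not — can be built by passing per-genotype
diet effects to tests, as the localisation test does, but is off by
default), mating-diet carryover, development time, vial effects, body-mass
or climbing phenotypes, or gridded transfer-schedule death times. Passing
recovery tests therefore show the *estimators* behave correctly under the
stated generating model, not that real fly data satisfy that model — indeed
the PH diagnostic is expected to fire on real-scale data with heterogeneous
aging rates.

## Known limitations

* No time-dependent covariates, stratified baselines, or estimated frailty
  terms; the PH violation that genotype-specific aging rates induce is
  reported by the diagnostic but not modelled.
* Contribution percentages depend on the realised cohort draw (χ²₃ with four
  cohorts); only orderings and magnitudes, not exact percentages, are stable
  targets.
* The median CI is undefined (NaN) when the survival curve or its band never
  crosses 0.5 — routine for small strata with light mortality.
* Cox–Snell R² is bounded well below 1 for censored data and is used only to
  compare nested fits, never as an absolute goodness-of-fit measure.
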