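# drlifespan

Survival analysis of dietary-restriction (DR) lifespan experiments in
*Drosophila melanogaster*, built for the question multi-laboratory replication
studies keep raising: **how much of a lifespan outcome is diet, and how much
is genotype, sex, laboratory — or plain stochastic variation between
cohorts?**

The package implements, from first principles, the statistical toolchain such
a study needs, wrapped in statsmodels-style Model/Results objects:

* **Kaplan–Meier** product-limit curves with Greenwood variance and a
  Brookmeyer–Crowley-style log(−log) confidence interval for the median;
* the two-group **log-rank test** (hypergeometric O−E over risk sets);
* **Cox proportional-hazards** regression by Newton–Raphson partial
  likelihood with Efron (default) or Breslow tie handling, plus the
  Grambsch–Therneau **Schoenfeld-residual diagnostic** for the proportional-
  hazards assumption;
* a likelihood-based **variance partition**: with ℓ the maximised log partial
  likelihood, each covariate's share of explanatory power is

      contribution(X_j) = (ℓ_full − ℓ_reduced,j) / Σ_i (ℓ_full − ℓ_reduced,i),

  reported with Cox–Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ)) for the full and each
  reduced model;
* the per-replicate **DR/AL pair grid**: one log-rank test per
  (lab, cohort, genotype, sex) stratum, Bonferroni familywise control (α/m),
  direction-of-effect calls, ΔL = median(DR) − median(AL), and Spearman
  cross-laboratory reproducibility correlations;
* a **synthetic-data generator** emulating a two-lab factorial design
  (2 labs × 4 cohorts × 4 genotypes × 2 sexes × 2 diets, ≈16,000 flies,
  25 per vial): Gompertz mortality with multiplicative covariate effects,
  shared cohort "stochasticity" frailty, and sporadic right-censoring — so
  every stage is testable without any wet-lab data.

A packaged fixture transcribes the 64-pair log-rank grid of a published
two-laboratory fly DR study (labs anonymised to `lab1`/`lab2`), so the
significance-counting machinery can be checked against published tallies.
See `docs/methods.md` for models, conventions, default parameters and their
rationale.

## Worked example

```python
from drlifespan import simulate_dataset, VariancePartition, DietPairAnalysis

df = simulate_dataset(seed=1)                  # 16,000 flies, 128 curves
print(VariancePartition(df).fit().summary())
print(DietPairAnalysis(df).fit().summary())
```

```
Likelihood-based variance partition (Cox partial likelihood, efron ties)
n = 16000, events = 15683
full-model loglik = -134728.422, null = -135891.219, Cox-Snell R2 = 0.1353

           loglik_reduced  loglik_drop  contribution_pct  r2_reduced
covariate
lab          -134748.1635      19.7417            1.6259      0.1331
sex          -134843.4394     115.0176            9.4728      0.1228
cohort       -134819.1731      90.7513            7.4742      0.1254
genotype     -135705.8069     977.3851           80.4967      0.0229
diet         -134739.7184      11.2966            0.9304      0.1341

Proportional-hazards diagnostic (full model, km transform): global chi2 = 12.61 on 9 df, p = 0.181

DR/AL pair grid: 64 pairs, Bonferroni threshold 0.00078125 (familywise alpha 0.05)
significant pairs: 0 favor DR, 0 favor AL
cross-lab longevity correlation: Spearman rho = 0.895, p = 2.33e-23 (n = 64)
cross-lab delta-L correlation: Spearman rho = -0.143, p = 0.434 (n = 32)
```

Reading it: genotype dominates (≈80% of the likelihood-based contribution),
cohort-to-cohort stochasticity and sex form the middle tier, lab is small and
diet — the treatment itself — explains under 1%. Removing genotype collapses
Cox–Snell R² from 0.135 to 0.023 while removing diet barely moves it. With a
uniformly small diet effect no single 125-fly-per-arm pair clears the
Bonferroni bar, yet stratum median lifespans still correlate strongly between
the labs (ρ = 0.895): reproducible biology, elusive per-replicate
significance. (In the real study significant pairs cluster in specific
genotypes — a genotype×diet interaction the generator deliberately omits by
default.)

The published grid ships with the package:

```bash
drlifespan pairs --fixture table3     # JSON: 17 DR-favoring and 5 AL-favoring
                                      # Bonferroni-significant pairs out of 64
```

The CLI also exposes the full pipeline on CSV event tables
(`drlifespan simulate|partition|pairs|report`, see `--help`).

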