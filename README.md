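# twinpheno

Heritability analysis of overlapping impulsivity–compulsivity phenotypes with
the classical twin design.

Impulsivity and compulsivity are usually studied as separate traits. An
alternative view treats them as *overlapping* dimensional phenotypes: an
orthogonal bifactor model of nine questionnaire subscales (UPPS-P urgency,
lack of premeditation, lack of perseverance, sensation seeking; IUS-12
predictability and paralysis; OBQ-44 perfectionism, threat, control of
thoughts) separates a general impulsive–compulsive dimension from narrower
Impulsivity and Obsessiveness group factors. Monozygotic (MZ) and dizygotic
(DZ) twin pairs then identify how much of each dimension's variance is
additive genetic (A²), shared environmental (C²), or unique environmental
plus error (E²), with heritability

    h² = (A² + D²) / (A² + D² + C² + E²).

`twinpheno` implements the full pipeline as a tested library plus CLI:

1. **synthetic twins** — generate twin-pair questionnaire data with a known
   bifactor measurement structure and known A/C/E decomposition per
   phenotype (`twinpheno.simulate`); closed-form population covariance as an
   oracle for every estimator.
2. **measurement model** — orthogonal bifactor CFA fit by full-information
   maximum likelihood (FIML) over arbitrary missingness patterns, with the
   χ²/RMSEA/CFI/SRMR battery, Bollen–Stine bootstrap p, modification-index
   guided post hoc error covariances under Benjamini–Hochberg FDR control
   (`twinpheno.cfa`).
3. **invariance testing** — configural → weak → strong → (partial) strict →
   equal-factor-variance ladder across the twin-1/twin-2 co-twin subsamples
   with nested Δχ² tests and latent-mean z tests (`twinpheno.invariance`).
4. **factor scores** — regression-method scores, per-factor determinacy ρ,
   fixed single-indicator error variances θ_δ = (1−ρ)·σ² (or (1−ρ²)·σ²),
   univariate outlier screening (`twinpheno.scores`).
5. **twin models** — ACE / ADE / AE / CE / E variance-components models on
   the paired scores with measurement error fixed at θ_δ, compared by χ²
   against a per-zygosity saturated model, BIC, and equal-prior BIC weights
   Pr(Hᵢ|D) (`twinpheno.twin`).

The FIML engine (`twinpheno.sem`) is written in-package on numpy/scipy:
missingness-pattern sufficient statistics, analytic gradients, quasi-Newton
optimization with a Newton polish, log-parameterized variances.

## Worked example

```python
from twinpheno import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=42), run_invariance=False)
print(report.dataset_summary["pairs_by_zygosity"])
print({k: round(v, 3) for k, v in report.score_diagnostics["determinacy"].items()})
for pheno, comp in report.comparisons.items():
    print(pheno, {k: round(v, 3) for k, v in comp.posterior.items()})
```

Output from one run (seed 42, default study conditions: 118 MZ + 55 DZ
complete pairs plus 141 singletons):

```
{'DZ': 55, 'MZ': 118}
{'general': 0.914, 'impulsivity': 0.86, 'obsessiveness': 0.852}
general {'ACE': 0.033, 'ADE': 0.024, 'AE': 0.452, 'CE': 0.49, 'E': 0.0}
impulsivity {'ACE': 0.034, 'ADE': 0.034, 'AE': 0.632, 'CE': 0.29, 'E': 0.01}
obsessiveness {'ACE': 0.005, 'ADE': 0.004, 'AE': 0.082, 'CE': 0.088, 'E': 0.821}
```

Reading this: the determinacies say the factor scores track the latent
dimensions well (ρ ≈ 0.85–0.91). The posterior columns are equal-prior BIC
weights over the candidate variance-components models. The general dimension
— generated here with C² = 0.36 and no additive effects — puts most posterior
mass on models without additive genetics (CE preferred, AE close behind:
at 173 pairs the design has limited power to separate them). Impulsivity,
generated with A² = 0.33, prefers AE. Obsessiveness (A² = 0.25) lands on E
at this sample size — a power statement, not a bias: at 5–10× the pair count
the correct model dominates (see the acceptance checks).

The same stages are available as a CLI:

```bash
twinpheno simulate --seed 3 --out twins.csv
twinpheno fit-measurement --data twins.csv
twinpheno invariance --data twins.csv
twinpheno scores --data twins.csv
twinpheno run-all --seed 3 --out results/
```

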