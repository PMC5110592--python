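# aqstruct

Latent-structure analysis of the adult Autism Spectrum Quotient (AQ): does
the 50-item questionnaire measure a continuum of autistic-trait severity,
or does it contain discrete latent classes?  `aqstruct` is aimed at
psychometricians and researchers in autism epidemiology who want to run —
or stress-test — the three families of methods this question is usually
attacked with, in one reproducible Python pipeline:

* **Taxometrics** (MAMBAC, MAXCOV, MAXEIG, L-Mode) on composite indicators
  built from dichotomized items, with bootstrapped comparison data and the
  comparison-curve fit index.  For fits of the observed curve panel to the
  idealized-categorical and idealized-dimensional ensembles,

  CCFI = fit_dim / (fit_cat + fit_dim) ∈ [0, 1],

  where fit is the RMS deviation from the ensemble's pointwise mean curve;
  CCFI > 0.6 supports a categorical structure, < 0.4 a dimensional one.
* **Latent class analysis** — mixtures of Bernoulli item profiles
  P(x | k) = Π_j ρ_kj^{x_j} (1 − ρ_kj)^{1−x_j}, fitted by EM, compared by
  AIC/BIC/SSABIC, relative entropy and the bootstrapped likelihood-ratio
  test, with bivariate-residual local-independence screening.
* **Latent profile analysis** — diagonal Gaussian mixtures on the
  composite indicators, plus a matched-class agreement cross-tabulation
  against the LCA solution.

Because real AQ response datasets are rarely public, the package includes a
first-class synthetic-data module that generates item- and indicator-level
data with known taxonic, dimensional, or six-class structure, calibrated to
the scale of a large non-clinical AQ sample (n ≈ 1139, total-score mean
≈ 21.5, a high-severity class of prevalence ≈ 0.15).

## Worked example

```python
import numpy as np
from aqstruct import synthetic_data as sd, comparison, taxometrics as tx

# four integer composite indicators, n = 1139; a 15% taxon separated by
# d = 2 pooled-SD units with within-class correlation 0.2
spec = sd.PopulationSpec(structure="taxonic", n=1139,
                         class_weights=(0.85, 0.15),
                         target_d=2.0, within_class_r=0.2, seed=1)
ind, labels = sd.generate_continuous_indicators(spec)

results = comparison.ccfi_analysis(ind, base_rate=0.15, B=100, seed=11)
for proc, ens in results.items():
    print(f"{proc}: CCFI = {ens.ccfi:.3f} ({ens.label})")

est = tx.estimate_base_rates(tx.maxcov_panel(ind, seed=3))
print(f"MAXCOV base rate (averaged curve): {est.averaged_curve:.3f}")
print(f"L-Mode base rate: {tx.lmode_analysis(ind).base_rate:.3f}")
```

Output:

```
MAMBAC: CCFI = 0.799 (categorical)
MAXCOV: CCFI = 0.812 (categorical)
MAXEIG: CCFI = 0.846 (categorical)
LMODE: CCFI = 0.826 (categorical)
MAXCOV base rate (averaged curve): 0.147
L-Mode base rate: 0.140
```

All four procedures land above the 0.6 categorical threshold, and the
covariance-peak and factor-score estimators recover the generating taxon
prevalence of 0.15 to within window resolution.  Re-running
`ccfi_analysis` on the moment-matched dimensional variant
(`structure="dimensional"`) drives the mean CCFI below 0.4.

The full pipeline (score → indicators → taxometrics + CCFI → LCA → LPA →
report with tables and comparison-curve figures) is available as a CLI:

```sh
aqstruct run --seed 1 --outdir run1       # synthetic six-class demo
aqstruct simulate -n 1139 items.csv       # write a synthetic item CSV
aqstruct score items.csv totals.csv
aqstruct lca items.csv --k-max 9
```

## Layout

| module | contents |
|---|---|
| `aqstruct.synthetic_data` | taxonic / dimensional / six-class generators, CSV+YAML I/O |
| `aqstruct.scoring` | dichotomization, imputation, descriptives, putative-taxon cut |
| `aqstruct.indicators` | principal-axis EFA, varimax, retention suite, composites, validity screen |
| `aqstruct.taxometrics` | MAMBAC / MAXCOV / MAXEIG / L-Mode curves and base rates |
| `aqstruct.comparison` | bootstrapped comparison ensembles and the CCFI |
| `aqstruct.lca` | binary latent class models, fit indices, BLRT, residuals, covariate logit |
| `aqstruct.lpa` | Gaussian profile mixtures and LCA/LPA agreement |
| `aqstruct.pipeline`, `aqstruct.cli` | end-to-end orchestration and the `aqstruct` command |

See `docs/methods.md` for the statistical details and the design choices
behind each stage.
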