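# urinorm

Normalization of quantitative urinary metabolomics data, and a systematic
comparison of how the choice of normalization propagates into
epidemiological analyses.

## The problem

Spot-urine metabolite concentrations are confounded by urine water volume:
every metabolite in sample *i* is multiplied by the same unknown dilution
factor *d<sub>i</sub>*, which varies widely day-to-day and person-to-person.
Before metabolite concentrations can be correlated with each other or
regressed against clinical outcomes, this per-sample scale must be divided
out. Several conventions coexist, and they do not agree; this package
implements all of them as pure transforms, plus the downstream analysis
protocol needed to quantify how much the choice matters.

Each scheme estimates a per-sample scale factor *s<sub>i</sub>* and returns
*x<sub>ij</sub> / s<sub>i</sub>*:

| Scheme | *s<sub>i</sub>* |
|---|---|
| **ABS** | 1 (absolute concentrations, no normalization) |
| **IS-CREA / IS-GLUC / IS-UREA / IS-PSEURID** | concentration of one internal-standard metabolite (creatinine, glucose, urea, pseudouridine) |
| **CS** | constant sum: Σ<sub>j</sub> x<sub>ij</sub> over all quantified metabolites |
| **PQN** | probabilistic quotient: median<sub>j</sub> of x<sub>ij</sub> / r<sub>j</sub>, with reference profile r<sub>j</sub> = median over samples |
| **DESEQ2** | same quotient construction with r<sub>j</sub> = geometric mean over samples (the median-of-ratios size factor from RNA-seq) |

Downstream, the package provides the standard epidemiological protocol:
sex-adjusted Spearman metabolite–metabolite correlation heat maps ordered by
two-dimensional hierarchical clustering of a reference scheme; extreme-value
truncation to Q3 + 8×IQR followed by log transform and SD-unit linear
regression of each metabolite against clinical outcomes (BMI, mean arterial
pressure); and a Bonferroni threshold α / m<sub>eff</sub> where
m<sub>eff</sub> is the number of principal components explaining >99% of the
metabolome's variance. A concordance module quantifies cross-scheme
agreement: pairwise mean R² over metabolites, correlation-matrix similarity,
association sign concordance, and — on synthetic data — recovery of the true
dilution factors, corr(log s<sub>i</sub>, log d<sub>i</sub>).

Because real urine cohorts ship without ground truth, the package includes a
first-class synthetic cohort generator: ~44 log-normal metabolites spanning
orders of magnitude (urea and creatinine dominant), correlated clusters, a
shared log-normal dilution factor, sex effects (creatinine as a muscle-mass
proxy), and outcomes built from standardized log concentrations so every
true SD-unit effect is known exactly.

## Worked example

```python
from urinorm import (GeneratorConfig, generate_cohort, normalize_all,
                     effective_tests, bonferroni_threshold, association_scan,
                     dilution_recovery, sign_concordance)

table, covariates, truth = generate_cohort(GeneratorConfig(n_samples=500, seed=11))
tables = normalize_all(table)                      # ABS, 4x IS, CS, PQN, DESEQ2
m_eff = effective_tests(table)                     # PCA effective test count
thr = bonferroni_threshold(0.05, m_eff)
print(f"m_eff = {m_eff}, p threshold = {thr.threshold}")
for t in tables[1:]:
    print(f"{t.label:<11} dilution recovery r = {dilution_recovery(t, truth):.3f}")
```

prints

```
m_eff = 41, p threshold = 0.0012
IS-CREA     dilution recovery r = 0.769
IS-GLUC     dilution recovery r = 0.639
IS-UREA     dilution recovery r = 0.734
IS-PSEURID  dilution recovery r = 0.907
CS          dilution recovery r = 0.772
PQN         dilution recovery r = 0.958
DESEQ2      dilution recovery r = 0.959
```

Of 44 correlated metabolites, 41 principal components are needed to explain
99% of the variance, so the family-wise 5% threshold relaxes only slightly,
to p < 0.0012. The quotient schemes (PQN, DESeq2-style) track the true
dilution factor far better than any single internal standard, and better
than the constant sum, whose estimate is dominated by urea. Continuing,

```python
records = association_scan(tables, covariates[["BMI", "MAP"]],
                           covariates=covariates[["sex"]],
                           threshold=thr, sex_adjusted=True)
robust = [r for r in records if r.scheme == "IS-CREA" and r.robust]
print(f"IS-CREA robust associations: {len(robust)}")
for r in robust[:2]:
    print(f"  {r.metabolite:<10} ~ {r.outcome}: beta = {r.beta:+.3f} "
          f"(SE {r.se:.3f}), p = {r.p_value:.2e}")
print(sign_concordance(records, "IS-CREA"))
```

```
IS-CREA robust associations: 16
  tyrosine   ~ BMI: beta = +0.246 (SE 0.045), p = 8.95e-08
  valine     ~ BMI: beta = +0.251 (SE 0.045), p = 4.60e-08
```

The betas are in SD units (SD of outcome per SD of log metabolite); planted
generator effects (e.g. valine → BMI at 0.25–0.30) are recovered within
sampling error, and the sign concordance of CS/PQN/DESEQ2 with the IS-CREA
reference over its robust associations is 1.0 here — different normalizations
move effect magnitudes but rarely flip the direction of a robust association.

The same pipeline runs from the shell:

```bash
urinorm run --seed 11 --out results/demo        # generate -> normalize ->
                                                # correlate -> associate -> compare
urinorm normalize cohort/metabolites.csv --method pqn
urinorm correlate cohort/metabolites.csv --scheme is-crea \
    --covariates cohort/covariates.csv --n-clusters 8
```

Every run writes a JSON manifest (config, seed, versions) from which all
numeric outputs are exactly regenerable.

## Layout

- `urinorm.cohort` — synthetic cohort generator with stored ground truth
- `urinorm.normalize` — the eight data versions (ABS, IS×4, CS, PQN, DESEQ2)
- `urinorm.correlations` — sex-adjusted Spearman maps, clustering, display order
- `urinorm.regression` — truncation, SD-unit association scan, PCA-based m_eff
- `urinorm.concordance` — cross-scheme agreement and dilution recovery
- `urinorm.io` / `urinorm.cli` — delimited-text I/O, pipeline, subcommand CLI

See `docs/methods.md` for the model, parameter choices and limitations.
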