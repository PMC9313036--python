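# Methods

## Normalization schemes

All schemes are pure transforms of a strictly positive sample × metabolite
concentration matrix X. Concentrations below detection are outside the data
model: zeros are rejected at load, never imputed, so the geometric mean and
all quotients are always defined.

**ABS** is the identity (s_i = 1) and serves as the dilution-confounded
baseline. **IS** divides each row by one reference column and drops that
column from the output — its normalized value is identically 1, and keeping
it would plant spurious blank structure in correlation maps. **CS** divides
each row by its summed concentration over a configurable subset (default:
all columns), producing compositions that sum to 1.

**PQN** proceeds in four steps: (1) optionally prescale each row to its
constant sum; (2) take the per-metabolite median across samples as the
reference profile r_j; (3) form quotients q_ij = x_ij / r_j; (4) use the
per-sample median of the quotients as the scale factor. The prescaling flag
(`pqn_pre_cs`, default on) matches the original probabilistic-quotient
recipe, in which the reference is built from *relative* concentrations; the
raw-reference variant is provided because both readings occur in practice.
A single-sample table is its own reference, giving s = 1. **DESEQ2** is the
same quotient construction with the per-metabolite geometric mean of the
absolute concentrations as the reference and no prescaling — the
median-of-ratios size factor familiar from RNA-seq, without the
zero-handling that counts require.

`NormalizedTable.scale_factors` always stores the **total** divisor of the
raw input (for prescaled PQN this is the row sum times the median quotient),
so `values = raw / s` holds uniformly and corr(log s, log d) is a meaningful
dilution-recovery measure for every scheme.

### Dilution invariance

Multiplying one sample's row by c > 0 is exactly absorbed by IS, CS and
prescaled PQN even when the scheme is refit on the perturbed table. For the
raw-reference quotient schemes (PQN without prescaling, DESEQ2) the
reference profile itself shifts when a single sample is rescaled (a median
order statistic can move; a geometric mean moves by c^(1/n)), so exact
single-sample invariance is a property of the **per-sample transform given
a reference profile**, not of refitting: against a fixed reference the
scale factor changes by exactly c and the normalized values are unchanged.
Both entry points exist (`reference=` parameter), and the invariance suite
tests each scheme in the form that holds exactly. In large cohorts the
refitted and fixed-reference behaviours coincide to O(1/n).

## Synthetic cohort generator

The generator emulates a morning spot-urine NMR cohort with known truth:

    log c_ij = mu_j + beta_sex_j * sex_i
               + sigma_j (sqrt(rho) F_{i,k(j)} + sqrt(1-rho) u_ij) + nu e_ij
    x_ij     = c_ij * d_i,   log d_i ~ N(0, dilution_log_sd²)

Choices and defaults, with rationale:

- **Log-normality** for concentrations and dilution: positivity plus the
  fat-tailed abundance behaviour of urinary metabolites. Abundance means
  mu_j span >3 natural-log orders (≈0.004–1 mmol/L) with urea (~250 mmol/L)
  and creatinine (~10 mmol/L) dominant, so the constant sum is genuinely
  urea-driven, as in real urine.
- **Clusters**: 8 planted clusters, round-robin assignment, factor-model
  correlation `within_cluster_corr = 0.5` on the biological component.
  With biological SD 0.6 and measurement noise SD 0.1 the realized
  log-scale correlation is rho·sigma²/(sigma²+nu²) ≈ 0.49.
- **dilution_log_sd = 0.6**: spot-urine osmolality spans roughly an order
  of magnitude across individuals; ±2 SD then covers an ~11-fold dilution
  range. This is a free parameter of the generator, not a cohort estimate.
- **Sex effects** on the log scale: creatinine +0.35 (muscle mass),
  3-methylhistidine +0.20, urea +0.10, with sex coded 0 = female, 1 = male.
  These make the known IS-CREA muscle-mass bias testable.
- **Glucose heavy tail**: with probability 0.08 a sample's log glucose gets
  a +1.2 bump, emulating saturated tubular reabsorption spilling glucose
  into urine; this is what degrades IS-GLUC dilution recovery.
- **Pseudouridine** gets the smallest biological SD (0.25), reflecting the
  near-constant whole-body RNA turnover that motivates it as a standard.
- **Outcomes** are linear combinations of sample-standardized log
  physiological concentrations plus Gaussian noise scaled so the latent
  outcome variance is ~1; the configured coefficients are therefore SD-unit
  effects, exact up to sampling error. Default effect metabolites sit in
  distinct clusters so each marginal SD-unit beta equals its configured
  value. BMI = 26 + 4·u (kg/m²); MAP = 93 + 8·u (mmHg) with a positive
  pulse pressure so SBP ≥ DBP > 0 and MAP = (SBP + 2·DBP)/3 holds exactly.
- **Randomness**: one global seed; per-component sub-streams are spawned
  from it, so adding or disabling a component never perturbs the others,
  and reruns are bit-identical.

What the generator does **not** emulate: NMR spectral artefacts and
quantification error structure, detection limits / censoring, kidney
function (eGFR) as a confounder, non-Gaussian biological dependence beyond
the one-factor cluster model, and any cohort-specific correlation topology.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behaviour of the schemes under dilution, not agreement with any
particular real cohort's cluster memberships or association counts.

## Correlation structure

"Spearman adjusted for sex" is a rank-residual partial correlation:
average-rank transform, least-squares residualization of the ranks on an
intercept plus covariates, Pearson correlation of residuals. With no
covariates this is exactly classical Spearman. Undefined correlations
(zero residual variance, or the excluded IS reference) are carried as
blanked entries, never silently filled.

Display ordering uses agglomerative clustering on the dissimilarity
1 − rho. The linkage criterion is configurable {single, complete, average,
ward} with **average** as default — a conventional choice for correlation
dissimilarities; ties break deterministically by original index. The
default cut at **8 clusters** is a display convention, not an inferential
claim. Other schemes are re-rendered in the reference scheme's leaf order
without recomputation; creatinine, excluded from the IS-CREA matrix, is
appended as the last display row.

## Regression protocol

Per metabolite and scheme, on the normalized scale: truncate above
Q3 + 8×IQR (linear-interpolation quartiles — the common default; with
IQR = 0 the cap is Q3), log-transform, standardize to unit SD; regress the
z-scored outcome on the z-scored log metabolite by OLS, optionally with sex
as a covariate. Betas are SD-per-SD; they are invariant to any positive
rescaling of the input but deliberately **not** invariant across
normalization schemes — that difference is the object of study. Outcomes
are z-scored only, not otherwise transformed.

The effective number of tests m_eff is the smallest k whose top-k
eigenvalues of the correlation matrix of the log-standardized
absolute-concentration matrix exceed 99% of the total (the scheme used for
the PCA is configurable; the absolute matrix is the default so the
threshold does not depend on the normalization under comparison). The
family-wise threshold alpha/m_eff is rounded to two significant digits for
reporting; the robust flag compares p against this rounded threshold.

## Concordance measures

Pairwise mean R² between schemes is computed per shared metabolite on the
**log** scale (Pearson of logs, squared, averaged; a flag switches to the
raw scale) — logs stabilize the heavy-tailed distributions and match the
regression transform. Sign concordance against a reference scheme is
restricted to the reference's robust cells, since direction consistency is
only meaningful above the noise floor. Matrix similarity is the Pearson
correlation of the strict lower triangles over metabolites defined in both
maps. Dilution recovery is corr(log s_i, log d_i) and is undefined (NaN
with a warning) for ABS, whose scale factors are constant.

## Numerical conventions

Medians over an even count are the mean of the two central order
statistics. Quantiles use linear interpolation. Standardization uses the
n−1 denominator. Tables are written as UTF-8 CSV/TSV with 6 significant
digits; correlation and similarity values are clipped to [−1, 1] against
float drift; positivity and rank checks use absolute guards at 1e-12.

## Problem sizes

Default analyses run at n = 500–1000 samples × 44 metabolites; the
acceptance script uses n = 994 for its main cohort and 50 replicate
cohorts of n = 1000 for effect-recovery rates. These sizes put Monte-Carlo
error well inside the tolerances asserted (SE of a correlation at n ≈ 1000
is ~0.03 or less) while keeping the full suite fast.

## Known limitations

- Osmolality, specific-gravity and dry-mass normalization are out of scope
  (they need measurements this data model does not carry).
- The scan fits independent per-metabolite OLS models; no mixed models,
  longitudinal structure, or kidney-function adjustment.
- Cohort-specific quantities (cluster memberships, robust-association
  counts) are data-dependent and are reported descriptively, not asserted.
- CS/PQN/DESEQ2 outputs are compositional: normalized concentrations are
  interdependent, and correlated biological variation across many
  metabolites can still produce normalization artefacts — the package
  measures this (it is visible as the CS row-sum constraint and the
  weakened within-cluster correlations under PQN/DESEQ2) but does not
  correct for it.
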