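"""Metabolome-wide regression protocol with PCA-based multiple testing.

For each (normalization scheme, metabolite, outcome) cell the protocol is:

1. truncate extreme metabolite levels to Q3 + 8 x IQR (linear-interpolation
   quartiles),
2. natural-log transform and standardize to zero mean / unit SD,
3. ordinary least squares of the standardized outcome on the standardized
   log metabolite, optionally adjusting for sex, reporting the SD-unit
   beta, its SE and the two-sided p value,
4. declare an association robust when p falls below a Bonferroni threshold
   alpha / m_eff, where the effective number of independent tests m_eff is
   the number of principal components needed to explain a cumulative
   variance criterion (default 99%) of the log-standardized concentration
   matrix — correlated metabolites should not each count as a full test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .normalize import NormalizedTable
from .tables import as_positive_frame


@dataclass
class AssociationRecord:
    """One metabolite-outcome association under one normalization scheme."""

    metabolite: str
    outcome: str
    scheme: str
    beta: float          # SD outcome per SD log-metabolite
    se: float
    p_value: float
    n: int
    sex_adjusted: bool
    robust: bool = False


@dataclass
class ScanThreshold:
    """Family-wise error threshold relaxed by the effective test count."""

    alpha: float
    m_eff: int
    threshold: float
    variance_cut: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m_eff < 1:
            raise ValueError("m_eff must be >= 1")


def truncate_extremes(values) -> tuple[np.ndarray, int]:
    """Cap values above Q3 + 8 x IQR; return (capped values, number capped).

    Quartiles use the linear-interpolation convention. With IQR = 0 the cap
    is Q3 itself, leaving a constant vector unchanged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if arr.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation
    cap = q3 + 8.0 * (q3 - q1)
    count = int((arr > cap).sum())
    return np.minimum(arr, cap), count


def prepare_metabolite(values) -> np.ndarray:
    """Truncate, log-transform, and standardize one metabolite vector.

    The result has mean 0 and SD 1; any positive rescaling of the input
    (a change of units, or a global scale factor) yields the same output.
    """
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("metabolite values must be strictly positive")
    capped, _ = truncate_extremes(arr)
    logged = np.log(capped)
    sd = logged.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero variance after log transform")
    return (logged - logged.mean()) / sd


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero-variance outcome")
    return (values - values.mean()) / sd


def _name_collinear_column(design: np.ndarray, names: list[str]) -> str:
    rank = np.linalg.matrix_rank(design)
    for j in range(design.shape[1] - 1, -1, -1):
        if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank:
            return names[j]
    return names[-1]


def fit_association(metabolite, outcome, covariates=None, *, scheme: str = "",
                    metabolite_name: str = "", outcome_name: str = "",
                    sex_adjusted: bool | None = None,
                    threshold: ScanThreshold | None = None) -> AssociationRecord:
    """OLS of the standardized outcome on standardized log-metabolite z-scores.

    ``metabolite`` should already be z-scores (see :func:`prepare_metabolite`);
    the outcome is z-scored internally so ``beta`` is in SD/SD units.
    """
    x = np.asarray(metabolite, dtype=float)
    y = _zscore(np.asarray(outcome, dtype=float))
    names = ["intercept", metabolite_name or "metabolite"]
    design = np.column_stack([np.ones_like(x), x])
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        design = np.column_stack([design, cov.to_numpy(dtype=float)])
        names += [str(c) for c in cov.columns]
    n, k = design.shape
    if n <= k + 1:
        raise ValueError("too few samples for the number of predictors")
    if np.linalg.matrix_rank(design) < k:
        culprit = _name_collinear_column(design, names)
        raise ValueError(f"rank-deficient design: column {culprit!r} is collinear")
    fit = sm.OLS(y, design).fit()
    p = float(fit.pvalues[1])
    record = AssociationRecord(
        metabolite=metabolite_name,
        outcome=outcome_name,
        scheme=scheme,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=p,
        n=n,
        sex_adjusted=bool(covariates is not None if sex_adjusted is None else sex_adjusted),
        robust=bool(threshold is not None and p < threshold.threshold),
    )
    return record


def effective_tests(table, variance_cut: float = 0.99) -> int:
    """Effective number of independent tests from a PCA of the metabolome.

    The concentration matrix is log-transformed and column-standardized
    internally; m_eff is the smallest k whose top-k eigenvalues of the
    correlation matrix cumulatively exceed ``variance_cut`` of the total.
    """
    frame = as_positive_frame(table)
    if not 0 <= variance_cut < 1:
        raise ValueError("variance_cut must be in [0, 1)")
    logged = np.log(frame.to_numpy())
    sd = logged.std(axis=0, ddof=1)
    if (sd < 1e-12).any():
        bad = frame.columns[int(np.argmax(sd < 1e-12))]
        raise ValueError(f"zero-variance metabolite {bad!r}")
    z = (logged - logged.mean(axis=0)) / sd
    eigvals = np.linalg.eigvalsh(np.corrcoef(z, rowvar=False))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    cumulative = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(cumulative, variance_cut, side="right") + 1)


def bonferroni_threshold(alpha: float, m_eff: int,
                         variance_cut: float = 0.99) -> ScanThreshold:
    """Family-wise threshold alpha / m_eff, rounded to 2 significant digits."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    raw = alpha / m_eff
    digits = 1 - int(math.floor(math.log10(abs(raw))))
    return ScanThreshold(
        alpha=alpha,
        m_eff=int(m_eff),
        threshold=round(raw, digits),
        variance_cut=variance_cut,
    )


def association_scan(tables, outcomes, covariates=None, *,
                     threshold: ScanThreshold,
                     sex_adjusted: bool = True) -> list[AssociationRecord]:
    """Regress every metabolite of every scheme against every outcome.

    ``tables`` is a list of :class:`NormalizedTable` sharing one sample
    set; ``outcomes`` a DataFrame of outcome columns (e.g. BMI, MAP);
    ``covariates`` the adjustment variables (used when ``sex_adjusted``).
    Returns one record per (scheme, metabolite, outcome), ordered by
    scheme, then outcome, then metabolite — internal-standard schemes
    contribute one metabolite fewer (their reference is excluded).
    """
    outcomes = pd.DataFrame(outcomes)
    sample_index = tables[0].values.index
    for t in tables:
        if not t.values.index.equals(sample_index):
            raise ValueError(f"sample set mismatch in scheme {t.label}")
    cov = None
    if sex_adjusted:
        if covariates is None:
            raise ValueError("sex_adjusted scan requires covariates")
        cov = pd.DataFrame(covariates).loc[sample_index]
    records: list[AssociationRecord] = []
    for table in tables:
        prepared = {m: prepare_metabolite(table.values[m]) for m in table.metabolites}
        for outcome in outcomes.columns:
            y = outcomes[outcome].loc[sample_index].to_numpy(dtype=float)
            for metabolite in table.metabolites:
                records.append(
                    fit_association(
                        prepared[metabolite], y, cov,
                        scheme=table.label,
                        metabolite_name=metabolite,
                        outcome_name=str(outcome),
                        sex_adjusted=sex_adjusted,
                        threshold=threshold,
                    )
                )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten association records into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "scheme": r.scheme,
                "metabolite": r.metabolite,
                "outcome": r.outcome,
                "sex_adjusted": r.sex_adjusted,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "p": r.p_value,
                "robust": r.robust,
            }
            for r in records
        ]
    )
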