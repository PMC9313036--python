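"""Covariate-adjusted Spearman correlation structure of the metabolome.

Metabolite-metabolite association heat maps are the primary visual device
for comparing normalization schemes: the matrix for a reference scheme
(conventionally IS-CREA) is ordered by two-dimensional hierarchical
clustering, and every other scheme is rendered in that fixed metabolite
order so differences are attributable to the normalization, not to the
layout.

"Spearman adjusted for sex" is operationalized as a rank-residual partial
correlation: rank-transform each variable (average ranks on ties),
residualize the ranks on an intercept plus the covariates by least
squares, and take the Pearson correlation of the residuals. With no
covariates this reduces exactly to the classical Spearman rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .normalize import NormalizedTable

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class CorrelationResult:
    """A symmetric metabolite x metabolite correlation matrix plus display state.

    ``blanked`` lists metabolites whose correlations are undefined for this
    scheme (the internal-standard reference metabolite, left blank in its
    own heat map). ``display_order`` is a permutation of the metabolite
    names used purely for rendering; entry (a, b) never depends on it.
    """

    matrix: pd.DataFrame
    scheme: str
    adjusted_for: tuple[str, ...] = ()
    display_order: tuple[str, ...] = ()
    cluster_labels: dict[str, int] | None = None
    blanked: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.display_order:
            self.display_order = tuple(self.matrix.columns)

    @property
    def metabolites(self) -> list[str]:
        return list(self.matrix.columns)

    def ordered_matrix(self) -> pd.DataFrame:
        """The matrix permuted to display order (a pure view)."""
        order = [m for m in self.display_order if m in self.matrix.columns]
        return self.matrix.loc[order, order]


def _residualize_ranks(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Rank-transform each column, then residualize on intercept + covariates."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    n = ranks.shape[0]
    design = np.ones((n, 1))
    if covariates is not None and covariates.size:
        design = np.column_stack([design, covariates])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def partial_spearman(x, y, covariates=None) -> float:
    """Spearman rank correlation of x and y, partialled on covariates.

    Returns NaN when either rank-residual has zero variance (the
    correlation is undefined, e.g. a constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size and cov.shape[0] != x.size:
            raise ValueError("covariate rows must match observations")
    resid = _residualize_ranks(np.column_stack([x, y]), cov)
    sd = resid.std(axis=0)
    if (sd < 1e-12).any():
        return float("nan")
    r = float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(norm, covariates=None, adjust: bool = True) -> CorrelationResult:
    """All pairwise (partial) Spearman correlations of a normalized table.

    ``covariates`` is a DataFrame (or array) of adjustment variables,
    typically the single column ``sex``; pass ``adjust=False`` (or no
    covariates) for the unadjusted analysis. For internal-standard schemes
    the excluded reference metabolite is recorded as blanked. Creatinine,
    when present, is moved to the last display row, mirroring the heat-map
    convention of appending the customary reference below the clustered
    block.
    """
    if isinstance(norm, NormalizedTable):
        frame = norm.values
        scheme = norm.label
        blanked = tuple(norm.excluded)
    else:
        frame = pd.DataFrame(norm)
        scheme = ""
        blanked = ()
    if len(frame) < 4:
        raise ValueError("need at least 4 samples")
    adjusted_for: tuple[str, ...] = ()
    cov_arr = None
    if adjust and covariates is not None:
        cov_frame = pd.DataFrame(covariates)
        cov_frame = cov_frame.loc[frame.index] if cov_frame.index.equals(
            frame.index) or set(frame.index) <= set(cov_frame.index) else cov_frame
        cov_arr = cov_frame.to_numpy(dtype=float)
        adjusted_for = tuple(str(c) for c in cov_frame.columns)
    resid = _residualize_ranks(frame.to_numpy(dtype=float), cov_arr)
    sd = resid.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr[np.ix_(sd < 1e-12, np.arange(len(sd)))] = np.nan
    corr[np.ix_(np.arange(len(sd)), sd < 1e-12)] = np.nan
    np.fill_diagonal(corr, np.where(sd < 1e-12, np.nan, 1.0))
    matrix = pd.DataFrame(corr, index=frame.columns, columns=frame.columns)
    degenerate = tuple(matrix.columns[sd < 1e-12])
    order = [m for m in matrix.columns if m != "creatinine"]
    if "creatinine" in matrix.columns:
        order.append("creatinine")
    return CorrelationResult(
        matrix=matrix,
        scheme=scheme,
        adjusted_for=adjusted_for,
        display_order=tuple(order),
        blanked=tuple(dict.fromkeys(blanked + degenerate)),
    )


def cluster_order(result: CorrelationResult, linkage: str = "average",
                  n_clusters: int = 8) -> CorrelationResult:
    """Order a correlation matrix by two-dimensional hierarchical clustering.

    Agglomerative clustering on the dissimilarity 1 - rho; the display
    order is the dendrogram leaf order and ``cluster_labels`` come from
    cutting the tree into ``n_clusters`` groups. Fully deterministic for a
    given matrix (scipy's linkage breaks ties by original index).
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    matrix = result.matrix
    if matrix.isna().any().any():
        raise ValueError("cannot cluster a matrix with undefined (blanked) entries")
    p = matrix.shape[0]
    if not 1 <= n_clusters <= p:
        raise ValueError("need 1 <= n_clusters <= number of metabolites")
    dist = 1.0 - matrix.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    leaves = hierarchy.leaves_list(tree)
    labels = hierarchy.fcluster(tree, t=n_clusters, criterion="maxclust")
    names = list(matrix.columns)
    return replace(
        result,
        display_order=tuple(names[i] for i in leaves),
        cluster_labels={names[i]: int(labels[i]) for i in range(p)},
    )


def apply_reference_order(result: CorrelationResult,
                          reference: CorrelationResult) -> CorrelationResult:
    """Re-render one scheme's matrix in another scheme's display order.

    Correlations are not recomputed; only ``display_order`` changes.
    Metabolites absent from the reference are tolerated only if they are
    the reference scheme's blanked/excluded metabolites (e.g. creatinine
    when ordering by the IS-CREA map); they are appended at the end, in
    keeping with the creatinine-last heat-map convention.
    """
    ref_known = set(reference.display_order) | set(reference.blanked)
    extra = [m for m in result.metabolites if m not in ref_known]
    if extra:
        raise ValueError(
            f"reference ordering is missing non-blanked metabolites: {extra}"
        )
    present = set(result.metabolites)
    order = [m for m in reference.display_order if m in present]
    order += [m for m in result.metabolites if m not in set(order)]
    labels = None
    if reference.cluster_labels is not None:
        labels = {m: c for m, c in reference.cluster_labels.items() if m in present}
    return replace(result, display_order=tuple(order), cluster_labels=labels)
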