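"""Agreement measures between normalization schemes.

Four complementary views of how much the choice of normalization matters:

* per-metabolite mean R² between every unordered pair of schemes (the
  eight standard data versions give C(8, 2) = 28 pairs),
* correlation-matrix similarity (Pearson correlation of the vectorized
  lower triangles of two metabolite-metabolite correlation maps),
* sign concordance of association betas against a reference scheme over
  the cells the reference calls robust,
* dilution-factor recovery — the correlation between a scheme's log scale
  factors and the true log dilution factors of a synthetic cohort, the
  directly mechanistic measure of normalization quality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SyntheticTruth
from .normalize import NormalizedTable
from .regression import AssociationRecord


@dataclass
class SchemePairSummary:
    """Mean per-metabolite R² between two schemes' normalized values."""

    scheme_a: str
    scheme_b: str
    mean_r2: float
    n_metabolites: int


def _pair_mean_r2(a: NormalizedTable, b: NormalizedTable, log: bool) -> SchemePairSummary:
    shared = [m for m in a.metabolites if m in set(b.metabolites)]
    if not shared:
        raise ValueError(f"no shared metabolites between {a.label} and {b.label}")
    xa = a.values[shared].to_numpy(dtype=float)
    xb = b.values[shared].to_numpy(dtype=float)
    if log:
        xa, xb = np.log(xa), np.log(xb)
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    num = (xa * xb).sum(axis=0)
    den = np.sqrt((xa ** 2).sum(axis=0) * (xb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    # a metabolite constant in both versions is trivially concordant;
    # constant in only one contributes r = 0
    both_const = ((xa ** 2).sum(axis=0) < 1e-300) & ((xb ** 2).sum(axis=0) < 1e-300)
    r = np.where(both_const, 1.0, r)
    return SchemePairSummary(
        scheme_a=a.label,
        scheme_b=b.label,
        mean_r2=float(np.mean(np.clip(r, -1, 1) ** 2)),
        n_metabolites=len(shared),
    )


def pairwise_mean_r2(tables, log: bool = True) -> list[SchemePairSummary]:
    """Mean R² for every unordered pair of schemes.

    For each metabolite shared by a pair (IS reference metabolites are
    excluded from their own scheme, hence from that pair), the squared
    Pearson correlation between the two normalized versions is computed —
    on the log scale by default, which tames the heavy-tailed abundance
    distributions — and averaged.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two schemes to compare")
    index = tables[0].values.index
    for t in tables:
        if not t.values.index.equals(index):
            raise ValueError(f"sample set mismatch in scheme {t.label}")
    return [
        _pair_mean_r2(a, b, log) for a, b in itertools.combinations(tables, 2)
    ]


def matrix_similarity(a, b) -> float:
    """Pearson correlation of two correlation maps' lower-triangle entries.

    Only metabolite pairs defined (non-blanked) in both maps contribute;
    at least 3 shared entries are required.
    """
    shared = [m for m in a.matrix.columns
              if m in set(b.matrix.columns)
              and m not in set(a.blanked) and m not in set(b.blanked)]
    ma = a.matrix.loc[shared, shared].to_numpy(dtype=float)
    mb = b.matrix.loc[shared, shared].to_numpy(dtype=float)
    rows, cols = np.tril_indices(len(shared), k=-1)
    va, vb = ma[rows, cols], mb[rows, cols]
    keep = ~(np.isnan(va) | np.isnan(vb))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared correlation entries")
    return float(np.corrcoef(va[keep], vb[keep])[0, 1])


def sign_concordance(records, reference_scheme: str) -> dict[str, float]:
    """Fraction of reference-robust associations with matching beta sign.

    Cells are (metabolite, outcome, adjustment) triples; the comparison is
    restricted to cells the reference scheme flags robust, since direction
    consistency is only meaningful for associations that clear the
    multiple-testing threshold. Every scheme must cover every reference
    cell (IS reference metabolites excluded from a scheme's own table are
    the one tolerated gap and are skipped for that scheme).
    """
    records = list(records)
    by_scheme: dict[str, dict[tuple, AssociationRecord]] = {}
    for rec in records:
        by_scheme.setdefault(rec.scheme, {})[
            (rec.metabolite, rec.outcome, rec.sex_adjusted)
        ] = rec
    if reference_scheme not in by_scheme:
        raise ValueError(f"no records for reference scheme {reference_scheme!r}")
    reference = by_scheme[reference_scheme]
    robust_cells = [cell for cell, rec in reference.items() if rec.robust]
    result: dict[str, float] = {}
    for scheme, cells in by_scheme.items():
        own_metabolites = {cell[0] for cell in cells}
        relevant = [c for c in robust_cells if c[0] in own_metabolites]
        missing = [c for c in relevant if c not in cells]
        if missing:
            raise ValueError(f"scheme {scheme!r} missing cells: {missing[:5]}")
        if not relevant:
            result[scheme] = float("nan")
            continue
        matches = sum(
            np.sign(cells[c].beta) == np.sign(reference[c].beta) for c in relevant
        )
        result[scheme] = matches / len(relevant)
    return result


def dilution_recovery(norm: NormalizedTable, truth: SyntheticTruth) -> float:
    """Correlation of a scheme's log scale factors with the true log dilution.

    Returns NaN (with a warning) for schemes whose scale factors are
    constant — the absolute baseline estimates no dilution at all.
    """
    s = norm.scale_factors.to_numpy(dtype=float)
    d = truth.dilution_factors.loc[norm.scale_factors.index].to_numpy(dtype=float)
    log_s = np.log(s)
    if log_s.std() < 1e-12:
        warnings.warn(
            f"scheme {norm.label} has constant scale factors; "
            "dilution recovery undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(log_s, np.log(d))[0, 1])


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Flatten pair summaries into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "scheme_a": s.scheme_a,
                "scheme_b": s.scheme_b,
                "mean_r2": s.mean_r2,
                "n_metabolites": s.n_metabolites,
            }
            for s in summaries
        ]
    )
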