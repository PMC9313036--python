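"""Urinary metabolite normalization schemes.

Spot-urine concentrations are confounded by a per-sample dilution factor
(urine water volume): every metabolite in sample *i* is scaled by the same
unknown d_i. Each scheme here estimates a per-sample scale factor s_i and
divides the row by it:

* **ABS** — no normalization; s_i = 1 (the absolute-concentration baseline).
* **IS** — internal-standard normalization: s_i is the concentration of one
  designated reference metabolite (creatinine -> IS-CREA, glucose -> IS-GLUC,
  urea -> IS-UREA, pseudouridine -> IS-PSEURID).
* **CS** — constant sum: s_i is the summed concentration of all quantified
  metabolites, so every row becomes a composition.
* **PQN** — probabilistic quotient normalization: a reference profile r_j is
  taken as the per-metabolite median across samples (of the constant-sum
  prescaled values by default); s_i is the median over metabolites of the
  quotients x_ij / r_j.
* **DESEQ2** — the median-of-ratios size factor from RNA-seq transplanted to
  concentrations: identical to PQN except the reference profile is the
  per-metabolite geometric mean of the absolute concentrations, with no
  prescaling step.

All transforms return a :class:`NormalizedTable` carrying the normalized
values, the scale factors s_i (always expressed as the total divisor of the
*raw* input, so ``values = raw / s`` holds for every scheme), the reference
profile where one exists, and the scheme identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ConfigurationError, MetaboliteTable, ValidationError, as_positive_frame

METHODS = ("ABS", "IS", "CS", "PQN", "DESEQ2")

#: Conventional abbreviations for the internal-standard variants.
IS_LABELS = {
    "creatinine": "IS-CREA",
    "glucose": "IS-GLUC",
    "urea": "IS-UREA",
    "pseudouridine": "IS-PSEURID",
}


@dataclass
class NormalizationSpec:
    """Identity and options of a normalization scheme.

    ``reference_metabolite`` is required iff ``method == "IS"``.
    ``pqn_pre_cs`` toggles the constant-sum prescaling of the PQN reference
    (on by default, matching the original probabilistic-quotient recipe).
    ``metabolite_subset`` restricts the columns used to build the CS, PQN or
    DESEQ2 reference; the default uses every column.
    """

    method: str
    reference_metabolite: str | None = None
    pqn_pre_cs: bool = True
    metabolite_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown normalization method {self.method!r}; "
                f"expected one of {METHODS}"
            )
        if self.method == "IS" and not self.reference_metabolite:
            raise ConfigurationError("IS normalization requires a reference metabolite")
        if self.metabolite_subset is not None and len(self.metabolite_subset) == 0:
            raise ConfigurationError("metabolite_subset must be non-empty")

    @property
    def label(self) -> str:
        """Display label, e.g. ``IS-CREA`` or ``PQN``."""
        if self.method == "IS":
            ref = self.reference_metabolite
            return IS_LABELS.get(ref, f"IS-{ref.upper()}")
        return self.method


@dataclass
class NormalizedTable:
    """A normalized concentration matrix plus its provenance.

    ``scale_factors[i]`` is the total divisor applied to raw sample *i*, so
    ``values == raw[values.columns] / scale_factors`` for every scheme.
    ``reference_profile`` is empty for ABS and IS. ``excluded`` lists columns
    dropped from the output (the IS reference metabolite).
    """

    values: pd.DataFrame
    scale_factors: pd.Series
    reference_profile: pd.Series
    excluded: tuple[str, ...]
    scheme: NormalizationSpec

    @property
    def label(self) -> str:
        return self.scheme.label

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


def _resolve_subset(frame: pd.DataFrame, subset) -> list[str]:
    if subset is None:
        return list(frame.columns)
    subset = list(subset)
    if not subset:
        raise ValidationError("empty metabolite subset")
    missing = [m for m in subset if m not in frame.columns]
    if missing:
        raise ValidationError(f"subset metabolites not in table: {missing}")
    return subset


def normalize_abs(table) -> NormalizedTable:
    """Absolute-concentration baseline: the identity transform, s_i = 1."""
    frame = as_positive_frame(table)
    return NormalizedTable(
        values=frame.copy(),
        scale_factors=pd.Series(1.0, index=frame.index, name="scale_factor"),
        reference_profile=pd.Series(dtype=float),
        excluded=(),
        scheme=NormalizationSpec("ABS"),
    )


def normalize_is(table, reference: str) -> NormalizedTable:
    """Divide every metabolite by the internal-standard column.

    The reference column is removed from the output (its normalized value is
    identically 1, carrying no information).
    """
    frame = as_positive_frame(table)
    if reference not in frame.columns:
        raise ValidationError(f"reference metabolite {reference!r} not in table")
    s = frame[reference].astype(float)
    values = frame.drop(columns=[reference]).div(s, axis=0)
    return NormalizedTable(
        values=values,
        scale_factors=s.rename("scale_factor"),
        reference_profile=pd.Series(dtype=float),
        excluded=(reference,),
        scheme=NormalizationSpec("IS", reference_metabolite=reference),
    )


def normalize_cs(table, subset=None) -> NormalizedTable:
    """Constant-sum normalization: divide each row by its summed concentration.

    With the default full subset every output row sums to 1 (a composition).
    """
    frame = as_positive_frame(table)
    cols = _resolve_subset(frame, subset)
    s = frame[cols].sum(axis=1)
    return NormalizedTable(
        values=frame.div(s, axis=0),
        scale_factors=s.rename("scale_factor"),
        reference_profile=pd.Series(dtype=float),
        excluded=(),
        scheme=NormalizationSpec("CS", metabolite_subset=None if subset is None else tuple(cols)),
    )


def _quotient_scale_factors(frame: pd.DataFrame, reference: pd.Series, cols) -> pd.Series:
    """Per-sample median of metabolite-wise quotients against a reference profile."""
    ref = reference.reindex(cols)
    if ref.isna().any():
        missing = list(ref.index[ref.isna()])
        raise ValidationError(f"reference profile missing metabolites: {missing}")
    if (ref <= 0).any():
        bad = ref.index[(ref <= 0).to_numpy().argmax()]
        raise ValidationError(f"non-positive reference value for {bad!r}")
    quotients = frame[cols].div(ref, axis=1)
    return quotients.median(axis=1).rename("scale_factor")


def pqn_reference(table, pre_cs: bool = True, subset=None) -> pd.Series:
    """PQN reference profile: per-metabolite median across samples.

    With ``pre_cs`` (the default) the medians are taken over constant-sum
    prescaled values — the "relative concentrations" of the original
    probabilistic-quotient recipe — making the reference itself immune to
    per-sample dilution.
    """
    frame = as_positive_frame(table)
    cols = _resolve_subset(frame, subset)
    if pre_cs:
        frame = frame.div(frame[cols].sum(axis=1), axis=0)
    return frame[cols].median(axis=0).rename("reference")


def deseq2_reference(table, subset=None) -> pd.Series:
    """DESeq2-style reference profile: per-metabolite geometric mean across samples."""
    frame = as_positive_frame(table)
    cols = _resolve_subset(frame, subset)
    return pd.Series(
        np.exp(np.log(frame[cols].to_numpy()).mean(axis=0)),
        index=cols,
        name="reference",
    )


def normalize_pqn(table, pre_cs: bool = True, subset=None,
                  reference: pd.Series | None = None) -> NormalizedTable:
    """Probabilistic quotient normalization.

    Steps: (1) optionally constant-sum prescale each row; (2) reference
    profile r_j = per-metabolite median across samples; (3) quotients
    q_ij = x_ij / r_j; (4) per-sample scale factor s_i = median_j q_ij over
    the subset; (5) divide the (prescaled) row by s_i.

    A precomputed ``reference`` profile may be supplied to apply the scheme
    as a fixed per-sample transform (e.g. to new samples); otherwise the
    reference is fit from ``table`` itself. A single-sample table is its own
    reference: all quotients are 1 and s_i = 1.
    """
    frame = as_positive_frame(table)
    cols = _resolve_subset(frame, subset)
    working = frame
    row_sums = None
    if pre_cs:
        row_sums = frame[cols].sum(axis=1)
        working = frame.div(row_sums, axis=0)
    if reference is None:
        reference = working[cols].median(axis=0).rename("reference")
    s_med = _quotient_scale_factors(working, reference, cols)
    values = working.div(s_med, axis=0)
    total = s_med if row_sums is None else (row_sums * s_med)
    return NormalizedTable(
        values=values,
        scale_factors=total.rename("scale_factor"),
        reference_profile=reference,
        excluded=(),
        scheme=NormalizationSpec(
            "PQN", pqn_pre_cs=pre_cs,
            metabolite_subset=None if subset is None else tuple(cols),
        ),
    )


def normalize_deseq2(table, subset=None,
                     reference: pd.Series | None = None) -> NormalizedTable:
    """Median-of-ratios normalization with a geometric-mean reference.

    Identical to :func:`normalize_pqn` with no prescaling step, except the
    reference profile is the per-metabolite geometric mean of the absolute
    concentrations instead of the median. Strict positivity is required for
    the geometric mean to be defined; there is no zero-handling as in
    RNA-seq counts.
    """
    frame = as_positive_frame(table)
    cols = _resolve_subset(frame, subset)
    if reference is None:
        reference = deseq2_reference(frame, subset=cols)
    s = _quotient_scale_factors(frame, reference, cols)
    return NormalizedTable(
        values=frame.div(s, axis=0),
        scale_factors=s.rename("scale_factor"),
        reference_profile=reference,
        excluded=(),
        scheme=NormalizationSpec(
            "DESEQ2", metabolite_subset=None if subset is None else tuple(cols)
        ),
    )


def apply_scheme(table, spec: NormalizationSpec) -> NormalizedTable:
    """Dispatch a :class:`NormalizationSpec` to the matching transform."""
    method = spec.method
    if method == "ABS":
        return normalize_abs(table)
    if method == "IS":
        return normalize_is(table, spec.reference_metabolite)
    if method == "CS":
        return normalize_cs(table, subset=spec.metabolite_subset)
    if method == "PQN":
        return normalize_pqn(table, pre_cs=spec.pqn_pre_cs, subset=spec.metabolite_subset)
    if method == "DESEQ2":
        return normalize_deseq2(table, subset=spec.metabolite_subset)
    raise ConfigurationError(f"unknown normalization method {method!r}")


def standard_schemes() -> list[NormalizationSpec]:
    """The eight standard data versions: ABS, four IS variants, CS, PQN, DESEQ2."""
    specs = [NormalizationSpec("ABS")]
    specs += [NormalizationSpec("IS", reference_metabolite=m) for m in IS_LABELS]
    specs += [NormalizationSpec("CS"), NormalizationSpec("PQN"), NormalizationSpec("DESEQ2")]
    return specs


def normalize_all(table, specs=None) -> list[NormalizedTable]:
    """Apply a list of schemes (default: the eight standard ones) to one table."""
    if specs is None:
        specs = standard_schemes()
    return [apply_scheme(table, spec) for spec in specs]
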