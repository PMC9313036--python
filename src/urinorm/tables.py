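"""Sample-by-metabolite concentration tables and their validation.

The whole toolkit operates on strictly positive concentration matrices
(samples in rows, named metabolites in columns), as produced by targeted
quantification of spot-urine specimens. Values below the detection limit
are outside the data model: zeros and negatives are rejected at the door
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A concentration table violates the data contract."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent."""


@dataclass
class MetaboliteTable:
    """A strictly positive sample x metabolite concentration matrix.

    Parameters
    ----------
    data:
        DataFrame with one row per sample (index = sample IDs) and one
        column per metabolite, in concentration units (e.g. mmol/L).
    classes:
        Optional metabolite -> metabolic-class labels (amino acids,
        carbohydrate metabolism, microbial metabolism, ...). Purely
        annotational; no computation depends on them.
    """

    data: pd.DataFrame
    classes: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = as_positive_frame(self.data)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def as_positive_frame(data) -> pd.DataFrame:
    """Coerce to a validated, strictly positive float DataFrame.

    Raises :class:`ValidationError` on empty input, duplicate sample or
    metabolite names, non-numeric cells, or non-positive values, naming
    the offending location where one exists.
    """
    if isinstance(data, MetaboliteTable):
        return data.data
    frame = pd.DataFrame(data)
    if frame.size == 0:
        raise ValidationError("empty concentration table")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValidationError(f"duplicate metabolite name: {dup!r}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate sample ID: {dup!r}")
    try:
        values = frame.astype(float)
    except (TypeError, ValueError):
        row, col = _first_bad_cell(frame)
        raise ValidationError(
            f"non-numeric value at sample {row!r}, metabolite {col!r}"
        ) from None
    arr = values.to_numpy()
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"missing value at sample {values.index[i]!r}, "
            f"metabolite {values.columns[j]!r}"
        )
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"non-positive concentration at sample {values.index[i]!r}, "
            f"metabolite {values.columns[j]!r}: {arr[i, j]}"
        )
    return values


def _first_bad_cell(frame: pd.DataFrame) -> tuple:
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            return frame.index[bad.to_numpy().argmax()], col
    return frame.index[0], frame.columns[0]
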