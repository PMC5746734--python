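"""Molecular-descriptor table filtering and chemometric preprocessing.

Descriptor values (compounds x descriptors) arrive precomputed; this
module reduces them the way QSRR practice does before modelling:
descriptors missing for any compound are removed first, then descriptors
whose coefficient of variation |sd / mean| falls below a threshold
(default 20%) are removed.  The CV uses the sample (n-1) standard
deviation and the absolute value of the mean, so negative-valued
descriptors are judged by magnitude; a zero mean gives CV = +inf when the
column varies and CV = 0 when it is constant.

Preprocessing helpers: ``autoscale`` (mean 0, sample sd 1 per column,
used before PCA and PLS) and ``center`` (mean 0, used before ASCA), both
returning the transform parameters for inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable", "FilterReport",
    "completeness_filter", "variation_filter",
    "autoscale", "center",
]


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix (NaN marks a missing value)."""

    values: pd.DataFrame
    block_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("compound and descriptor names must be unique")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, descriptors: list[str]) -> "DescriptorTable":
        labels = {d: self.block_labels[d] for d in descriptors if d in self.block_labels}
        return DescriptorTable(self.values[descriptors].copy(), labels)


@dataclass
class FilterReport:
    removed_low_variation: list[str] = field(default_factory=list)
    removed_incomplete: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    cv: dict[str, float] = field(default_factory=dict)

    @property
    def removed(self) -> list[str]:
        return self.removed_incomplete + self.removed_low_variation


def completeness_filter(table: DescriptorTable) -> tuple[DescriptorTable, FilterReport]:
    """Remove every descriptor column with at least one missing value."""
    missing = table.values.isna().any(axis=0)
    removed = list(table.values.columns[missing])
    retained = list(table.values.columns[~missing])
    return table.subset(retained), FilterReport(removed_incomplete=removed, retained=retained)


def _cv(col: np.ndarray) -> float:
    sd = float(np.std(col, ddof=1))
    mean = float(np.mean(col))
    if mean == 0.0:
        return np.inf if sd > 0 else 0.0
    return abs(sd / mean)


def variation_filter(table: DescriptorTable,
                     threshold: float = 0.20) -> tuple[DescriptorTable, FilterReport]:
    """Remove descriptors whose |sd/mean| is strictly below ``threshold``.

    Constant (sd = 0) columns are removed at any threshold.  Columns must
    be complete (run :func:`completeness_filter` first); a column with
    missing values raises.
    """
    if table.values.isna().any().any():
        raise ValueError("variation_filter requires a complete table; "
                         "run completeness_filter first")
    cvs = {d: _cv(table.values[d].to_numpy(dtype=float)) for d in table.descriptor_names}
    sds = {d: float(np.std(table.values[d].to_numpy(dtype=float), ddof=1))
           for d in table.descriptor_names}
    # a constant column carries no information and is always removed,
    # whatever the threshold; otherwise strict |sd/mean| < threshold
    removed = [d for d, v in cvs.items() if sds[d] == 0 or v < threshold]
    retained = [d for d in table.descriptor_names if d not in removed]
    return table.subset(retained), FilterReport(removed_low_variation=removed,
                                                retained=retained, cv=cvs)


def _as_array(X) -> tuple[np.ndarray, object]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X
    return np.asarray(X, dtype=float), None


def _wrap(arr: np.ndarray, like) -> np.ndarray | pd.DataFrame:
    if like is not None:
        return pd.DataFrame(arr, index=like.index, columns=like.columns)
    return arr


def autoscale(X) -> tuple[np.ndarray | pd.DataFrame, np.ndarray, np.ndarray]:
    """Column-wise standardization to mean 0 and sample sd 1.

    Returns (scaled matrix, column means, column sds); a constant column
    is an error naming the offender, since it cannot be scaled.
    """
    arr, like = _as_array(X)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = (list(np.asarray(like.columns)[bad]) if like is not None else list(bad))
        raise ValueError(f"cannot autoscale constant column(s): {names}")
    return _wrap((arr - means) / sds, like), means, sds


def center(X) -> tuple[np.ndarray | pd.DataFrame, np.ndarray]:
    """Column-wise mean centering; returns (centered matrix, column means)."""
    arr, like = _as_array(X)
    means = arr.mean(axis=0)
    return _wrap(arr - means, like), means
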