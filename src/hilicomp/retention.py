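"""Retention factors and assembly of the runs x metabolites matrix D.

The retention factor of an analyte is k = (t_R - t_0) / t_0, with t_R its
retention time and t_0 the column dead time.  t_0 can be derived
theoretically from the column dead volume: V_0 = pi (d/2)^2 L eps (column
geometry times total porosity), t_0 = V_0 / F at flow rate F.

Targets are located in per-run ROI matrices by their expected m/z (in their
preferred ionization polarity); t_R is the retention time of the global
apex of the matched ROI trace.  Missing targets yield masked records,
never silent drops, and matrix D carries an explicit missing-value mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import ROIMatrix, ROINotFoundError, roi_trace

__all__ = [
    "MetaboliteTarget",
    "RetentionRecord",
    "RetentionMatrix",
    "retention_factor",
    "dead_time",
    "match_and_measure",
    "assemble_D",
]

FAMILIES = ("nucleoside", "amino_acid", "sugar", "organic_acid", "other")


@dataclass(frozen=True)
class MetaboliteTarget:
    """A target compound: name, family, expected m/z and preferred polarity."""

    name: str
    family: str
    expected_mz: float
    preferred_polarity: str = "either"  # positive | negative | either

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.expected_mz <= 0:
            raise ValueError("expected_mz must be positive")
        if self.preferred_polarity not in ("positive", "negative", "either"):
            raise ValueError(f"unknown polarity {self.preferred_polarity!r}")


@dataclass
class RetentionRecord:
    run_id: str
    metabolite: str
    t_R: float  # min; NaN when masked
    t_0: float  # min
    k: float  # (t_R - t_0)/t_0; NaN when masked
    masked: bool = False
    reason: str = ""


def retention_factor(t_R: float, t_0: float) -> float:
    """k = (t_R - t_0) / t_0.

    ``t_0 <= 0`` is an error; ``t_R < t_0`` (an apparently unretained or
    early-eluting compound) is legal but warned about, and the negative k
    is returned as computed.
    """
    if t_0 <= 0:
        raise ValueError("invalid dead time: t_0 must be positive")
    if t_R < 0:
        raise ValueError("t_R must be nonnegative")
    if t_R < t_0:
        warnings.warn(f"t_R={t_R} < t_0={t_0}: early eluter, negative retention factor")
    return (t_R - t_0) / t_0


def dead_time(column_length_mm: float, internal_diameter_mm: float,
              porosity: float, flow_mL_min: float) -> float:
    """Theoretical dead time from column geometry, total porosity and flow.

    V_0 [mL] = pi (d/2)^2 L eps / 1000 with d, L in mm; t_0 = V_0 / F.
    Typical total porosity for packed LC columns is ~0.7, which downstream
    code uses as its configurable default.
    """
    if column_length_mm <= 0 or internal_diameter_mm <= 0 or flow_mL_min <= 0:
        raise ValueError("column length, diameter and flow must be positive")
    if not 0 < porosity < 1:
        raise ValueError("porosity must lie in (0, 1)")
    v0_mL = math.pi * (internal_diameter_mm / 2.0) ** 2 * column_length_mm * porosity / 1000.0
    return v0_mL / flow_mL_min


def _best_hit(roi: ROIMatrix | None, mz: float, tol: float):
    """(apex intensity, apex rt) of the matched trace, or None."""
    if roi is None:
        return None
    try:
        _, trace = roi_trace(roi, mz, tol)
    except ROINotFoundError:
        return None
    i = int(np.argmax(trace))
    return float(trace[i]), float(roi.rt_axis[i])


def match_and_measure(roi_pos: ROIMatrix | None, roi_neg: ROIMatrix | None,
                      targets: list[MetaboliteTarget], tolerance: float,
                      t_0: float, run_id: str = "") -> list[RetentionRecord]:
    """Locate each target in the per-polarity ROI matrices and measure k.

    Targets with ``preferred_polarity='either'`` are searched in both modes
    and the hit with the higher apex intensity wins.  t_R is the retention
    time of the global maximum of the matched trace.  Targets found in
    neither mode produce masked records with a reason, never silent drops.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    run_id = run_id or (roi_pos.run_id if roi_pos is not None else
                        roi_neg.run_id if roi_neg is not None else "")
    records = []
    for tgt in targets:
        hits = []
        if tgt.preferred_polarity in ("positive", "either"):
            h = _best_hit(roi_pos, tgt.expected_mz, tolerance)
            if h:
                hits.append(h)
        if tgt.preferred_polarity in ("negative", "either"):
            h = _best_hit(roi_neg, tgt.expected_mz, tolerance)
            if h:
                hits.append(h)
        if hits:
            _, t_R = max(hits)  # higher apex wins
            records.append(RetentionRecord(run_id, tgt.name, t_R, t_0,
                                           retention_factor(t_R, t_0)))
        else:
            records.append(RetentionRecord(run_id, tgt.name, float("nan"), t_0,
                                           float("nan"), masked=True,
                                           reason="not found"))
    return records


@dataclass
class RetentionMatrix:
    """Matrix D: runs (with factorial metadata) x metabolite retention factors."""

    design: pd.DataFrame  # indexed by run_id; factor + replicate columns
    values: pd.DataFrame  # run_id x metabolite, float (NaN where masked)
    mask: pd.DataFrame  # same shape, True where missing
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.design.index):
            raise ValueError("values rows must match design run order")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("run and metabolite labels must be unique")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())

    def require_complete(self) -> "RetentionMatrix":
        """Strict mode: any masked cell is an error."""
        if not self.is_complete:
            n = int(self.mask.to_numpy().sum())
            raise ValueError(f"matrix D has {n} masked cells; resolve or drop them")
        return self

    def drop_masked_columns(self) -> "RetentionMatrix":
        """Drop-mode completeness: remove metabolite columns with any mask."""
        bad = self.mask.any(axis=0)
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} masked metabolite columns: "
                          f"{list(self.mask.columns[bad])}")
        keep = self.values.columns[~bad]
        return RetentionMatrix(self.design, self.values[keep].copy(),
                               self.mask[keep].copy(), self.n_clipped)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def assemble_D(records: list[RetentionRecord], design: pd.DataFrame,
               targets: list[MetaboliteTarget | str]) -> RetentionMatrix:
    """Arrange retention records into matrix D in design x target order.

    Row order follows ``design`` (indexed by run_id), column order follows
    ``targets``.  Duplicate (run, metabolite) records are an error; missing
    cells are masked and the masked fraction is reported via a warning.
    """
    names = [t if isinstance(t, str) else t.name for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target names")
    seen = set()
    for r in records:
        if r.run_id not in design.index:
            raise ValueError(f"record run_id {r.run_id!r} not in design")
        key = (r.run_id, r.metabolite)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)

    values = pd.DataFrame(np.nan, index=design.index, columns=names)
    for r in records:
        if r.metabolite in values.columns and not r.masked:
            values.loc[r.run_id, r.metabolite] = r.k
    mask = values.isna()
    frac = float(mask.to_numpy().mean())
    if frac > 0:
        warnings.warn(f"matrix D has {frac:.1%} masked cells")
    return RetentionMatrix(design, values, mask)
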