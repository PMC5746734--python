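"""PLS1 regression of retention factors on molecular descriptors, with
leave-one-out latent-variable selection, VIP scoring and cross-condition
overlap analysis.

The regression is the NIPALS deflation algorithm for a single response:
per latent variable, w = X'y / ||X'y||, t = X w, p = X't / t't,
q = y't / t't, then X is deflated by t p'.  X and y are autoscaled
internally (sample sd) and predictions invert the scaling.  The
regression vector is b = W (P'W)^{-1} q.

Variable importance in projection for descriptor j over A latent
variables:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

with SSY_a = q_a^2 t_a't_a the y-variance explained by LV a and p the
descriptor count; the mean squared VIP is 1 by construction and VIP > 1
conventionally marks an important variable.

One model is fitted per chromatographic condition (stationary phase x
pH), on replicate-averaged retention factors at low ionic strength —
12 models in the study layout — and the VIP>1 descriptor sets are
compared across conditions by exhaustive disjoint-region (Venn) counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .retention import RetentionMatrix

__all__ = [
    "PLSModel", "CVReport", "VIPSelection", "OverlapSummary", "ConditionResult",
    "pls_fit", "loo_select_lv", "vip_scores", "select_vip",
    "overlap_analysis", "run_condition_models",
]


@dataclass
class PLSModel:
    n_lv: int
    W: np.ndarray  # p x A, unit-norm X-weights
    P: np.ndarray  # p x A, X-loadings
    T: np.ndarray  # n x A, X-scores (mutually orthogonal)
    q: np.ndarray  # A, y-loadings
    b: np.ndarray  # p, regression vector in autoscaled space
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    ssy: np.ndarray  # A, y-variance explained per LV (scaled units)
    r2y_cum: np.ndarray  # A, cumulative fraction of y-variance explained
    descriptor_names: list[str] = field(default_factory=list)
    condition: tuple | None = None

    def predict(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.b)


def _nipals(Xs: np.ndarray, ys: np.ndarray, n_lv: int):
    """Deflation loop on autoscaled data; returns W, P, T, q."""
    n, p = Xs.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    q = np.empty(n_lv)
    Xd = Xs.copy()
    for a in range(n_lv):
        w = Xd.T @ ys
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"no residual covariance left at LV {a + 1}; "
                             "reduce n_lv")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate score vector at LV {a + 1}")
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xd.T @ t / tt
        q[a] = float(ys @ t) / tt
        Xd = Xd - np.outer(t, P[:, a])
    return W, P, T, q


def pls_fit(X, y, n_lv: int, descriptor_names: list[str] | None = None) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (autoscaling internal)."""
    if isinstance(X, pd.DataFrame):
        descriptor_names = descriptor_names or list(X.columns)
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.size != n:
        raise ValueError("X and y length mismatch")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError("n_lv must satisfy 1 <= n_lv <= min(rows-1, cols)")
    y_sd = float(np.std(ya, ddof=1))
    if y_sd == 0:
        raise ValueError("zero-variance response")
    x_mean = Xa.mean(axis=0)
    x_sd = Xa.std(axis=0, ddof=1)
    if np.any(x_sd == 0):
        bad = [descriptor_names[j] if descriptor_names else j
               for j in np.flatnonzero(x_sd == 0)]
        raise ValueError(f"cannot autoscale constant descriptor(s): {bad}")
    y_mean = float(ya.mean())
    Xs = (Xa - x_mean) / x_sd
    ys = (ya - y_mean) / y_sd

    W, P, T, q = _nipals(Xs, ys, n_lv)
    b = W @ np.linalg.solve(P.T @ W, q)
    tt = (T ** 2).sum(axis=0)
    ssy = q ** 2 * tt
    r2y_cum = np.cumsum(ssy) / float(ys @ ys)
    return PLSModel(n_lv, W, P, T, q, b, x_mean, x_sd, y_mean, y_sd,
                    ssy, r2y_cum, descriptor_names or [])


@dataclass
class CVReport:
    rmsecv: np.ndarray  # per LV count, 1..max_lv
    chosen_n_lv: int
    loo_predictions: np.ndarray  # n x max_lv


def loo_select_lv(X, y, max_lv: int) -> CVReport:
    """Choose the latent-variable count by leave-one-out cross-validation.

    Every fold refits (and rescales) on the remaining rows; the chosen
    count minimizes RMSECV, ties broken toward fewer latent variables.
    ``max_lv`` beyond what the folds can support is capped with a warning.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    cap = min(max_lv, n - 2, p)  # folds have n-1 rows, so n_lv <= n-2
    if cap < max_lv:
        warnings.warn(f"max_lv={max_lv} capped at {cap} for {n} samples, {p} descriptors")

    preds = np.empty((n, cap))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, yt = Xa[keep], ya[keep]
        y_sd = float(np.std(yt, ddof=1))
        if y_sd == 0:
            raise ValueError("zero-variance response in a LOO fold")
        x_mean, x_sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
        if np.any(x_sd == 0):
            raise ValueError("constant descriptor in a LOO fold")
        y_mean = float(yt.mean())
        W, P, T, q = _nipals((Xt - x_mean) / x_sd, (yt - y_mean) / y_sd, cap)
        xs = (Xa[i] - x_mean) / x_sd
        for a in range(1, cap + 1):
            b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            preds[i, a - 1] = y_mean + y_sd * float(xs @ b)

    rmsecv = np.sqrt(((preds - ya[:, None]) ** 2).mean(axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # argmin returns the first (smallest) on ties
    return CVReport(rmsecv, chosen, preds)


def vip_scores(model: PLSModel) -> np.ndarray | dict[str, float]:
    """Variable importance in projection for every descriptor.

    Returns a name -> VIP mapping when the model carries descriptor
    names, else a plain array.  Mean squared VIP is 1 by construction.
    """
    p = model.W.shape[0]
    wn = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn ** 2 @ model.ssy) / model.ssy.sum())
    if model.descriptor_names:
        return dict(zip(model.descriptor_names, vip))
    return vip


@dataclass
class VIPSelection:
    condition: tuple | str | None
    vip: dict[str, float]
    selected: set[str]
    top: pd.DataFrame  # (descriptor, VIP) sorted descending

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_vip(vip: Mapping[str, float], threshold: float = 1.0,
               top_k: int = 20, condition=None) -> VIPSelection:
    """Strict VIP > threshold selection plus a top-k table.

    The table is sorted by descending VIP, ties broken alphabetically.
    """
    vip = dict(vip)
    selected = {d for d, v in vip.items() if v > threshold}
    ordered = sorted(vip.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    top = pd.DataFrame(ordered, columns=["descriptor", "VIP"])
    return VIPSelection(condition, vip, selected, top)


@dataclass
class OverlapSummary:
    set_labels: list
    set_sizes: dict
    unique_counts: dict
    regions: dict[frozenset, int]  # exclusive membership pattern -> count
    union_size: int

    def intersection_size(self, labels) -> int:
        """Size of the plain (non-exclusive) intersection of the given sets."""
        want = set(labels)
        return sum(n for pat, n in self.regions.items() if want <= pat)


def overlap_analysis(selections: Mapping) -> OverlapSummary:
    """Exhaustive disjoint-region (Venn) counts across selected sets."""
    labels = list(selections)
    if len(labels) < 2:
        raise ValueError("overlap analysis needs at least 2 sets")
    if len(labels) > 6:
        raise ValueError("more than 6 sets: region count explodes")
    sets = {k: set(v) for k, v in selections.items()}
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for inside in itertools.combinations(labels, r):
            members = set.intersection(*(sets[k] for k in inside))
            for k in labels:
                if k not in inside:
                    members -= sets[k]
            if members:
                regions[frozenset(inside)] = len(members)
    union = set().union(*sets.values())
    uniques = {k: regions.get(frozenset([k]), 0) for k in labels}
    return OverlapSummary(labels, {k: len(s) for k, s in sets.items()},
                          uniques, regions, len(union))


@dataclass
class ConditionResult:
    condition: tuple
    model: PLSModel
    cv: CVReport
    selection: VIPSelection


def run_condition_models(D: RetentionMatrix, table: DescriptorTable,
                         conditions: list[tuple[str, str]] | None = None,
                         low_is_only: bool = True, low_is_level: str = "low",
                         max_lv: int = 10, vip_threshold: float = 1.0
                         ) -> dict[tuple[str, str], ConditionResult]:
    """Fit one PLS/VIP model per (phase, pH) condition.

    Runs are restricted to low ionic strength (where the retention
    chemistry is to be modelled), replicate injections are averaged into
    one retention factor per metabolite, and the descriptor matrix rows
    are aligned to the metabolite columns of D.  The study layout gives
    4 phases x 3 pH values = 12 models.
    """
    D = D.require_complete()
    design = D.design
    sub = design[design["ionic_strength"] == low_is_level] if low_is_only else design
    if conditions is None:
        conditions = list(dict.fromkeys(zip(sub["phase"], sub["pH"])))
    Xfull = table.values.reindex(D.metabolites)
    if Xfull.isna().any().any():
        raise ValueError("descriptor table incomplete or missing compounds; "
                         "align and filter it first")
    results: dict[tuple[str, str], ConditionResult] = {}
    for phase, ph in conditions:
        rows = sub[(sub["phase"] == phase) & (sub["pH"] == ph)].index
        if len(rows) == 0:
            raise ValueError(f"condition {(phase, ph)} missing from D")
        y = D.values.loc[rows].mean(axis=0).reindex(D.metabolites).to_numpy()
        cv = loo_select_lv(Xfull, y, max_lv)
        model = pls_fit(Xfull, y, cv.chosen_n_lv)
        model.condition = (phase, ph)
        sel = select_vip(vip_scores(model), vip_threshold, condition=(phase, ph))
        results[(phase, ph)] = ConditionResult((phase, ph), model, cv, sel)
    return results
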