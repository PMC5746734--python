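"""PCA exploration and ANOVA-simultaneous component analysis (ASCA).

ASCA partitions a column-centered data matrix measured under a balanced
factorial design into additive effect matrices — one per design factor
and per pairwise interaction — plus a residual:

    X_c = X_phase + X_pH + X_IS + X_phase:pH + ... + E

A main-effect matrix repeats, for every run, the mean of the centered
rows at that run's factor level; an interaction matrix holds the cell
mean minus the two parent main effects.  On a balanced design these
subspaces are orthogonal, so the sums of squares are additive.  Factor
significance is assessed by permuting whole rows of the centered matrix
(jointly across metabolites, preserving their correlation) and
recomputing the tested term's sum of squares; the p-value is
(1 + #{null >= observed}) / (1 + n_perm), so the smallest attainable p
with 10,000 permutations is 0.0001.  Each term's structure is explored
by a component analysis of its level means ("scores at the mean level").

PCA here operates on autoscaled data, ASCA on centered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .descriptors import autoscale as _autoscale, center as _center
from .retention import RetentionMatrix

__all__ = [
    "PCAResult", "EffectDecomposition", "PermutationTestResult", "EffectScores",
    "pca", "asca_decompose", "asca_permutation_test", "asca_effect_scores",
    "parse_term",
]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: each loading column's largest-magnitude
    entry is positive; scores flip accordingly."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return loadings, scores


@dataclass
class PCAResult:
    scores: np.ndarray  # rows x components
    loadings: np.ndarray  # variables x components
    explained_variance_fraction: np.ndarray
    preprocessing: str = "autoscale"
    row_labels: list[str] = field(default_factory=list)
    variable_labels: list[str] = field(default_factory=list)


def pca(X, n_components: int, preprocessing: str = "autoscale") -> PCAResult:
    """Principal component analysis with a fixed sign convention.

    ``preprocessing`` is "autoscale" (default, as used for exploring
    matrix D), "center", or "none" (data already preprocessed).
    """
    if isinstance(X, RetentionMatrix):
        X = X.require_complete().values
    row_labels = list(X.index) if isinstance(X, pd.DataFrame) else []
    var_labels = list(X.columns) if isinstance(X, pd.DataFrame) else []
    arr = np.asarray(X, dtype=float)
    if n_components > min(arr.shape[0] - 1, arr.shape[1]):
        raise ValueError("n_components exceeds min(rows-1, cols)")
    if preprocessing == "autoscale":
        arr, _, _ = _autoscale(arr)
    elif preprocessing == "center":
        arr, _ = _center(arr)
    elif preprocessing != "none":
        raise ValueError(f"unknown preprocessing {preprocessing!r}")

    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(arr)
    loadings = model.components_.T.copy()
    loadings, scores = _fix_signs(loadings, scores)
    return PCAResult(scores, loadings, model.explained_variance_ratio_.copy(),
                     preprocessing, row_labels, var_labels)


def parse_term(term: str) -> tuple[str, ...]:
    """'phase' -> ('phase',); 'phase:pH' -> ('phase', 'pH')."""
    parts = tuple(p.strip() for p in term.split(":"))
    if not 1 <= len(parts) <= 2:
        raise ValueError(f"only main effects and pairwise interactions supported: {term!r}")
    return parts


def _check_balanced(design: pd.DataFrame, factors: list[str]) -> None:
    counts = design.groupby(factors, observed=True).size()
    full = int(np.prod([design[f].nunique() for f in factors]))
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError("ASCA requires balance: every factor-level cell needs "
                         "the same replicate count")


def _level_means(Xc: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Row means of Xc per level code; (n_levels x columns)."""
    out = np.empty((n_levels, Xc.shape[1]))
    for lv in range(n_levels):
        out[lv] = Xc[codes == lv].mean(axis=0)
    return out


@dataclass
class EffectDecomposition:
    grand_mean: np.ndarray  # column means of the raw matrix
    effects: dict[str, np.ndarray]  # term -> runs x metabolites
    residual: np.ndarray
    ssq: dict[str, float]  # per term + "residual" + "total"
    design: pd.DataFrame
    centered: np.ndarray
    level_means: dict[str, pd.DataFrame]  # term -> level(s) x metabolites
    variable_labels: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.effects)


def _default_terms(factors: list[str]) -> list[str]:
    terms = list(factors)
    for i, f in enumerate(factors):
        for g in factors[i + 1:]:
            terms.append(f"{f}:{g}")
    return terms


def asca_decompose(D, design: pd.DataFrame | None = None,
                   terms: list[str] | None = None) -> EffectDecomposition:
    """Decompose centered data into factor effect matrices plus residual.

    ``D`` is a :class:`RetentionMatrix` (strict completeness enforced) or
    an array with ``design`` given separately.  ``terms`` defaults to all
    main effects and all pairwise interactions of the design factors
    (replicate column excluded); the three-way term is pooled into the
    residual.
    """
    if isinstance(D, RetentionMatrix):
        design = D.design
        var_labels = D.metabolites
        X = D.require_complete().to_array()
    else:
        if design is None:
            raise ValueError("design required when D is a plain matrix")
        var_labels = list(D.columns) if isinstance(D, pd.DataFrame) else []
        X = np.asarray(D, dtype=float)
    if len(design) != X.shape[0]:
        raise ValueError("design rows must match data rows")
    factors = [c for c in design.columns if c != "replicate"]
    _check_balanced(design, factors)
    if terms is None:
        terms = _default_terms(factors)

    grand = X.mean(axis=0)
    Xc = X - grand

    codes: dict[str, tuple[np.ndarray, list]] = {}
    for f in factors:
        cats = pd.Categorical(design[f], categories=pd.unique(design[f]))
        codes[f] = (cats.codes.astype(int), list(cats.categories))

    effects: dict[str, np.ndarray] = {}
    level_means: dict[str, pd.DataFrame] = {}
    main_mean: dict[str, np.ndarray] = {}
    for term in terms:
        parts = parse_term(term)
        for p in parts:
            if p not in codes:
                raise ValueError(f"unknown factor {p!r} in term {term!r}")
        if len(parts) == 1:
            f = parts[0]
            c, cats = codes[f]
            m = _level_means(Xc, c, len(cats))
            main_mean[f] = m
            effects[term] = m[c]
            level_means[term] = pd.DataFrame(m, index=pd.Index(cats, name=f),
                                             columns=var_labels or None)
        else:
            f, g = parts
            for p in (f, g):  # interaction needs its parents' means
                if p not in main_mean:
                    c, cats = codes[p]
                    main_mean[p] = _level_means(Xc, c, len(cats))
            cf, catf = codes[f]
            cg, catg = codes[g]
            cell_code = cf * len(catg) + cg
            cell = _level_means(Xc, cell_code, len(catf) * len(catg))
            inter_cells = (cell.reshape(len(catf), len(catg), -1)
                           - main_mean[f][:, None, :] - main_mean[g][None, :, :])
            effects[term] = inter_cells.reshape(len(catf) * len(catg), -1)[cell_code]
            idx = pd.MultiIndex.from_product([catf, catg], names=[f, g])
            level_means[term] = pd.DataFrame(inter_cells.reshape(len(idx), -1),
                                             index=idx, columns=var_labels or None)

    residual = Xc - sum(effects.values())
    ssq = {t: float((m ** 2).sum()) for t, m in effects.items()}
    ssq["residual"] = float((residual ** 2).sum())
    ssq["total"] = float((Xc ** 2).sum())
    return EffectDecomposition(grand, effects, residual, ssq, design, Xc,
                               level_means, var_labels)


@dataclass
class PermutationTestResult:
    term: str
    observed_ssq: float
    null_ssq: np.ndarray
    n_perm: int
    seed: int

    @property
    def p_value(self) -> float:
        b = int(np.sum(self.null_ssq >= self.observed_ssq))
        return (1 + b) / (1 + self.n_perm)


def _term_ssq(Xp: np.ndarray, parts: tuple[str, ...],
              codes: dict[str, tuple[np.ndarray, list]]) -> float:
    """SSQ of one term for (possibly row-permuted) centered data."""
    if len(parts) == 1:
        c, cats = codes[parts[0]]
        m = _level_means(Xp, c, len(cats))
        counts = np.bincount(c, minlength=len(cats))
        return float((counts[:, None] * m ** 2).sum())
    f, g = parts
    cf, catf = codes[f]
    cg, catg = codes[g]
    mf = _level_means(Xp, cf, len(catf))
    mg = _level_means(Xp, cg, len(catg))
    cell_code = cf * len(catg) + cg
    cell = _level_means(Xp, cell_code, len(catf) * len(catg))
    inter = (cell.reshape(len(catf), len(catg), -1)
             - mf[:, None, :] - mg[None, :, :]).reshape(len(catf) * len(catg), -1)
    counts = np.bincount(cell_code, minlength=inter.shape[0])
    return float((counts[:, None] * inter ** 2).sum())


def asca_permutation_test(D, design: pd.DataFrame | None = None, term: str = "phase",
                          n_perm: int = 10_000, seed: int | None = None,
                          scheme: str = "rows") -> PermutationTestResult:
    """Permutation significance test for one ASCA term.

    Whole rows of the centered matrix are permuted against the design
    (synchronized across metabolites, preserving between-metabolite
    correlation) and only the tested term's SSQ is recomputed; for an
    interaction the two parent main effects are re-estimated under each
    permutation.  p = (1 + b) / (1 + n_perm).

    ``scheme="rows"`` (default) permutes all rows freely.  When factors
    outside the tested term carry large effects this is conservative:
    scrambling rows leaks those effects into the permuted term's SSQ.
    ``scheme="within"`` restricts permutations to the strata formed by
    the level combinations of the other design factors, which keeps the
    nuisance effects fixed and restores exact type-I calibration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if scheme not in ("rows", "within"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    decomp = asca_decompose(D, design)
    if term not in decomp.ssq:
        raise ValueError(f"unknown term {term!r}; available: {decomp.terms}")
    parts = parse_term(term)
    design = decomp.design
    factors = [c for c in design.columns if c != "replicate"]
    codes = {f: ((cats := pd.Categorical(design[f])).codes.astype(int),
                 list(cats.categories)) for f in factors}
    Xc = decomp.centered
    observed = decomp.ssq[term]

    strata: list[np.ndarray] | None = None
    if scheme == "within":
        others = [f for f in factors if f not in parts]
        if others:
            groups = design.groupby(others, observed=True).indices.values()
            strata = [np.asarray(ix) for ix in groups]

    rng = np.random.default_rng(seed)
    n = Xc.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for ix in strata:
                perm[ix] = ix[rng.permutation(ix.size)]
        null[i] = _term_ssq(Xc[perm], parts, codes)
    return PermutationTestResult(term, observed, null, n_perm, seed)


@dataclass
class EffectScores:
    term: str
    level_labels: list
    scores: np.ndarray  # levels x components
    loadings: np.ndarray  # variables x components
    explained_variance_fraction: np.ndarray
    variable_labels: list[str] = field(default_factory=list)


def asca_effect_scores(decomp: EffectDecomposition, term: str,
                       n_components: int = 2) -> EffectScores:
    """Component analysis of a term's level means ("scores at the mean level").

    The unique level-mean rows of the effect matrix (one row per factor
    level, or per level pair for an interaction) are factored by SVD;
    scores place the levels, loadings rank the metabolites that drive the
    separation.
    """
    if term not in decomp.level_means:
        raise ValueError(f"term {term!r} not in decomposition")
    M = decomp.level_means[term]
    if len(M) < 2:
        raise ValueError("effect scores need a term with at least 2 levels")
    n_components = min(n_components, len(M) - 1, M.shape[1])
    U, s, Vt = np.linalg.svd(M.to_numpy(dtype=float), full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T.copy()
    loadings, scores = _fix_signs(loadings, scores)
    total = float((s ** 2).sum())
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return EffectScores(term, list(M.index), scores, loadings, frac,
                        decomp.variable_labels)
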