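"""PCA and ASCA: effect decomposition against a textbook two-way ANOVA
oracle, permutation testing, effect scores."""

import numpy as np
import pandas as pd
import pytest

from hilicomp import (asca_decompose, asca_effect_scores,
                      asca_permutation_test, build_design, pca,
                      simulate_retention_matrix)
from conftest import effect_spec


class TestPCA:
    def test_rank_one_matrix_explains_everything_on_pc1(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6))
        res = pca(X, 2, preprocessing="center")
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_rotation_invariance_of_explained_fractions(self, rng):
        X = rng.normal(size=(12, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        a = pca(X, 3, preprocessing="center").explained_variance_fraction
        b = pca(X @ Q, 3, preprocessing="center").explained_variance_fraction
        assert np.allclose(a, b, atol=1e-10)

    def test_matches_direct_svd_oracle(self, rng):
        X = rng.normal(size=(10, 6))
        res = pca(X, 4, preprocessing="autoscale")
        # oracle: SVD of the autoscaled matrix
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        Xhat_oracle = (U[:, :4] * s[:4]) @ Vt[:4]
        assert np.allclose(res.scores @ res.loadings.T, Xhat_oracle, atol=1e-8)
        assert np.allclose(res.explained_variance_fraction,
                           s[:4] ** 2 / (s ** 2).sum(), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = rng.normal(size=(15, 4))
        res = pca(X, 3)
        for a in range(3):
            j = int(np.argmax(np.abs(res.loadings[:, a])))
            assert res.loadings[j, a] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(5, 3)), 5)


def two_way_anova_oracle(X, f_codes, g_codes):
    """Brute-force textbook two-way ANOVA decomposition of centered X."""
    Xc = X - X.mean(axis=0)
    alpha = {a: Xc[f_codes == a].mean(axis=0) for a in np.unique(f_codes)}
    beta = {b: Xc[g_codes == b].mean(axis=0) for b in np.unique(g_codes)}
    A = np.array([alpha[a] for a in f_codes])
    B = np.array([beta[b] for b in g_codes])
    cell = {(a, b): Xc[(f_codes == a) & (g_codes == b)].mean(axis=0)
            for a in np.unique(f_codes) for b in np.unique(g_codes)}
    AB = np.array([cell[(a, b)] for a, b in zip(f_codes, g_codes)]) - A - B
    return A, B, AB, Xc - A - B - AB


class TestDecompose:
    def test_noise_free_phase_effect_reproduced_exactly(self, design48, met_names):
        offs = {"BEH_amide": 1.0, "amide": -1.0, "zwitterionic": 0.0, "diol": 0.0}
        D = simulate_retention_matrix(design48, effect_spec(phase=offs), met_names, seed=0)
        dec = asca_decompose(D)
        for level, off in offs.items():
            rows = (design48["phase"] == level).to_numpy()
            assert np.allclose(dec.effects["phase"][rows], off, atol=1e-12)
        for term in dec.terms:
            if term != "phase":
                assert np.allclose(dec.effects[term], 0.0, atol=1e-12)
        assert np.allclose(dec.residual, 0.0, atol=1e-12)

    def test_random_data_effects_small_relative_to_residual(self, design48, met_names):
        D = simulate_retention_matrix(design48, effect_spec(residual_sd=1.0),
                                      met_names, seed=1)
        dec = asca_decompose(D)
        for term in dec.terms:
            assert dec.ssq[term] < 0.5 * dec.ssq["residual"]

    def test_matches_two_way_anova_oracle_on_8_row_toy(self, rng):
        design = build_design({"f": ["a", "b"], "g": ["x", "y"]}, 2)
        X = rng.normal(size=(8, 3))
        dec = asca_decompose(pd.DataFrame(X, index=design.index), design)
        A, B, AB, E = two_way_anova_oracle(
            X, design["f"].to_numpy(), design["g"].to_numpy())
        assert np.allclose(dec.effects["f"], A, atol=1e-8)
        assert np.allclose(dec.effects["g"], B, atol=1e-8)
        assert np.allclose(dec.effects["f:g"], AB, atol=1e-8)
        assert np.allclose(dec.residual, E, atol=1e-8)
        for mat, key in ((A, "f"), (B, "g"), (AB, "f:g"), (E, "residual")):
            assert dec.ssq[key] == pytest.approx((mat ** 2).sum(), abs=1e-8)

    def test_reconstruction_and_ssq_additivity(self, design48, met_names,
                                               strong_phase_spec):
        D = simulate_retention_matrix(design48, strong_phase_spec, met_names, seed=4)
        dec = asca_decompose(D)
        recon = sum(dec.effects.values()) + dec.residual
        assert np.allclose(recon, dec.centered, atol=1e-10)
        parts = sum(v for k, v in dec.ssq.items() if k != "total")
        assert parts == pytest.approx(dec.ssq["total"], rel=1e-8)

    def test_effect_columns_sum_to_zero(self, design48, met_names, strong_phase_spec):
        D = simulate_retention_matrix(design48, strong_phase_spec, met_names, seed=4)
        dec = asca_decompose(D)
        for mat in dec.effects.values():
            assert np.allclose(mat.sum(axis=0), 0.0, atol=1e-9)

    def test_unbalanced_design_rejected(self, rng):
        design = build_design({"f": ["a", "b"]}, 2).iloc[:-1]
        X = pd.DataFrame(rng.normal(size=(3, 2)), index=design.index)
        with pytest.raises(ValueError, match="balance"):
            asca_decompose(X, design)


class TestPermutationTest:
    def test_strong_effect_reaches_minimum_p(self, design48, met_names,
                                             strong_phase_spec):
        D = simulate_retention_matrix(design48, strong_phase_spec, met_names, seed=2)
        res = asca_permutation_test(D, term="phase", n_perm=500, seed=0)
        assert res.p_value == 1 / 501

    def test_p_value_bounds(self, design48, met_names):
        D = simulate_retention_matrix(design48, effect_spec(residual_sd=1.0),
                                      met_names, seed=6)
        res = asca_permutation_test(D, term="pH", n_perm=99, seed=1)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_bit_exact_reproducibility_under_seed(self, rng):
        design = build_design({"f": ["a", "b"]}, 2)
        X = pd.DataFrame(rng.normal(size=(4, 3)), index=design.index)
        a = asca_permutation_test(X, design, term="f", n_perm=3, seed=11)
        b = asca_permutation_test(X, design, term="f", n_perm=3, seed=11)
        assert np.array_equal(a.null_ssq, b.null_ssq)
        assert a.p_value == b.p_value

    def test_interaction_term_testable(self, design48, met_names):
        inter = {("phase", "pH"): {("diol", "acid"): 2.0, ("diol", "neutral"): -2.0,
                                   ("amide", "acid"): -2.0, ("amide", "neutral"): 2.0}}
        D = simulate_retention_matrix(design48,
                                      effect_spec(residual_sd=0.1, interactions=inter),
                                      met_names, seed=8)
        res = asca_permutation_test(D, term="phase:pH", n_perm=200, seed=3)
        assert res.p_value == 1 / 201

    def test_restricted_scheme_calibrated_with_active_nuisance(self, design48,
                                                               met_names):
        # with a strong phase effect, free row permutation is conservative for
        # a null ionic-strength term; within-strata permutation is not
        spec = effect_spec(phase={"BEH_amide": 0.5, "amide": -0.5,
                                  "zwitterionic": 0.25, "diol": -0.25},
                           residual_sd=0.1)
        ps = []
        for i in range(40):
            D = simulate_retention_matrix(design48, spec, met_names, seed=900 + i)
            ps.append(asca_permutation_test(D, term="ionic_strength", n_perm=99,
                                            seed=i, scheme="within").p_value)
        # p should look uniform, not pile up at 1
        assert 0.2 < np.mean(ps) < 0.8

    def test_bad_inputs(self, design48, met_names):
        D = simulate_retention_matrix(design48, effect_spec(residual_sd=0.1),
                                      met_names, seed=0)
        with pytest.raises(ValueError):
            asca_permutation_test(D, term="phase", n_perm=0, seed=1)
        with pytest.raises(ValueError, match="seed"):
            asca_permutation_test(D, term="phase", n_perm=10)
        with pytest.raises(ValueError, match="unknown term"):
            asca_permutation_test(D, term="nope", n_perm=10, seed=1)


class TestEffectScores:
    def test_two_level_factor_is_one_dimensional(self, rng):
        design = build_design({"f": ["a", "b"]}, 3)
        X = pd.DataFrame(rng.normal(size=(6, 4)), index=design.index)
        dec = asca_decompose(X, design)
        es = asca_effect_scores(dec, "f", n_components=2)
        assert es.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_symmetric_offsets_give_symmetric_scores(self, design48, met_names):
        offs = {"BEH_amide": 1.0, "amide": -1.0, "zwitterionic": 0.0, "diol": 0.0}
        D = simulate_retention_matrix(design48, effect_spec(phase=offs), met_names, seed=0)
        es = asca_effect_scores(asca_decompose(D), "phase")
        lookup = dict(zip(es.level_labels, es.scores[:, 0]))
        assert lookup["BEH_amide"] == pytest.approx(-lookup["amide"])
        assert lookup["zwitterionic"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_svd_oracle_on_level_means(self, design48, met_names,
                                               strong_phase_spec):
        D = simulate_retention_matrix(design48, strong_phase_spec, met_names, seed=13)
        dec = asca_decompose(D)
        es = asca_effect_scores(dec, "phase", n_components=3)
        M = dec.level_means["phase"].to_numpy()
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        assert np.allclose(np.abs(es.scores), np.abs(U[:, :3] * s[:3]), atol=1e-8)
        assert np.allclose(es.explained_variance_fraction,
                           s[:3] ** 2 / (s ** 2).sum(), atol=1e-10)
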