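"""Archetypal analysis, PCA co-embedding, and their oracles."""

import numpy as np
import pandas as pd
import pytest

from injuryarch import injury_space
from injuryarch.injury_space import (
    archetype_scores,
    assign_clusters,
    fit_archetypes,
    fit_pca,
    label_archetypes,
    rss_scree,
    simplex_lstsq,
    standardize,
    top_correlated_genes,
)
from injuryarch.synthetic_cohort import reference_profiles


class TestStandardize:
    def test_closed_form_three_values(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=["x", "y", "z"])
        out = standardize(df)
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 1.0])  # sample SD = 1

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        once = standardize(df)
        twice = standardize(once.df)
        assert np.abs(once.values - twice.values).max() < 1e-9

    def test_randomized_matrix_against_manual_accumulation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
        out = standardize(df)
        for j, col in enumerate("abc"):
            v = df[col].to_numpy()
            mean = sum(v) / len(v)
            sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
            assert np.allclose(out.values[:, j], (v - mean) / sd)

    def test_constant_column_becomes_zeros_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(df)
        assert np.allclose(out.values[:, 1], 0.0)


class TestSimplexProjection:
    def test_vertex_maps_to_unit_vector(self):
        Z = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w = simplex_lstsq(Z, np.array([1.0, 0.0]))
        assert np.allclose(w, [0, 1, 0], atol=1e-8)

    def test_midpoint_of_two_archetypes(self):
        Z = np.array([[0.0, 0.0], [2.0, 2.0]])
        w = simplex_lstsq(Z, np.array([1.0, 1.0]))
        assert np.allclose(w, [0.5, 0.5], atol=1e-8)

    def test_grid_dominance_on_random_points(self):
        # returned weights beat every vector on a 0.01-step simplex grid
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(3, 2))
        grid = np.array(
            [
                [i / 100, j / 100, (100 - i - j) / 100]
                for i in range(101)
                for j in range(101 - i)
            ]
        )
        for _ in range(5):
            x = rng.normal(size=2)
            w = simplex_lstsq(Z, x)
            best_grid = ((grid @ Z - x) ** 2).sum(axis=1).min()
            assert ((w @ Z - x) ** 2).sum() <= best_grid + 1e-10


class TestFitArchetypes:
    def test_exact_fit_three_repeated_points(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(3, 4))
        X = np.repeat(pts, 10, axis=0)
        model = fit_archetypes(X, k=3, restarts=5, seed=0)
        assert model.rss < 1e-10
        # archetypes match the three generators up to permutation
        d = np.linalg.norm(model.Z[:, None, :] - pts[None, :, :], axis=2)
        assert d.min(axis=1).max() < 1e-5

    def test_k1_gives_the_mean_point(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        model = fit_archetypes(X, k=1, restarts=3, seed=0)
        assert np.allclose(model.Z[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(model.A, 1.0)

    def test_simplex_conservation(self, small_cohort):
        model = fit_archetypes(standardize(small_cohort["scores"]), k=4, restarts=3, seed=1)
        assert np.abs(model.A.sum(axis=1) - 1).max() < 1e-8
        assert np.abs(model.B.sum(axis=1) - 1).max() < 1e-8
        assert (model.A >= -1e-12).all() and (model.B >= -1e-12).all()
        assert np.allclose(model.Z, model.B @ standardize(small_cohort["scores"]).values)

    def test_fit_dominates_one_hot_assignment(self, small_cohort):
        X = standardize(small_cohort["scores"]).values
        model = fit_archetypes(X, k=5, restarts=3, seed=2)
        d2 = ((X[:, None, :] - model.Z[None, :, :]) ** 2).sum(axis=2)
        one_hot_rss = d2.min(axis=1).sum()
        assert model.rss <= one_hot_rss + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="k="):
            fit_archetypes(np.zeros((3, 2)) + 1.0, k=4)
        with pytest.raises(ValueError, match="finite"):
            fit_archetypes(np.array([[np.nan, 1.0], [0.0, 1.0]]), k=1)


@pytest.fixture(scope="module")
def model(small_cohort):
    return fit_archetypes(standardize(small_cohort["scores"]), k=6, restarts=5, seed=3)


class TestScoringAndAssignment:

    def test_archetype_itself_gets_unit_weight(self, model):
        A_new = archetype_scores(model, model.Z)
        assert np.allclose(A_new, np.eye(model.k), atol=1e-6)

    def test_midpoint_symmetry_k2(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] * 5)
        model = fit_archetypes(X, k=2, restarts=3, seed=0)
        mid = model.Z.mean(axis=0)
        w = archetype_scores(model, mid[None, :])[0]
        assert np.allclose(w, [0.5, 0.5], atol=1e-6)

    def test_dimension_mismatch_is_an_error(self, model):
        with pytest.raises(ValueError, match="dimension"):
            archetype_scores(model, np.zeros((2, 5)))

    def test_assign_clusters_argmax_and_ties(self):
        A = np.array([[0.7, 0.1, 0.2], [0.5, 0.5, 0.0]])
        out = assign_clusters(A, ["a", "b"])
        assert out["archetype_index"].tolist() == [1, 1]  # tie -> lowest index
        assert out["max_score"].tolist() == [0.7, 0.5]
        assert out["sample_id"].tolist() == ["a", "b"]


class TestLabeling:
    def test_identity_on_noise_free_reference_data(self):
        ref = reference_profiles()
        X = pd.DataFrame(
            np.repeat(ref.to_numpy(), 12, axis=0), columns=ref.columns,
            index=[f"s{i}" for i in range(72)],
        )
        model = fit_archetypes(standardize(X), k=6, restarts=5, seed=0)
        labels, report = label_archetypes(model, X)
        # every scenario label appears exactly once
        assert sorted(labels.values()) == sorted(injury_space.ARCHETYPE_LABELS)
        # each labeled archetype reproduces its reference IRRAT ordering
        irrat = {labels[i + 1]: model.archetype_table.iloc[i]["IRRAT"] for i in range(6)}
        assert irrat["AKI2"] > irrat["AKI1"] > irrat["no injury"]

    def test_labels_follow_profiles_not_indices(self, small_cohort):
        model = fit_archetypes(standardize(small_cohort["scores"]), k=6, restarts=5, seed=4)
        labels, _ = label_archetypes(model)
        # permute archetype order and refit the mapping
        perm = np.array([2, 0, 1, 5, 4, 3])
        permuted = injury_space.ArchetypeModel(
            k=model.k, Z=model.Z[perm], A=model.A[:, perm], B=model.B[perm],
            rss=model.rss, n_iter=model.n_iter, converged=model.converged,
            seed=model.seed, restarts=model.restarts,
            feature_names=model.feature_names, sample_ids=model.sample_ids,
            means=model.means, sds=model.sds,
        )
        labels_p, _ = label_archetypes(permuted)
        for new_idx, old_idx in enumerate(perm):
            assert labels_p[new_idx + 1] == labels[old_idx + 1]

    def test_non_six_k_returns_indices(self, small_cohort):
        model = fit_archetypes(standardize(small_cohort["scores"]), k=3, restarts=2, seed=0)
        labels, _ = label_archetypes(model)
        assert labels == {1: "archetype_1", 2: "archetype_2", 3: "archetype_3"}


class TestScree:
    def test_exact_fit_data_reaches_zero_at_k3(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(3, 3))
        w = rng.dirichlet(np.ones(3), size=40)
        # the generator vertices must be present in the data for an exact fit:
        # archetypes live in the convex hull of the observed samples
        X = np.vstack([pts, w @ pts])
        scree = rss_scree(X, range(2, 6), restarts=5, seed=0)
        assert len(scree) == 4
        assert (scree.loc[3:] < 1e-8).all()

    def test_planted_k6_has_largest_drop_by_k6(self, small_cohort):
        X = standardize(small_cohort["scores"])
        scree = rss_scree(X, range(2, 8), restarts=3, seed=0)
        drops = -scree.diff().dropna() / scree.shift(1).dropna()
        assert drops.idxmax() <= 6


class TestPCA:
    def test_scores_reproduce_projection_and_variance(self, small_cohort):
        X = standardize(small_cohort["scores"])
        pca = fit_pca(X)
        proj = X.values @ pca.loadings.to_numpy()
        assert np.abs(proj - pca.scores.to_numpy()).max() < 1e-8
        assert pca.scores.to_numpy().var(axis=0, ddof=1).sum() == pytest.approx(
            X.values.var(axis=0, ddof=1).sum(), abs=1e-8
        )
        L = pca.loadings.to_numpy()
        assert np.abs(L.T @ L - np.eye(L.shape[1])).max() < 1e-8

    def test_orientation_is_deterministic_and_anchored(self, small_cohort):
        X = standardize(small_cohort["scores"])
        p1, p2 = fit_pca(X), fit_pca(X)
        pd.testing.assert_frame_equal(p1.scores, p2.scores)
        assert p1.loadings.loc["IRRAT", "PC1"] > 0
        assert p1.loadings.loc["IRRAT", "PC2"] < 0
        assert p1.loadings.loc["IGT", "PC3"] < 0

    def test_aki2_sits_below_ckd_on_pc2(self, small_cohort):
        X = standardize(small_cohort["scores"])
        pca = fit_pca(X)
        labs = small_cohort["truth"].cluster_labels
        pc2 = pca.scores["PC2"].to_numpy()
        assert pc2[labs == "AKI2"].mean() < pc2[labs == "CKD"].mean()


class TestTopCorrelatedGenes:
    def test_constructed_probe_ranks_first_and_last(self, small_cohort):
        from injuryarch.formats import ExpressionMatrix

        X = standardize(small_cohort["scores"])
        pca = fit_pca(X)
        pc3 = pca.scores["PC3"]
        rng = np.random.default_rng(7)
        base = np.exp(rng.normal(4, 1, size=(5, len(pc3))))
        vals = np.vstack([
            np.exp(pc3.to_numpy()),          # monotone in PC3 -> rho = 1
            np.exp(-pc3.to_numpy()),         # anti-correlated -> last
            base,
        ])
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=["hit", "anti"] + [f"bg{i}" for i in range(5)],
                         columns=pc3.index),
            [],
        )
        ranked = top_correlated_genes(expr, pc3, n_top=7)
        assert ranked.iloc[0]["probe_id"] == "hit"
        assert ranked.iloc[0]["rho"] == pytest.approx(1.0)
        assert ranked.iloc[-1]["probe_id"] == "anti"

    def test_rho_matches_brute_force_rank_correlation(self):
        from injuryarch.formats import ExpressionMatrix
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        vals = np.exp(rng.normal(3, 1, size=(6, 15)))
        samples = [f"s{i}" for i in range(15)]
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(6)], columns=samples), []
        )
        y = pd.Series(rng.normal(size=15), index=samples)
        ranked = top_correlated_genes(expr, y, n_top=6)
        for _, row in ranked.iterrows():
            expected = spearmanr(expr.values.loc[row["probe_id"]], y).statistic
            assert row["rho"] == pytest.approx(expected, abs=1e-12)
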