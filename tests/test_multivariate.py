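"""Population profiling: distances, UPGMA clustering, and correlation PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from breedvar import (
    PopulationPCA,
    UPGMAClusterer,
    cluster_profiles,
    euclidean_matrix,
    pca,
    population_means,
    upgma,
)
from breedvar.reference import GOMATI_M2_MEANS

from conftest import make_cell_table


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    d = squareform(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)), checks=False)
    labels = [f"P{i}" for i in range(n)]
    return pd.DataFrame(squareform(d), index=labels, columns=labels)


def power_iteration_eigh(C, n_iter=5000, tol=1e-12, seed=0):
    """Brute-force eigensolver: power iteration with deflation."""
    rng = np.random.default_rng(seed)
    C = C.copy().astype(float)
    p = C.shape[0]
    vals, vecs = [], []
    for _ in range(p):
        v = rng.normal(size=p)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = C @ v
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                lam = 0.0
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                lam = float(v @ C @ v)
                break
            v = w
            lam = float(v @ C @ v)
        vals.append(lam)
        vecs.append(v)
        C = C - lam * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


class TestPopulationMeans:
    def test_single_observation_cells_pass_through(self):
        table = make_cell_table({"L1": [4.0]}, treatment="A", trait="X")
        table = pd.concat([
            table,
            make_cell_table({"L1": [7.0]}, treatment="B", trait="X"),
        ])
        m = population_means(table, "V", "M2")
        assert m.loc["A", "X"] == 4.0 and m.loc["B", "X"] == 7.0

    def test_missing_cell_is_listed(self):
        table = pd.concat([
            make_cell_table({"L1": [4.0]}, treatment="A", trait="X"),
            make_cell_table({"L1": [5.0]}, treatment="A", trait="Y"),
            make_cell_table({"L1": [7.0]}, treatment="B", trait="X"),
        ])
        with pytest.raises(ValueError, match=r"\('B', 'Y'\)"):
            population_means(table, "V", "M2")


class TestEuclidean:
    def test_identical_rows_are_at_distance_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"],
                         columns=["x", "y"])
        d = euclidean_matrix(m)
        assert d.loc["a", "b"] == 0.0

    def test_single_trait_distance_is_absolute_difference(self):
        m = pd.DataFrame({"x": [3.0, 7.5]}, index=["a", "b"])
        assert euclidean_matrix(m).loc["a", "b"] == pytest.approx(4.5)

    def test_published_mean_matrix_minimum_pair(self):
        # the two most similar treated populations in the trial's first
        # segregating generation (printed as 2.66; raw means give 2.67)
        d = euclidean_matrix(GOMATI_M2_MEANS)
        assert d.loc["G1+S1", "S3"] == pytest.approx(2.67, abs=0.01)

    def test_metric_axioms_exhaustively(self):
        d = euclidean_matrix(GOMATI_M2_MEANS).to_numpy()
        n = d.shape[0]
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_standardize_flag_and_zero_variance_error(self):
        m = GOMATI_M2_MEANS.copy()
        dz = euclidean_matrix(m, standardize=True)
        assert not np.allclose(dz, euclidean_matrix(m))
        m["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            euclidean_matrix(m, standardize=True)


class TestUpgma:
    def test_three_leaf_hand_computation(self):
        d = pd.DataFrame(
            [[0.0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dend = upgma(d)
        assert dend.merges[0][:3] == (0, 1, 2.0)
        assert dend.merges[1][2] == pytest.approx(4.0)

    def test_equal_distances_merge_at_equal_heights_deterministically(self):
        labels = list("ABCD")
        d = pd.DataFrame(3.0 - 3.0 * np.eye(4), index=labels, columns=labels)
        dend = upgma(d)
        heights = [m[2] for m in dend.merges]
        assert np.allclose(heights, 3.0)
        assert upgma(d).merges == dend.merges  # rerun identical
        # smallest label pair first
        assert sorted([dend.leaf_labels[dend.merges[0][0]],
                       dend.leaf_labels[dend.merges[0][1]]]) == ["A", "B"]

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = random_distance_matrix(rng, int(rng.integers(4, 10)))
            ours = sorted(m[2] for m in upgma(d).merges)
            Z = linkage(squareform(d.to_numpy(), checks=False), method="average")
            assert np.allclose(ours, sorted(Z[:, 2]), atol=1e-10)

    def test_constant_shift_of_distances_shifts_heights(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = random_distance_matrix(rng, 6)
            c = 2.5
            shifted = d + c * (1 - np.eye(6))
            h0 = [m[2] for m in upgma(d).merges]
            h1 = [m[2] for m in upgma(shifted).merges]
            assert np.allclose(np.array(h1) - np.array(h0), c, atol=1e-9)

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            d = random_distance_matrix(rng, 8)
            heights = [m[2] for m in upgma(d).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_fewer_than_two_leaves_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match=">= 2"):
            upgma(d)

    def test_newick_roundtrip_has_all_leaves(self):
        d = euclidean_matrix(GOMATI_M2_MEANS)
        nwk = upgma(d).to_newick()
        assert nwk.endswith(";")
        for label in GOMATI_M2_MEANS.index:
            assert label in nwk


class TestClusterProfiles:
    def test_k_equals_n_reproduces_mean_matrix(self):
        m = GOMATI_M2_MEANS.iloc[:5]
        d = euclidean_matrix(m)
        dend = upgma(d)
        membership, profiles, _ = cluster_profiles(dend, 5, m, d)
        assert membership.nunique() == 5
        aligned = profiles.loc[membership.loc[m.index]].set_index(m.index)
        pd.testing.assert_frame_equal(aligned, m, check_names=False)

    def test_k_one_gives_column_means(self):
        m = GOMATI_M2_MEANS
        d = euclidean_matrix(m)
        membership, profiles, inter = cluster_profiles(upgma(d), 1, m, d)
        assert np.allclose(profiles.loc[1], m.mean(axis=0))
        assert inter.shape == (1, 1)

    def test_recovers_constructed_two_group_split(self):
        m = pd.DataFrame(
            {
                "x": [0.0, 0.1, 10.0, 10.2],
                "y": [0.0, -0.1, 5.0, 5.1],
            },
            index=["a1", "a2", "b1", "b2"],
        )
        d = euclidean_matrix(m)
        membership, profiles, inter = cluster_profiles(upgma(d), 2, m, d)
        assert membership["a1"] == membership["a2"]
        assert membership["b1"] == membership["b2"]
        assert membership["a1"] != membership["b1"]
        # brute force over the 3 balanced 2-splits: chosen one minimizes
        # within-cluster distance
        def within(split):
            return sum(d.loc[a, b] for grp in split for a in grp for b in grp) / 2
        splits = [
            (("a1", "a2"), ("b1", "b2")),
            (("a1", "b1"), ("a2", "b2")),
            (("a1", "b2"), ("a2", "b1")),
        ]
        best = min(splits, key=within)
        assert set(best[0]) in ({"a1", "a2"}, {"b1", "b2"})
        assert inter.loc[1, 2] == pytest.approx(
            d.loc[["a1", "a2"], ["b1", "b2"]].to_numpy().mean()
        )

    def test_invalid_k_rejected(self):
        d = euclidean_matrix(GOMATI_M2_MEANS)
        with pytest.raises(ValueError, match="k must lie"):
            upgma(d).cut(0)

    def test_outlier_population_isolates_at_k2(self):
        m = GOMATI_M2_MEANS.copy()
        m.loc["G4+S4"] += 500.0
        d = euclidean_matrix(m)
        membership = upgma(d).cut(2)
        assert (membership == membership["G4+S4"]).sum() == 1


class TestUPGMAClustererEstimator:
    def test_fit_labels_match_dendrogram_cut(self):
        est = UPGMAClusterer(n_clusters=3).fit(GOMATI_M2_MEANS)
        assert sorted(set(est.labels_)) == [1, 2, 3]
        assert np.array_equal(est.labels_, est.dendrogram_.cut(3).to_numpy())

    def test_precomputed_metric(self):
        d = euclidean_matrix(GOMATI_M2_MEANS)
        est = UPGMAClusterer(n_clusters=3, metric="precomputed").fit(d)
        ref = UPGMAClusterer(n_clusters=3).fit(GOMATI_M2_MEANS)
        assert np.array_equal(est.labels_, ref.labels_)


class TestPca:
    def test_two_trait_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.6 * x + 0.8 * rng.normal(size=200)
        m = pd.DataFrame({"x": x, "y": y})
        rho = float(np.corrcoef(x, y)[0, 1])
        fit = pca(m)
        assert fit.eigenvalues_[0] == pytest.approx(1 + abs(rho), abs=1e-10)
        assert fit.eigenvalues_[1] == pytest.approx(1 - abs(rho), abs=1e-10)
        assert fit.explained_pct_.iloc[0] == pytest.approx(
            100 * (1 + abs(rho)) / 2, abs=1e-8
        )

    def test_correlation_mode_identities(self):
        fit = pca(GOMATI_M2_MEANS)
        assert fit.eigenvalues_.sum() == pytest.approx(10.0, abs=1e-10)
        assert np.allclose(fit.cos2_.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(fit.contributions_.sum(axis=0), 100.0, atol=1e-8)
        assert ((fit.cos2_ >= -1e-12) & (fit.cos2_ <= 1 + 1e-12)).all().all()

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = pd.DataFrame(rng.normal(size=(13, 10)))
            fit = pca(m)
            Z = (m - m.mean()) / m.std(ddof=1)
            C = np.corrcoef(Z, rowvar=False)
            vals, vecs = power_iteration_eigh(C, seed=int(rng.integers(1e6)))
            assert np.allclose(sorted(vals), sorted(fit.eigenvalues_), atol=1e-8)
            for k in range(10):
                v_ref = vecs[:, np.argsort(vals)[::-1][k]]
                v = fit.components_.iloc[:, k].to_numpy()
                if fit.eigenvalues_[k] > 1e-8:
                    assert abs(abs(v_ref @ v) - 1.0) < 1e-6

    def test_row_permutation_permutes_scores_only(self):
        perm = list(GOMATI_M2_MEANS.index[::-1])
        a = pca(GOMATI_M2_MEANS)
        b = pca(GOMATI_M2_MEANS.loc[perm])
        assert np.allclose(a.eigenvalues_, b.eigenvalues_, atol=1e-10)
        assert np.allclose(
            a.scores_.loc[perm].to_numpy(), b.scores_.to_numpy(), atol=1e-8
        )

    def test_sign_convention_is_deterministic(self):
        a = pca(GOMATI_M2_MEANS)
        b = pca(GOMATI_M2_MEANS)
        pd.testing.assert_frame_equal(a.loadings_, b.loadings_)
        for k in a.components_.columns:
            col = a.components_[k]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_extreme_population_lands_at_extreme_pc1(self):
        m = GOMATI_M2_MEANS.copy()
        m.loc["G4+S4"] = m.loc["G4+S4"] + 80.0
        fit = pca(m)
        pc1 = fit.scores_["PC1"].abs()
        assert pc1.idxmax() == "G4+S4"

    def test_zero_variance_trait_named_in_error(self):
        m = GOMATI_M2_MEANS.copy()
        m["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            pca(m)

    def test_transform_matches_fitted_scores(self):
        fit = PopulationPCA().fit(GOMATI_M2_MEANS)
        again = fit.transform(GOMATI_M2_MEANS)
        assert np.allclose(again.to_numpy(), fit.scores_.to_numpy(), atol=1e-10)
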