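"""Correlation-matrix PCA and group summaries."""

import numpy as np
import pandas as pd
import pytest

import honeypower as hp
from honeypower.ordination import PCA_VARIABLES, pca_from_correlation


def compound_symmetry(p, rho):
    return (1 - rho) * np.eye(p) + rho * np.ones((p, p))


def test_compound_symmetry_closed_form():
    """rho=0.5, p=4: eigenvalues (2.5, 0.5, 0.5, 0.5) => 62.5/12.5/12.5/12.5%."""
    res = pca_from_correlation(compound_symmetry(4, 0.5))
    np.testing.assert_allclose(res.eigenvalues, [2.5, 0.5, 0.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(res.explained_pct, [62.5, 12.5, 12.5, 12.5], atol=1e-9)


def test_reconstruction_of_correlation_matrix():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 4))
    corr = np.corrcoef((a @ a.T + 6 * np.eye(6)))
    res = pca_from_correlation(corr)
    recon = res.components @ np.diag(res.eigenvalues) @ res.components.T
    np.testing.assert_allclose(recon, corr, atol=1e-9)
    # loadings carry the same reconstruction
    np.testing.assert_allclose(res.loadings @ res.loadings.T, corr, atol=1e-9)


def test_components_are_orthonormal():
    res = pca_from_correlation(compound_symmetry(5, 0.3))
    np.testing.assert_allclose(res.components.T @ res.components, np.eye(5), atol=1e-10)


def test_contributions_sum_to_100_per_component():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(50, 4))
    table = pd.DataFrame(x, columns=PCA_VARIABLES)
    res = hp.run_pca(table)
    np.testing.assert_allclose(res.contributions_pct.sum(axis=0), 100.0, atol=1e-9)
    np.testing.assert_allclose(res.explained_pct.sum(), 100.0, atol=1e-9)


def test_uncorrelated_variables_near_isotropy():
    rng = np.random.default_rng(11)
    table = pd.DataFrame(rng.normal(size=(20000, 4)), columns=PCA_VARIABLES)
    res = hp.run_pca(table)
    np.testing.assert_allclose(res.explained_pct, 25.0, atol=2.0)


def test_duplicated_variable_gives_zero_eigenvalue():
    rng = np.random.default_rng(5)
    x = rng.normal(size=100)
    table = pd.DataFrame({
        "free_acidity": x, "colour_L": x,  # r = 1 pair
        "colour_a": rng.normal(size=100), "power_of_honey": rng.normal(size=100),
    })
    res = hp.run_pca(table)
    assert abs(res.eigenvalues[-1]) < 1e-10


def test_row_permutation_leaves_decomposition_unchanged():
    rng = np.random.default_rng(7)
    table = pd.DataFrame(rng.normal(size=(60, 4)), columns=PCA_VARIABLES)
    res1 = hp.run_pca(table)
    res2 = hp.run_pca(table.sample(frac=1.0, random_state=1).reset_index(drop=True))
    np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
    np.testing.assert_allclose(res1.components, res2.components, atol=1e-10)


def test_sign_convention_largest_loading_positive():
    res = pca_from_correlation(compound_symmetry(4, 0.4))
    for j in range(4):
        k = np.argmax(np.abs(res.components[:, j]))
        assert res.components[k, j] > 0


def test_agreement_with_sklearn():
    """Independent cross-check of eigenvalues and explained variance."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(21)
    base = rng.normal(size=(200, 2))
    x = np.column_stack([base[:, 0], 0.7 * base[:, 0] + base[:, 1],
                         rng.normal(size=200), base[:, 1] - 0.5 * base[:, 0]])
    table = pd.DataFrame(x, columns=PCA_VARIABLES)
    res = hp.run_pca(table)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    sk = sklearn.PCA(n_components=4).fit(z)
    # sklearn scales eigenvalues by (n-1) sample covariance of z == corr
    np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_, rtol=1e-8)
    np.testing.assert_allclose(
        res.explained_pct, 100 * sk.explained_variance_ratio_, rtol=1e-8
    )


def test_guards():
    table = pd.DataFrame(np.ones((10, 4)), columns=PCA_VARIABLES)
    with pytest.raises(ValueError, match="constant"):
        hp.run_pca(table)
    small = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                         columns=PCA_VARIABLES)
    with pytest.raises(ValueError, match="too few"):
        hp.run_pca(small)


class TestGroups:
    def test_identical_scores_give_exact_centroids(self):
        scores = np.array([[1.0, 2.0]] * 3 + [[3.0, -1.0]] * 2)
        labels = ["a"] * 3 + ["b"] * 2
        out = hp.summarize_groups(scores, labels)
        assert out.loc[out.floral_type == "a", ["pc1", "pc2"]].to_numpy().tolist() == [[1.0, 2.0]]
        assert out.attrs["pairwise_distances"][("a", "b")] == pytest.approx(
            np.hypot(2.0, 3.0)
        )

    def test_single_group_centroid_is_column_mean(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(10, 3))
        out = hp.summarize_groups(scores, ["x"] * 10)
        np.testing.assert_allclose(
            out[["pc1", "pc2", "pc3"]].to_numpy()[0], scores.mean(0), atol=1e-12
        )

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError, match="align"):
            hp.summarize_groups(np.zeros((4, 2)), ["a", "b"])

    def test_forest_centroid_extreme_on_acidity_axis(self, default_cohort):
        """On the default cohort the forest centroid projects highest on the
        component aligned with free acidity / a*."""
        frame, _ = default_cohort
        table = hp.score_table(frame)
        pca_in = pd.DataFrame({
            "free_acidity": frame["free_acidity"],
            "colour_L": frame["colour_L"],
            "colour_a": frame["colour_a"],
            "power_of_honey": table["power_of_honey"],
        })
        res = hp.run_pca(pca_in)
        cent = hp.summarize_groups(res.scores, frame["floral_type"].to_numpy())
        # component with the largest |loading| on free_acidity
        j = int(np.argmax(np.abs(res.loadings[0, :])))
        sign = np.sign(res.loadings[0, j])
        proj = cent.set_index("floral_type")[f"pc{j + 1}"] * sign
        assert proj.idxmax() == "forest"
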