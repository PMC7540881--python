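import numpy as np
import pytest

from elnm.models import SuitabilityMap
from elnm.niche_space import (cluster_niches, dendrogram_newick, dissimilarity,
                              fit_pca, hellinger_i, inertia_ellipse,
                              overlap_matrix, project_eln, schoener_d)
from elnm.raster import Grid

from conftest import make_stack


def suit_map(values, group_id="g"):
    values = np.atleast_2d(np.asarray(values, float))
    g = Grid(*values.shape, 0.0, float(values.shape[0]), 1.0)
    return SuitabilityMap(group_id, g, values, np.zeros(values.shape, bool))


def square_stack(arrays):
    n = next(iter(arrays.values())).shape[0]
    g = Grid(n, n, 0.0, float(n), 1.0)
    return make_stack(g, arrays)


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self, rng):
        a = rng.standard_normal((20, 20))
        pca = fit_pca(square_stack({"a": a, "b": 3 * a + 1}))
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_eigenvalues_match_correlation_eigendecomposition(self, rng):
        arrays = {f"v{i}": rng.standard_normal((15, 15)) for i in range(4)}
        pca = fit_pca(square_stack(arrays))
        X = np.column_stack([a.ravel() for a in arrays.values()])
        expected = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert np.allclose(np.sort(pca.eigenvalues)[::-1], expected, atol=1e-9)

    def test_independent_equal_variance_split_evenly(self, rng):
        a = rng.standard_normal((60, 60))
        b = rng.standard_normal((60, 60))
        pca = fit_pca(square_stack({"a": a, "b": b}))
        assert pca.explained_variance_fraction[0] == pytest.approx(0.5, abs=0.03)

    def test_sklearn_cross_check(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        arrays = {f"v{i}": rng.standard_normal((12, 12)) for i in range(5)}
        pca = fit_pca(square_stack(arrays))
        X = np.column_stack([a.ravel() for a in arrays.values()])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = SkPCA().fit(Z)
        # same spectrum and, up to sign, the same scores
        assert np.allclose(pca.eigenvalues, sk.explained_variance_, atol=1e-8)
        ours = pca.transform(X)
        theirs = sk.transform(Z)
        for j in range(5):
            assert np.allclose(np.abs(ours[:, j]), np.abs(theirs[:, j]), atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        arrays = {f"v{i}": rng.standard_normal((10, 10)) for i in range(6)}
        pca = fit_pca(square_stack(arrays))
        gram = pca.loadings.T @ pca.loadings
        assert np.abs(gram - np.eye(6)).max() < 1e-8


class TestProjection:
    def test_zero_threshold_projects_all_valid_cells(self, rng):
        stack = square_stack({"a": rng.random((8, 8)), "b": rng.random((8, 8))})
        pca = fit_pca(stack)
        eln = suit_map(rng.uniform(0.01, 1.0, (8, 8)))
        cloud = project_eln(pca, eln, stack, threshold=0.0)
        assert cloud.scores.shape[0] == 64

    def test_cell_count_above_threshold(self, rng):
        stack = square_stack({"a": rng.random((5, 5)), "b": rng.random((5, 5))})
        pca = fit_pca(stack)
        values = np.full((5, 5), 0.2)
        values.ravel()[:7] = 0.95
        cloud = project_eln(pca, suit_map(values), stack, threshold=0.9)
        assert cloud.scores.shape[0] == 7 and not cloud.empty

    def test_empty_cloud_flagged(self, rng):
        stack = square_stack({"a": rng.random((5, 5)), "b": rng.random((5, 5))})
        pca = fit_pca(stack)
        cloud = project_eln(pca, suit_map(np.full((5, 5), 0.5)), stack, 0.9)
        assert cloud.empty and cloud.scores.shape[0] == 0


class TestEllipse:
    def test_gaussian_coverage_matches_target(self, rng):
        pts = rng.standard_normal((100_000, 2))
        spec = inertia_ellipse(pts, coverage=0.61)
        assert spec.contains(pts).mean() == pytest.approx(0.61, abs=0.01)

    def test_isotropic_cloud_has_equal_axes(self, rng):
        pts = rng.standard_normal((50_000, 2))
        spec = inertia_ellipse(pts, coverage=0.61)
        eigvals = np.linalg.eigvalsh(spec.covariance)
        assert eigvals[1] / eigvals[0] == pytest.approx(1.0, abs=0.05)

    def test_zero_coverage_degenerates_to_center(self, rng):
        pts = rng.standard_normal((100, 2))
        spec = inertia_ellipse(pts, coverage=0.0)
        assert np.all(spec.covariance == 0)
        assert np.allclose(spec.center, pts.mean(axis=0))


class TestOverlap:
    def test_identical_maps_overlap_one(self, rng):
        m = suit_map(rng.random((4, 4)))
        assert schoener_d(m, m) == pytest.approx(1.0)
        assert hellinger_i(m, m) == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        a = suit_map([[1.0, 1.0, 0.0, 0.0]])
        b = suit_map([[0.0, 0.0, 1.0, 1.0]])
        assert schoener_d(a, b) == 0.0
        assert hellinger_i(a, b) == pytest.approx(0.0)

    def test_hand_evaluated_half_overlap(self):
        a = suit_map([[0.5, 0.5, 0.0]])
        b = suit_map([[0.0, 0.5, 0.5]])
        assert schoener_d(a, b) == pytest.approx(0.5)
        assert hellinger_i(a, b) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        vals = rng.random((5, 5))
        a, b = suit_map(vals), suit_map(rng.random((5, 5)))
        scaled = suit_map(vals * 0.37)
        assert schoener_d(a, b) == pytest.approx(schoener_d(scaled, b), abs=1e-12)
        assert hellinger_i(a, b) == pytest.approx(hellinger_i(scaled, b), abs=1e-12)

    def test_literal_formula_oracle(self, rng):
        for _ in range(20):
            u, v = rng.random(30), rng.random(30)
            a, b = suit_map([u]), suit_map([v])
            p, q = u / u.sum(), v / v.sum()
            assert schoener_d(a, b) == pytest.approx(
                1 - 0.5 * np.abs(p - q).sum(), abs=1e-12)
            assert hellinger_i(a, b) == pytest.approx(
                1 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum(), abs=1e-12)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            schoener_d(suit_map([[0.0, 0.0]]), suit_map([[0.5, 0.5]]))

    def test_matrix_symmetry_and_pairwise_consistency(self, rng):
        maps = [suit_map(rng.random((4, 4)), f"{i}") for i in range(3)]
        D, I = overlap_matrix(maps)
        for M in (D, I):
            assert np.allclose(M.values, M.values.T, atol=1e-12)
            assert np.allclose(np.diag(M.values), 1.0)
        assert D.loc["0", "2"] == pytest.approx(schoener_d(maps[0], maps[2]))
        assert np.allclose(np.diag(dissimilarity(D).values), 0.0)


def brute_force_complete_linkage(rows):
    """O(n^3) agglomeration oracle on Euclidean distances between rows."""
    clusters = [[i] for i in range(len(rows))]
    dist = lambda i, j: float(np.linalg.norm(rows[i] - rows[j]))
    merges = []
    active = list(range(len(rows)))
    members = {i: [i] for i in active}
    next_id = len(rows)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                h = max(dist(x, y) for x in members[a] for y in members[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merges.append(h)
        members[next_id] = members.pop(a) + members.pop(b)
        active = [k for k in active if k not in (a, b)] + [next_id]
        next_id += 1
    return merges


class TestClustering:
    def test_identical_niches_merge_first_at_zero(self, rng):
        vals = rng.random((4, 4))
        maps = [suit_map(vals, "a"), suit_map(vals, "b"),
                suit_map(rng.random((4, 4)), "c")]
        D, _ = overlap_matrix(maps)
        link = cluster_niches(dissimilarity(D))
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(link[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_monotone(self, rng):
        import pandas as pd

        for _ in range(5):
            link = cluster_niches(pd.DataFrame(rng.random((7, 7))))
            assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_four_niche_case_matches_brute_force(self, rng):
        rows = rng.random((4, 4))
        import pandas as pd
        link = cluster_niches(pd.DataFrame(rows))
        assert np.allclose(sorted(link[:, 2]),
                           sorted(brute_force_complete_linkage(rows)), atol=1e-12)

    def test_newick_serialization_parses(self, rng):
        import dendropy
        import pandas as pd

        rows = rng.random((5, 5))
        labels = [f"g{i}" for i in range(5)]
        nwk = dendrogram_newick(cluster_niches(pd.DataFrame(rows)), labels)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == labels
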