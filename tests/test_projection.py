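import numpy as np
import pytest

import cytoref as cr
from cytoref import (
    QueryCytometry,
    cosine_distance,
    inconsistency_score,
    project,
    rank_normalize,
)


def brute_force_knn(qry, ref, k):
    """All-pairs cosine-distance scan oracle (per-event python loop)."""
    out = []
    for i in range(qry.shape[0]):
        d = np.array([cosine_distance(qry[i], ref[j]) for j in range(ref.shape[0])])
        out.append(np.argsort(d, kind="stable")[:k])
    return np.array(out)


class TestRankNormalize:
    def test_basic_convention(self):
        np.testing.assert_allclose(rank_normalize([3, 1, 2]), [1.0, 0.0, 0.5])

    def test_tie_convention_average_ranks(self):
        np.testing.assert_allclose(rank_normalize([5, 5, 1]), [0.75, 0.75, 0.0])

    def test_endpoints_exact(self, rng):
        r = rank_normalize(rng.normal(size=50))
        assert r.min() == 0.0 and r.max() == 1.0

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=100)
        for f in (np.exp, lambda v: v**3, lambda v: np.arcsinh(3 * v)):
            np.testing.assert_allclose(rank_normalize(f(x)), rank_normalize(x))

    def test_all_tied_warns_half(self):
        with pytest.warns(UserWarning, match="tied"):
            r = rank_normalize(np.full(5, 2.0))
        assert np.all(r == 0.5)


class TestCosineDistance:
    def test_closed_forms(self):
        assert cosine_distance([1, 2], [1, 2]) == pytest.approx(0.0)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 1], [1, 0]) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="undefined direction"):
            cosine_distance([0, 0], [1, 1])


class TestInconsistencyScore:
    def test_identical_rows_zero(self):
        assert inconsistency_score(np.ones((4, 3))) == 0.0

    def test_two_rows_distance(self):
        x = np.array([[0.0, 0], [3.0, 4]])
        assert inconsistency_score(x) == pytest.approx(5.0)

    def test_matches_bruteforce_pairwise_mean(self, rng):
        x = rng.normal(size=(4, 10))
        pairs = [np.linalg.norm(x[i] - x[j]) for i in range(4) for j in range(i + 1, 4)]
        assert inconsistency_score(x) == pytest.approx(np.mean(pairs))

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            inconsistency_score(np.ones((1, 3)))


class TestProject:
    def test_knn_matches_bruteforce_oracle(self, atlas, rng):
        from cytoref.projection import _rank_matrix, shared_markers

        for _ in range(5):
            idx = rng.choice(atlas.n_cells, size=50, replace=False)
            sub = atlas.subset_cells(idx)
            qvals = rng.normal(size=(10, 5))
            query = QueryCytometry(intensities=qvals,
                                   marker_names=sub.expr.feature_names[:5])
            res = project(query, sub, k=4, inconsistency_threshold=np.inf)
            markers = shared_markers(query, sub)
            oracle = brute_force_knn(_rank_matrix(qvals[:, :len(markers)]),
                                     _rank_matrix(sub.expr.subset_features(markers).values), 4)
            expected = [[sub.expr.cell_ids[j] for j in row] for row in oracle]
            assert [list(r) for r in res.neighbor_ids] == expected

    def test_self_projection_identity(self, atlas):
        """The atlas's own antibody matrix, arbitrarily monotonically
        transformed, self-matches at k=1 for cells with distinct profiles."""
        sub = atlas.subset_cells(np.arange(200))
        query = QueryCytometry(intensities=np.exp(sub.expr.values),
                               marker_names=sub.expr.feature_names)
        res = project(query, sub, k=1, inconsistency_threshold=np.inf)
        matches = np.array([res.neighbor_ids[i][0] == sub.expr.cell_ids[i]
                            for i in range(200)])
        assert matches.mean() > 0.99
        assert np.all(res.transferred_label[matches]
                      == sub.cell_type[np.flatnonzero(matches)])

    def test_monotone_invariance_end_to_end(self, atlas, config, rng):
        query, _ = cr.generate_query(config, 100, seed=3)
        base = project(query, atlas, k=4)
        x = query.intensities
        transformed = QueryCytometry(
            intensities=np.stack([np.exp(0.3 * x[:, j]) if j % 2 else x[:, j] ** 3
                                  for j in range(x.shape[1])], axis=1),
            marker_names=query.marker_names,
        )
        res = project(transformed, atlas, k=4)
        assert [list(r) for r in res.neighbor_ids] == [list(r) for r in base.neighbor_ids]
        assert np.array_equal(res.transferred_label, base.transferred_label)

    def test_embedding_is_neighbor_mean(self, atlas, config):
        query, _ = cr.generate_query(config, 20, seed=4)
        res = project(query, atlas, k=4)
        id_to_row = {c: i for i, c in enumerate(atlas.expr.cell_ids)}
        for i in range(20):
            rows = [id_to_row[c] for c in res.neighbor_ids[i]]
            np.testing.assert_allclose(res.embedding_coords[i],
                                       atlas.embedding[rows].mean(axis=0))

    def test_filtered_fraction_monotone_in_threshold(self, atlas, config):
        query, _ = cr.generate_query(config, 300, seed=5)
        res = project(query, atlas, k=4, inconsistency_threshold=np.inf)
        kept = [np.mean(res.inconsistency <= t) for t in (0.1, 0.5, 1.0, 2.0, np.inf)]
        assert all(a <= b for a, b in zip(kept, kept[1:]))

    def test_identical_latent_rows_give_zero_inconsistency(self, atlas):
        sub = atlas.subset_cells(np.arange(10))
        sub.latent[:] = 1.0
        query = QueryCytometry(intensities=sub.expr.values,
                               marker_names=sub.expr.feature_names)
        res = project(query, sub, k=4, inconsistency_threshold=8.0)
        assert np.all(res.inconsistency == 0.0)
        assert np.all(res.kept)

    def test_too_few_shared_markers_errors(self, atlas):
        query = QueryCytometry(intensities=np.random.default_rng(0).normal(size=(5, 2)),
                               marker_names=["nope1", "nope2"])
        with pytest.raises(ValueError, match="shared markers"):
            project(query, atlas)

    def test_k_larger_than_atlas_errors(self, atlas):
        sub = atlas.subset_cells(np.arange(3))
        query = QueryCytometry(intensities=sub.expr.values,
                               marker_names=sub.expr.feature_names)
        with pytest.raises(ValueError, match="k must"):
            project(query, sub, k=4)
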