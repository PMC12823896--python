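"""Hashed embeddings, SVD projector fitting, projection and component selection."""

import numpy as np
import pytest
import scipy.linalg

import lingscreen as ls
from lingscreen.errors import ConfigError, DegenerateLabelsError, ShapeError


class TestHashedEmbedding:
    def test_identical_texts_identical_rows(self):
        E = ls.hashed_embedding(["a b c", "a b c", "x y"], dim=16, seed=0)
        assert np.array_equal(E.rows[0], E.rows[1])
        assert not np.array_equal(E.rows[0], E.rows[2])

    def test_deterministic_across_calls(self):
        a = ls.hashed_embedding(["one two", "three"], dim=8, seed=5).rows
        b = ls.hashed_embedding(["one two", "three"], dim=8, seed=5).rows
        assert np.array_equal(a, b)
        c = ls.hashed_embedding(["one two", "three"], dim=8, seed=6).rows
        assert not np.array_equal(a, c)

    def test_rows_unit_norm(self):
        E = ls.hashed_embedding(["hello world", "a", "b c d e"], dim=32, seed=1)
        norms = np.linalg.norm(E.rows, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_empty_text_gives_zero_row_with_warning(self):
        E = ls.hashed_embedding(["a b", ""], dim=8, seed=0)
        assert np.all(E.rows[1] == 0)
        assert any("empty" in w for w in E.warnings)

    def test_disjoint_vocabularies_cluster(self):
        group_a = ["apple banana cherry", "banana cherry apple", "cherry apple"]
        group_b = ["stone iron copper", "iron copper stone", "copper stone"]
        E = ls.hashed_embedding(group_a + group_b, dim=64, seed=3)
        cos = E.rows @ E.rows.T
        within = [cos[i, j] for g in (range(3), range(3, 6)) for i in g for j in g if i < j]
        between = [cos[i, j] for i in range(3) for j in range(3, 6)]
        assert np.mean(within) > np.mean(between)


class TestFitSvdProjector:
    E_DIAG = ls.EmbeddingMatrix(
        rows=np.array([[2.0, 0.0], [0.0, 1.0], [0.0, 0.0]]), ids=["a", "b", "c"]
    )

    def test_diagonal_case(self):
        proj = ls.fit_svd_projector(self.E_DIAG, k=2)
        assert np.allclose(proj.singular_values, [2.0, 1.0])
        assert np.allclose(proj.V[:, 0], [1.0, 0.0])
        assert np.allclose(proj.V[:, 1], [0.0, 1.0])

    def test_orthonormal_columns(self, rng):
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((12, 6)), ids=[str(i) for i in range(12)])
        proj = ls.fit_svd_projector(E, k=4)
        assert np.allclose(proj.V.T @ proj.V, np.eye(4), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        # independent route: right singular vectors are eigenvectors of E^T E
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((8, 5)), ids=[str(i) for i in range(8)])
        proj = ls.fit_svd_projector(E, k=5)
        evals, evecs = scipy.linalg.eigh(E.rows.T @ E.rows)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for j in range(5):
            assert np.allclose(evals[order][j], proj.singular_values[j] ** 2, atol=1e-8)
            got = E.rows @ proj.V[:, j]
            want = E.rows @ evecs[:, j]
            assert np.allclose(np.abs(got), np.abs(want), atol=1e-8)  # up to sign

    def test_sign_convention_largest_entry_positive(self, rng):
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((10, 4)), ids=[str(i) for i in range(10)])
        proj = ls.fit_svd_projector(E, k=4)
        for j in range(4):
            col = proj.V[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_row_order_invariance(self, rng):
        rows = rng.standard_normal((9, 5))
        ids = [str(i) for i in range(9)]
        proj1 = ls.fit_svd_projector(ls.EmbeddingMatrix(rows=rows, ids=ids), k=3)
        perm = rng.permutation(9)
        proj2 = ls.fit_svd_projector(
            ls.EmbeddingMatrix(rows=rows[perm], ids=[ids[i] for i in perm]), k=3
        )
        assert np.allclose(proj1.V, proj2.V, atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        rows = rng.standard_normal((7, 5))
        E = ls.EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(7)])
        proj = ls.fit_svd_projector(E, k=5)
        recon = (rows @ proj.V) @ proj.V.T
        assert np.linalg.norm(rows - recon) < 1e-6 * np.linalg.norm(rows)

    def test_k_out_of_range_is_config_error(self):
        with pytest.raises(ConfigError):
            ls.fit_svd_projector(self.E_DIAG, k=5)


class TestProjectComponent:
    def _proj(self):
        return ls.fit_svd_projector(TestFitSvdProjector.E_DIAG, k=2)

    def test_diagonal_fixture_projection(self):
        assert ls.project_component(np.array([3.0, 4.0]), self._proj(), 2) == pytest.approx(4.0)

    def test_orthogonal_embedding_projects_to_zero(self):
        assert ls.project_component(np.array([5.0, 0.0]), self._proj(), 2) == 0.0

    def test_linearity(self, rng):
        proj = self._proj()
        e = rng.standard_normal(2)
        assert ls.project_component(3.5 * e, proj, 1) == pytest.approx(
            3.5 * ls.project_component(e, proj, 1)
        )

    def test_dimension_mismatch_is_shape_error(self):
        with pytest.raises(ShapeError):
            ls.project_component(np.ones(3), self._proj(), 1)

    def test_default_component_is_projector_index(self):
        proj = self._proj()
        e = np.array([3.0, 4.0])
        assert ls.project_component(e, proj) == ls.project_component(e, proj, proj.component_index)


class TestSelectComponent:
    def test_single_component_returns_one(self, rng):
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((20, 4)), ids=[str(i) for i in range(20)])
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert ls.select_component(E, y, k=1) == 1

    def test_single_class_labels_rejected(self, rng):
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((10, 4)), ids=[str(i) for i in range(10)])
        with pytest.raises(DegenerateLabelsError):
            ls.select_component(E, np.ones(10, int), k=2)

    def test_signal_on_second_variance_axis_found(self, rng):
        # construct: axis 1 has high label-independent variance, axis 2 carries labels
        n = 60
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        style = rng.normal(0, 5.0, n)
        topic = (2 * y - 1) * 1.0 + rng.normal(0, 0.3, n)
        noise = rng.normal(0, 0.1, (n, 3))
        rows = np.column_stack([style, topic, noise])
        E = ls.EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(n)])
        assert ls.select_component(E, y, k=4) == 2

    def test_permuted_labels_have_low_correlation(self, rng):
        # with labels independent of E, no component correlates strongly at n=100
        n = 100
        rows = rng.standard_normal((n, 8))
        E = ls.EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(n)])
        proj = ls.fit_svd_projector(E, k=8)
        hits = 0
        for seed in range(10):
            y = np.random.default_rng(seed).permutation(np.r_[np.zeros(50, int), np.ones(50, int)])
            corrs = [
                abs(ls.point_biserial(ls.project_matrix(E, proj, j), y))
                for j in range(1, 9)
            ]
            hits += max(corrs) < 0.5
        assert hits >= 9


class TestOrientToLabels:
    def test_oriented_projection_correlates_positively(self, rng):
        n = 40
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        rows = rng.standard_normal((n, 6)) + np.outer(y, rng.standard_normal(6))
        E = ls.EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(n)])
        proj = ls.fit_svd_projector(E, k=4, component_index=1)
        oriented = ls.orient_to_labels(proj, E, y)
        corr = ls.point_biserial(ls.project_matrix(E, oriented), y)
        assert corr >= 0
        assert oriented.sign_convention == "label-oriented"


class TestProjectorSerialization:
    def test_json_round_trip_is_exact(self, rng):
        E = ls.EmbeddingMatrix(rows=rng.standard_normal((10, 4)), ids=[str(i) for i in range(10)])
        proj = ls.fit_svd_projector(E, k=3, backend_config={"dim": 4})
        restored = ls.SvdProjector.from_json(proj.to_json())
        assert np.array_equal(restored.V, proj.V)
        assert np.array_equal(restored.singular_values, proj.singular_values)
        assert restored.component_index == proj.component_index
        assert restored.config_hash() == proj.config_hash()
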