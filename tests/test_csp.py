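"""CSP derivation: normalized covariances, whitening, paired spectra, features."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import preictal as p
from preictal.csp import DegenerateInputError

from .conftest import random_spd_pair


class TestNormalizedCovariance:
    def test_identity_segment(self):
        cov = p.normalized_covariance(np.eye(2))
        assert np.allclose(cov.matrix, [[0.5, 0.0], [0.0, 0.5]])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        data=hnp.arrays(
            float, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2,
                                    max_side=12),
            elements=st.floats(min_value=-100, max_value=100),
        )
    )
    def test_unit_trace_and_symmetry(self, data):
        # ramp keeps every channel non-constant without hiding the property
        data = data + np.linspace(0.0, 1.0, data.shape[1])
        cov = p.normalized_covariance(data)
        assert np.isclose(np.trace(cov.matrix), 1.0)
        assert np.allclose(cov.matrix, cov.matrix.T)

    def test_zero_row_is_tolerated(self):
        d = np.array([[1.0, -1.0, 2.0], [0.0, 0.0, 0.0]])
        cov = p.normalized_covariance(d)
        assert cov.matrix[1, 1] == 0.0
        assert cov.matrix[0, 1] == 0.0

    def test_all_zero_segment_rejected(self):
        with pytest.raises(DegenerateInputError, match="zero"):
            p.normalized_covariance(np.zeros((3, 10)))

    def test_constant_nonzero_channel_rejected(self):
        d = np.vstack([np.ones(10), np.random.default_rng(0).normal(size=10)])
        with pytest.raises(DegenerateInputError, match="constant"):
            p.normalized_covariance(d)


class TestClassMean:
    def test_mean_of_identical_is_identity_operation(self):
        c = p.normalized_covariance(np.random.default_rng(1).normal(size=(3, 50)))
        mean = p.class_mean_covariance([c, c])
        assert np.allclose(mean.matrix, c.matrix)
        assert mean.n_epochs == 2

    def test_fixed_pair_hand_mean(self):
        a = p.Covariance(np.array([[0.6, 0.1], [0.1, 0.4]]))
        b = p.Covariance(np.array([[0.2, -0.1], [-0.1, 0.8]]))
        mean = p.class_mean_covariance([a, b])
        assert np.allclose(mean.matrix, [[0.4, 0.0], [0.0, 0.6]])

    def test_unit_trace_preserved(self):
        rng = np.random.default_rng(2)
        covs = [
            p.normalized_covariance(rng.normal(size=(4, 64))) for _ in range(7)
        ]
        assert np.isclose(np.trace(p.class_mean_covariance(covs).matrix), 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            p.class_mean_covariance([])


class TestFitCsp:
    def test_diagonal_complementary_pair(self):
        m = p.fit_csp(
            p.Covariance(np.diag([0.8, 0.2])), p.Covariance(np.diag([0.2, 0.8]))
        )
        assert np.allclose(m.lambda1, [0.8, 0.2])
        assert np.allclose(m.lambda2, [0.2, 0.8])
        assert np.allclose(m.lambda1 + m.lambda2, 1.0)

    def test_paired_eigenvalues_sum_to_one(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            dim = int(rng.integers(2, 17))
            c1, c2 = random_spd_pair(dim, rng)
            m = p.fit_csp(c1, c2)
            assert np.allclose(m.lambda1 + m.lambda2, 1.0, atol=1e-8)

    def test_matches_generalized_eigensolver(self):
        rng = np.random.default_rng(11)
        c1, c2 = random_spd_pair(4, rng)
        m = p.fit_csp(c1, c2)
        oracle = np.sort(
            scipy.linalg.eigh(
                c1.matrix, c1.matrix + c2.matrix, eigvals_only=True
            )
        )[::-1]
        assert np.allclose(m.lambda1, oracle, atol=1e-8)

    def test_whitening_identity(self):
        rng = np.random.default_rng(12)
        c1, c2 = random_spd_pair(6, rng)
        m = p.fit_csp(c1, c2)
        cc = c1.matrix + c2.matrix
        assert np.allclose(m.P @ cc @ m.P.T, np.eye(6), atol=1e-8)

    def test_whitened_classes_simultaneously_diagonalized(self):
        rng = np.random.default_rng(13)
        c1, c2 = random_spd_pair(5, rng)
        m = p.fit_csp(c1, c2)
        s1 = m.P @ c1.matrix @ m.P.T
        s2 = m.P @ c2.matrix @ m.P.T
        d1 = m.U.T @ s1 @ m.U
        d2 = m.U.T @ s2 @ m.U
        assert np.allclose(d1, np.diag(np.diag(d1)), atol=1e-8)
        assert np.allclose(d2, np.diag(np.diag(d2)), atol=1e-8)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        c1, c2 = random_spd_pair(5, rng)
        perm = rng.permutation(5)
        pm = np.eye(5)[perm]
        m = p.fit_csp(c1, c2)
        mp = p.fit_csp(
            p.Covariance(pm @ c1.matrix @ pm.T),
            p.Covariance(pm @ c2.matrix @ pm.T),
        )
        assert np.allclose(mp.lambda1, m.lambda1, atol=1e-8)
        assert np.allclose(np.abs(mp.W @ pm), np.abs(m.W), atol=1e-6)

    def test_first_filter_maximizes_variance_ratio(self):
        """The leading CSP filter attains the max generalized Rayleigh quotient."""
        rng = np.random.default_rng(15)
        c1, c2 = random_spd_pair(6, rng)
        m = p.fit_csp(c1, c2)
        w0 = m.W[0]
        ratio0 = (w0 @ c1.matrix @ w0) / (w0 @ (c1.matrix + c2.matrix) @ w0)
        best = scipy.linalg.eigh(
            c1.matrix, c1.matrix + c2.matrix, eigvals_only=True
        ).max()
        assert np.isclose(ratio0, best, atol=1e-8)
        for w in m.W[1:]:
            r = (w @ c1.matrix @ w) / (w @ (c1.matrix + c2.matrix) @ w)
            assert r <= ratio0 + 1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p.fit_csp(p.Covariance(np.eye(2) / 2), p.Covariance(np.eye(3) / 3))


class TestProjection:
    def test_identity_and_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 20))
        assert np.array_equal(p.project(x, np.eye(3)), x)
        perm = np.eye(3)[[2, 0, 1]]
        assert np.array_equal(p.project(x, perm), x[[2, 0, 1]])

    def test_fixed_product(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.array([[1.0, 1.0], [1.0, -1.0]])
        assert np.array_equal(p.project(x, w), [[4.0, 6.0], [-2.0, -2.0]])

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        c1, c2 = random_spd_pair(3, rng)
        m = p.fit_csp(c1, c2)
        with pytest.raises(ValueError, match="channels"):
            p.project(rng.normal(size=(4, 10)), m)


class TestLogVarianceFeatures:
    def test_unit_variance_gives_zero(self):
        row = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        row = row / row.std(ddof=1)
        feats = p.log_variance_features(np.vstack([row, 2 * row]))
        assert np.isclose(feats[0], 0.0)

    def test_length_matches_channel_count(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(23, 768))
        assert p.log_variance_features(x).shape == (23,)

    def test_row_scaling_shifts_by_two_log_c(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 100))
        f0 = p.log_variance_features(x)
        x2 = x.copy()
        x2[0] *= 3.0
        f1 = p.log_variance_features(x2)
        assert np.isclose(f1[0] - f0[0], 2 * np.log(3.0))
        assert np.isclose(f1[1], f0[1])

    def test_zero_variance_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            p.log_variance_features(np.vstack([np.ones(10), np.zeros(10) + 2]))
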