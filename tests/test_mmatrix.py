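"""Structured weights, the M-matrix reformulation, and <M> averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticawalk import (
    build_M,
    build_weights,
    center,
    covariances,
    expected_M,
    generate_random_walk,
    tica,
)
from ticawalk._linalg import abs_corr

from .conftest import align_signs, sampled_cosine, sampled_sine


class TestBuildWeights:
    def test_small_main_example(self):
        w = build_weights(5, 2, "main")
        A = w.A.toarray()
        expected_A = np.zeros((5, 5))
        for t in range(3):  # (1,3),(2,4),(3,5) in 1-based indexing
            expected_A[t, t + 2] = expected_A[t + 2, t] = 1.0
        np.testing.assert_array_equal(A, expected_A)
        np.testing.assert_array_equal(w.b_diag, [1, 1, 2, 1, 1])

    def test_small_alternative_example(self):
        w = build_weights(5, 2, "alternative")
        np.testing.assert_array_equal(w.A.toarray(), build_weights(5, 2, "main").A.toarray())
        np.testing.assert_array_equal(w.b_diag, [2, 2, 2, 2, 2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(4, 200), st.data())
    def test_counting_identity(self, n, data):
        tau = data.draw(st.integers(1, n - 2))
        w = build_weights(n, tau, "main")
        assert w.A.nnz == 2 * (n - tau)
        assert w.A.sum() == 2 * (n - tau)
        assert w.b_diag.sum() == 2 * (n - tau)

    @pytest.mark.parametrize("method", ["main", "alternative"])
    def test_quadratic_forms_match_covariances(self, method):
        traj = generate_random_walk(60, 4, seed=21)
        tau = 7
        w = build_weights(60, tau, method)
        X = traj.coords.T  # d x n
        pair = covariances(traj, tau, method)
        np.testing.assert_allclose(
            X @ w.A.toarray() @ X.T, 2 * (60 - tau) * pair.lagged, rtol=1e-8
        )
        if method == "main":
            np.testing.assert_allclose(
                X @ np.diag(w.b_diag) @ X.T, 2 * (60 - tau) * pair.instantaneous,
                rtol=1e-8,
            )
        else:
            np.testing.assert_allclose(
                X @ np.diag(w.b_diag) @ X.T, 2 * traj.coords.T @ traj.coords, rtol=1e-8
            )

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            build_weights(5, 4, "main")


class TestBuildM:
    @pytest.mark.parametrize("method", ["main", "alternative"])
    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_with_direct_tica(self, method, seed):
        """Nonzero eigenpairs of M reproduce the generalized-eigenproblem
        solution: same eigenvalues, same projections up to sign."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        d = int(rng.integers(2, 40))
        tau = int(rng.integers(1, max(2, n // 10)))
        traj = generate_random_walk(n, d, seed=seed + 1000)
        res = tica(traj, tau, method)
        md = build_M(traj, tau, method)
        m = res.eigenvalues.size
        np.testing.assert_allclose(
            md.generalized_eigenvalues[:m], res.eigenvalues, atol=1e-8
        )
        aligned = align_signs(md.eigenvectors[:, :m], res.projections)
        assert np.max(np.abs(aligned - res.projections)) < 1e-6

    def test_eigenpair_count_bounded(self):
        traj = generate_random_walk(200, 12, seed=5)
        md = build_M(traj, 4, "main")
        assert md.eigenvalues.size <= min(traj.d, traj.n - 1)

    def test_materialized_M_has_same_spectrum(self):
        traj = generate_random_walk(80, 6, seed=7)
        md = build_M(traj, 3, "main")
        dense = np.linalg.eigvals(md.materialize()).real
        dense = np.sort(dense[np.abs(dense) > 1e-8])[::-1]  # drop the null space
        np.testing.assert_allclose(dense, md.eigenvalues, atol=1e-8)

    def test_d_equals_n_approaches_binv_a_spectrum(self):
        """For d = n the nonzero spectrum of M matches that of B^-1 A (minus
        the constant-vector eigenvalue), up to a boundary effect of the
        centering null direction that vanishes with n."""
        from ticawalk import binv_a

        prev = None
        for n in (40, 100, 200):
            traj = generate_random_walk(n, n, seed=5)
            M = build_M(traj, 3, "main").materialize()
            em = np.sort(np.linalg.eigvals(M).real)
            w, V = np.linalg.eig(binv_a(n, 3, "main"))
            ones = np.ones(n) / np.sqrt(n)
            i_const = int(np.argmax(np.abs(V.conj().T @ ones)))
            assert w[i_const].real == pytest.approx(1.0, abs=1e-10)
            eb = np.sort(np.delete(w.real, i_const))
            em = np.delete(em, int(np.argmin(np.abs(em))))  # centering null mode
            gap = np.max(np.abs(em - eb))
            if prev is not None:
                assert gap < prev
            prev = gap
        assert prev < 1e-3

    def test_uncentered_rejected(self):
        from ticawalk import Trajectory

        traj = Trajectory(np.random.default_rng(0).normal(size=(40, 3)) + 4)
        with pytest.raises(ValueError, match="center"):
            build_M(traj, 2, "main")


class TestExpectedM:
    def test_linearity_over_seed_batches(self):
        """<M> over the union of two disjoint seed batches equals the
        sample-size-weighted mean of the batch averages, exactly."""
        from ticawalk.mmatrix import mean_P

        n, d, tau = 60, 5, 4
        seeds = list(range(10))
        Pa = mean_P(n, d, tau, "main", seeds[:4])
        Pb = mean_P(n, d, tau, "main", seeds[4:])
        Pall = mean_P(n, d, tau, "main", seeds)
        np.testing.assert_allclose(Pall, (4 * Pa + 6 * Pb) / 10, atol=1e-12)

    def test_deterministic_given_seed(self):
        a = expected_M(80, 6, 5, "main", n_samples=20, seed=3, keep_mean=False)
        b = expected_M(80, 6, 5, "main", n_samples=20, seed=3, keep_mean=False)
        np.testing.assert_array_equal(a.projections, b.projections)
        np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)

    def test_expected_projections_are_low_frequency_cosines(self):
        exp = expected_M(300, 20, 4, "main", n_samples=400, seed=2, k=3)
        assert abs_corr(exp.projections[:, 0], sampled_cosine(300, 1)) > 0.99
        assert abs_corr(exp.projections[:, 1], sampled_cosine(300, 2)) > 0.98
        assert np.all(np.diff(exp.eigenvalues) <= 1e-12)

    def test_alternative_gives_doubled_frequency_sines(self):
        exp = expected_M(300, 20, 4, "alternative", n_samples=400, seed=2, k=3)
        assert abs_corr(exp.projections[:, 0], sampled_sine(300, 2)) > 0.9

    def test_mean_M_agrees_with_averaged_dense_M(self):
        n, d, tau = 50, 4, 3
        exp = expected_M(n, d, tau, "main", n_samples=6, seed=9)
        from ticawalk.mmatrix import _walk_seeds

        Ms = []
        for s in _walk_seeds(9, 6):
            traj = generate_random_walk(n, d, s)
            Ms.append(build_M(traj, tau, "main").materialize())
        np.testing.assert_allclose(exp.mean_M, np.mean(Ms, axis=0), atol=1e-10)

    def test_eigenvectors_of_mean_match_mean_of_projections(self):
        """At small lag the <M> eigenvectors agree with the average of the
        individually sign-aligned per-walk projections."""
        from ticawalk.mmatrix import _walk_seeds

        n, d, tau, n_samples = 200, 15, 3, 300
        exp = expected_M(n, d, tau, "main", n_samples=n_samples, seed=4, k=2)
        acc = np.zeros((n, 2))
        for s in _walk_seeds(4, n_samples):
            traj = generate_random_walk(n, d, s)
            acc += build_M(traj, tau, "main").eigenvectors[:, :2]
        for k in range(2):
            assert abs_corr(exp.projections[:, k], acc[:, k]) > 0.95

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            expected_M(50, 4, 3, "main", n_samples=0, seed=0)
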