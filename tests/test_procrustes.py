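"""Orthogonal Procrustes alignment and diagnostics, checked against
independent geometric oracles (exhaustive 2x2 grid, rejection sampling,
deflation-based principal angles, scipy's subspace_angles)."""

import numpy as np
import pytest
from scipy import linalg

from gradalign import GradientSet, align_to_reference, apply_transform
from gradalign.procrustes import (ProcrustesAlignment, correspondence,
                                  fit_procrustes, principal_angles,
                                  subspace_similarity,
                                  transformation_magnitudes)
from conftest import random_orthonormal


def _gset(mat, evals=None):
    mat = np.asarray(mat, float)
    if evals is None:
        evals = np.linspace(1.0, 0.5, mat.shape[1])
    return GradientSet(components=mat, eigenvalues=evals)


def _residual(a, t, b):
    return np.linalg.norm(a @ t - b)


class TestFitProcrustes:
    def test_self_alignment_recovers_identity(self, rng):
        a = random_orthonormal(rng, 10, 4)
        res = fit_procrustes(a, a)
        assert np.allclose(res.transform, np.eye(4), atol=1e-10)
        assert _residual(a, res.transform, a) < 1e-10

    def test_sign_flip_recovery(self, rng):
        a = random_orthonormal(rng, 8, 2)
        b = a @ np.diag([1.0, -1.0])
        res = fit_procrustes(a, b)
        assert np.allclose(res.transform, np.diag([1.0, -1.0]), atol=1e-10)
        assert _residual(a, res.transform, b) < 1e-10

    def test_transform_is_orthogonal_and_svd_consistent(self, rng):
        for _ in range(20):
            a = rng.standard_normal((8, 3))
            b = rng.standard_normal((8, 3))
            res = fit_procrustes(a, b)
            t = res.transform
            assert np.allclose(t.T @ t, np.eye(3), atol=1e-8)
            assert np.allclose(t, res.u @ res.v.T, atol=1e-10)
            assert np.all(np.diff(res.singular_values) <= 1e-12)
            # C = (B'A)' identity from the construction
            assert np.allclose(res.cross_covariance, a.T @ b, atol=1e-12)

    def test_n2_matches_exhaustive_orthogonal_grid_oracle(self, rng):
        """For n=2 every orthogonal matrix is a rotation or a reflection;
        scan 100k angles of both families."""
        angles = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        cos, sin = np.cos(angles), np.sin(angles)
        rots = np.stack([np.stack([cos, -sin], -1),
                         np.stack([sin, cos], -1)], 1)      # (N, 2, 2)
        refl = rots.copy()
        refl[:, :, 1] *= -1                                  # det = -1 family
        candidates = np.concatenate([rots, refl])
        for _ in range(5):
            a = rng.standard_normal((8, 2))
            b = rng.standard_normal((8, 2))
            res = fit_procrustes(a, b)
            fitted = _residual(a, res.transform, b)
            grid_best = np.sqrt(
                ((np.einsum("mi,nij->nmj", a, candidates) - b) ** 2)
                .sum(axis=(1, 2))).min()
            assert fitted <= grid_best + 1e-6

    def test_beats_random_orthogonal_candidates(self, rng):
        n_candidates = 2000
        g = rng.standard_normal((n_candidates, 3, 3))
        qs = np.linalg.qr(g).Q
        for _ in range(20):
            a = rng.standard_normal((8, 3))
            b = rng.standard_normal((8, 3))
            res = fit_procrustes(a, b)
            fitted = _residual(a, res.transform, b)
            rand_best = np.sqrt(
                ((np.einsum("mi,nij->nmj", a, qs) - b) ** 2)
                .sum(axis=(1, 2))).min()
            assert fitted <= rand_best + 1e-12

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fit_procrustes(rng.standard_normal((5, 2)),
                           rng.standard_normal((5, 3)))


class TestApplyTransform:
    def test_identity_and_permutation(self, rng):
        a = _gset(rng.standard_normal((6, 3)))
        res = fit_procrustes(a, a)
        assert np.allclose(apply_transform(a, res).components, a.components,
                           atol=1e-8)
        perm = np.eye(3)[:, [2, 0, 1]]
        res.transform = perm
        out = apply_transform(a, res)
        assert np.allclose(out.components, a.components @ perm)
        assert out.params.get("aligned") is True

    def test_frobenius_norm_preserved(self, rng):
        a = rng.standard_normal((10, 4))
        b = rng.standard_normal((10, 4))
        res = fit_procrustes(a, b)
        assert np.linalg.norm(a @ res.transform) == pytest.approx(
            np.linalg.norm(a), abs=1e-8)


class TestDiagnostics:
    def test_correspondence_scalar_case(self, rng):
        a = rng.standard_normal((6, 1))
        res = fit_procrustes(a, -a)
        assert correspondence(res) == pytest.approx(1.0)

    def test_correspondence_printed_formula(self):
        res = fit_procrustes(np.eye(3), np.eye(3))
        res.transform = np.array([[0.9, 0, 0], [0.1, 0, 0], [0.0, 0, 0]])
        # direct arithmetic on max/sum of |first column|
        assert correspondence(res) == pytest.approx(0.9)
        res.transform = np.array([[0.5, 0.0], [0.5, 0.0]])
        assert correspondence(res) == pytest.approx(0.5)

    def test_correspondence_pigeonhole_bounds(self, rng):
        for _ in range(50):
            n = rng.integers(1, 6)
            a = rng.standard_normal((8, n))
            b = rng.standard_normal((8, n))
            c = correspondence(fit_procrustes(a, b))
            assert 1.0 / n - 1e-12 <= c <= 1.0 + 1e-12

    def test_magnitudes_identity_and_rotation(self, rng):
        res = fit_procrustes(np.eye(3), np.eye(3))
        assert transformation_magnitudes(res) == pytest.approx((3.0, 1.0))
        s2 = np.sqrt(2) / 2
        res.transform = np.array([[s2, -s2], [s2, s2]])
        tt, tp = transformation_magnitudes(res)
        assert tt == pytest.approx(4 * s2)
        assert tp == pytest.approx(2 * s2)

    def test_magnitudes_signed_permutation(self, rng):
        n = 4
        perm = np.eye(n)[rng.permutation(n)] * rng.choice([-1, 1], n)
        res = fit_procrustes(np.eye(n), np.eye(n))
        res.transform = perm
        tt, tp = transformation_magnitudes(res)
        assert tt == pytest.approx(n)
        assert tp == pytest.approx(1.0)


def _deflation_angles(a, b, seed=0):
    """Independent principal-angle oracle: alternating projections find the
    unit-vector pair of maximal cosine; the found directions are projected
    out of both spans and the search repeats."""
    rng = np.random.default_rng(seed)
    qa, _ = np.linalg.qr(np.asarray(a, float))
    qb, _ = np.linalg.qr(np.asarray(b, float))
    angles = []
    for _ in range(min(qa.shape[1], qb.shape[1])):
        x = qa @ rng.standard_normal(qa.shape[1])
        x /= np.linalg.norm(x)
        for _ in range(5000):
            y = qb @ (qb.T @ x)
            ny = np.linalg.norm(y)
            if ny < 1e-14:
                y = qb[:, 0]
                break
            y /= ny
            x_new = qa @ (qa.T @ y)
            x_new /= np.linalg.norm(x_new)
            if np.linalg.norm(x_new - x) < 1e-14:
                x = x_new
                break
            x = x_new
        cos = abs(np.clip(x @ y, -1.0, 1.0))
        angles.append(np.arccos(cos))
        # deflate both spans by the found directions (rank-revealing orth)
        qa = linalg.orth((np.eye(len(x)) - np.outer(x, x)) @ qa, rcond=1e-9)
        qb = linalg.orth((np.eye(len(y)) - np.outer(y, y)) @ qb, rcond=1e-9)
        if qa.size == 0 or qb.size == 0:
            break
    return np.sort(np.array(angles))


class TestSubspaceSimilarity:
    def test_identical_subspaces_zero_angles(self, rng):
        a = random_orthonormal(rng, 10, 3)
        w_norm, theta, theta_norm = subspace_similarity(a, a)
        assert theta_norm == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(theta, 0.0, atol=1e-7)
        assert w_norm == pytest.approx(np.sqrt(3), abs=1e-10)

    def test_orthogonal_subspaces_limit(self, rng):
        q = random_orthonormal(rng, 10, 6)
        a, b = q[:, :3], q[:, 3:]
        _w, theta, theta_norm = subspace_similarity(a, b)
        assert np.allclose(theta, np.pi / 2, atol=1e-8)
        assert theta_norm == pytest.approx((np.pi / 2) * np.sqrt(3), abs=1e-8)

    def test_matches_deflation_oracle(self, rng):
        a = rng.standard_normal((10, 3))
        b = rng.standard_normal((10, 3))
        theta = np.sort(principal_angles(a, b))
        oracle = _deflation_angles(a, b)
        assert np.allclose(theta, oracle, atol=1e-6)

    def test_matches_scipy_subspace_angles(self, rng):
        for _ in range(10):
            a = rng.standard_normal((10, 3))
            b = rng.standard_normal((10, 3))
            ours = np.sort(principal_angles(a, b))
            scipys = np.sort(linalg.subspace_angles(a, b))
            assert np.allclose(ours, scipys, atol=1e-8)

    def test_symmetry_and_basis_invariance(self, rng):
        a = rng.standard_normal((12, 3))
        b = rng.standard_normal((12, 3))
        t1 = subspace_similarity(a, b)[2]
        t2 = subspace_similarity(b, a)[2]
        assert t1 == pytest.approx(t2, abs=1e-9)
        # invertible recombination of columns spans the same subspace
        mix = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        t3 = subspace_similarity(a @ mix, b)[2]
        assert t1 == pytest.approx(t3, abs=1e-7)

    def test_rank_deficient_input_raises(self, rng):
        a = rng.standard_normal((8, 3))
        a[:, 2] = a[:, 0] + a[:, 1]
        with pytest.raises(ValueError, match="rank-deficient"):
            principal_angles(a, rng.standard_normal((8, 3)))


def _best_first_column_residual(a, b1, tol=1e-10):
    """min over unit t of ||A t - b1||: Lagrange bisection on
    (A'A + lam I) t = A'b1 with ||t|| = 1."""
    ata = a.T @ a
    atb = a.T @ b1
    evals = np.linalg.eigvalsh(ata)

    def norm_t(lam):
        return np.linalg.norm(np.linalg.solve(ata + lam * np.eye(len(atb)), atb))

    lo = -evals[0] + 1e-9
    hi = lo + 1.0
    while norm_t(hi) > 1:
        hi = lo + (hi - lo) * 10
    for _ in range(200):
        mid = (lo + hi) / 2
        if norm_t(mid) > 1:
            lo = mid
        else:
            hi = mid
    t = np.linalg.solve(ata + hi * np.eye(len(atb)), atb)
    t /= np.linalg.norm(t)
    return np.linalg.norm(a @ t - b1)


class TestAlignToReference:
    def test_single_component_diagnostics(self, rng):
        sub = _gset(rng.standard_normal((8, 3)))
        ref = _gset(rng.standard_normal((8, 3)))
        _al, _res, d = align_to_reference(sub, ref, 1)
        assert d.correspondence == pytest.approx(1.0)
        assert d.trans_total == pytest.approx(1.0)
        assert d.trans_pg == pytest.approx(1.0)

    def test_subject_equals_reference(self, rng):
        ref = _gset(random_orthonormal(rng, 8, 3))
        aligned, _res, d = align_to_reference(ref, ref, 3)
        assert np.allclose(aligned.components, ref.components, atol=1e-8)
        assert d.theta_norm == pytest.approx(0.0, abs=1e-6)

    def test_component_subset_selection(self, rng):
        sub = _gset(rng.standard_normal((8, 5)))
        ref = _gset(rng.standard_normal((8, 5)))
        aligned, res, d = align_to_reference(sub, ref, 2,
                                             component_indices=[4, 3, 2])
        assert d.n_align == 3
        assert aligned.components.shape == (8, 3)

    def test_n_align_exceeding_components_raises(self, rng):
        sub = _gset(rng.standard_normal((8, 3)))
        with pytest.raises(ValueError, match="exceed"):
            align_to_reference(sub, sub, 4)

    def test_monotone_capacity_of_principal_gradient_fit(self, rng):
        """Appending components to both sets can only improve the best
        achievable residual of the principal-gradient fit."""
        for _ in range(10):
            a = rng.standard_normal((10, 5))
            b1 = rng.standard_normal(10)
            residuals = [_best_first_column_residual(a[:, :n], b1)
                         for n in range(2, 6)]
            assert np.all(np.diff(residuals) <= 1e-8)


class TestProcrustesAlignmentEstimator:
    def test_fit_transform_and_diagnostics(self, rng):
        ref = random_orthonormal(rng, 10, 4)
        sub = random_orthonormal(rng, 10, 4)
        est = ProcrustesAlignment(n_align=3)
        out = est.fit(ref).transform(sub)
        assert out.shape == (10, 3)
        assert est.diagnostics_.n_align == 3
        assert 1 / 3 <= est.diagnostics_.correspondence <= 1
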