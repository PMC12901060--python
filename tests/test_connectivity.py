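"""Connectivity and motion-metric unit tests."""

import numpy as np
import pytest

from gradalign import (ConnectivityMatrix, MotionSeries, ParcelTimeSeries,
                       bold_fd_correlations, fisher_z, framewise_displacement,
                       group_mean_fc, inverse_fisher_z, ks_compare, pearson_fc,
                       tfc)

# 3-parcel, 5-frame toy series; FC frozen from a direct covariance /
# standard-deviation computation
TOY_TS = np.array([[1.0, 2.0, 0.5],
                   [2.0, 1.5, 1.0],
                   [3.0, 3.5, 0.0],
                   [4.0, 2.0, 2.0],
                   [5.0, 4.0, 1.5]])
TOY_FC = np.array([[1.0, 0.65639246, 0.6],
                   [0.65639246, 1.0, -0.14586499],
                   [0.6, -0.14586499, 1.0]])


class TestPearsonFC:
    def test_matches_hand_computed_covariance_oracle(self):
        fc = pearson_fc(ParcelTimeSeries(TOY_TS))
        assert np.allclose(fc.values, TOY_FC, atol=1e-8)

    def test_identical_and_negated_columns(self, rng):
        base = rng.standard_normal(20)
        ts = ParcelTimeSeries(np.column_stack([base, base, -base]))
        fc = pearson_fc(ts)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(fc.values), 1.0)

    def test_zero_variance_parcel_named_in_error(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 7.0
        ts = ParcelTimeSeries(x, parcel_labels=["a", "bad_parcel", "c"])
        with pytest.raises(ValueError, match="bad_parcel"):
            pearson_fc(ts)

    def test_invariant_to_affine_rescaling(self, rng):
        x = rng.standard_normal((30, 5))
        scaled = x * np.array([1.0, 2.5, 10.0, 0.3, 7.0]) + np.arange(5)
        a = pearson_fc(ParcelTimeSeries(x)).values
        b = pearson_fc(ParcelTimeSeries(scaled)).values
        assert np.allclose(a, b, atol=1e-10)


class TestFisherZ:
    def test_fixed_point_and_roundtrip(self):
        assert fisher_z(0.0) == 0.0
        assert inverse_fisher_z(fisher_z(0.5)) == pytest.approx(0.5, abs=1e-12)

    def test_against_high_precision_atanh(self):
        # mpmath 30-digit evaluation of atanh(0.9)
        assert fisher_z(0.9) == pytest.approx(1.47221948958322023, abs=1e-14)

    def test_clips_at_unit_correlation(self, caplog):
        with caplog.at_level("WARNING"):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))


class TestGroupMeanFC:
    def _fc(self, val):
        m = np.full((3, 3), val, dtype=float)
        np.fill_diagonal(m, 1.0)
        return ConnectivityMatrix(m)

    def test_idempotent_on_identical_inputs(self):
        fc = self._fc(0.4)
        out = group_mean_fc([fc] * 5)
        assert np.allclose(out.values, fc.values, atol=1e-12)

    def test_odd_symmetry(self):
        out = group_mean_fc([self._fc(0.5), self._fc(-0.5)])
        assert out.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_z_space_mean_differs_from_arithmetic(self):
        # mpmath: tanh((atanh 0.3 + atanh 0.8) / 2) = 0.6069422537725751
        out = group_mean_fc([self._fc(0.3), self._fc(0.8)])
        assert out.values[0, 1] == pytest.approx(0.6069422537725751, abs=1e-12)
        assert out.values[0, 1] != pytest.approx(0.55, abs=1e-3)

    def test_order_invariance_and_dim_mismatch(self, rng):
        mats = []
        for _ in range(4):
            x = rng.standard_normal((30, 3))
            mats.append(pearson_fc(ParcelTimeSeries(x)))
        a = group_mean_fc(mats).values
        b = group_mean_fc(mats[::-1]).values
        assert np.allclose(a, b, atol=1e-12)
        bad = ConnectivityMatrix(np.eye(4))
        with pytest.raises(ValueError, match="mismatch"):
            group_mean_fc([mats[0], bad])


class TestFramewiseDisplacement:
    @staticmethod
    def _motion(trans, rot):
        return MotionSeries(translations=np.asarray(trans, float),
                            rotations=np.asarray(rot, float))

    def test_no_motion_gives_zero(self):
        m = self._motion(np.ones((5, 3)), np.full((5, 3), 0.2))
        fd = framewise_displacement(m)
        assert np.all(fd.fd_series == 0)
        assert fd.mean_fd == 0

    @pytest.mark.parametrize("column,step,expected", [
        (0, 1.0, 1.0),      # 1 mm translation step
        (3, 0.02, 1.0),     # 0.02 rad rotation at 50 mm radius
    ])
    def test_single_parameter_step(self, column, step, expected):
        trans = np.zeros((4, 3))
        rot = np.zeros((4, 3))
        (trans if column < 3 else rot)[2:, column % 3] = step
        fd = framewise_displacement(self._motion(trans, rot))
        assert fd.fd_series[2] == pytest.approx(expected)
        assert fd.fd_series[0] == 0
        assert fd.fd_series[1] == 0
        assert fd.fd_series[3] == 0

    def test_translation_invariance(self, rng):
        trans = rng.standard_normal((20, 3))
        rot = rng.standard_normal((20, 3)) * 0.01
        fd1 = framewise_displacement(self._motion(trans, rot)).fd_series
        fd2 = framewise_displacement(
            self._motion(trans + 5.0, rot + 0.3)).fd_series
        assert np.allclose(fd1, fd2, atol=1e-12)

    def test_requires_parameters(self):
        m = MotionSeries(fd_series=np.array([0.0, 0.1, 0.2]))
        with pytest.raises(ValueError, match="rigid-body"):
            framewise_displacement(m)

    def test_mean_fd_excludes_first_frame(self):
        m = MotionSeries(fd_series=np.array([0.0, 0.2, 0.4]))
        assert m.mean_fd == pytest.approx(0.3)


class TestTFC:
    A = ConnectivityMatrix(np.array([[1, .2, .4, -.1], [.2, 1, .3, .5],
                                     [.4, .3, 1, .0], [-.1, .5, .0, 1.]]))
    B = ConnectivityMatrix(np.array([[1, .1, .5, .2], [.1, 1, .2, .4],
                                     [.5, .2, 1, -.3], [.2, .4, -.3, 1.]]))

    def test_self_typicality_is_one(self):
        assert tfc(self.A, self.A) == pytest.approx(1.0)

    def test_negated_triangle_gives_zero(self):
        neg = -self.A.values
        np.fill_diagonal(neg, 1.0)
        assert tfc(ConnectivityMatrix(neg), self.A) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_matches_hand_computed_r(self):
        # frozen: r over the 6 upper-triangle pairs = 0.6866900307692713
        assert tfc(self.A, self.B) == pytest.approx(0.8433450153846356, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.standard_normal((20, 6))
            y = rng.standard_normal((20, 6))
            val = tfc(pearson_fc(ParcelTimeSeries(x)),
                      pearson_fc(ParcelTimeSeries(y)))
            assert 0.0 <= val <= 1.0


class TestBoldFDCorrelations:
    def test_parcel_equal_to_fd_correlates_perfectly(self, rng):
        t = 50
        fd = np.concatenate([[0.0], np.abs(rng.standard_normal(t - 1))])
        x = rng.standard_normal((t, 3))
        x[1:, 1] = fd[1:]
        r = bold_fd_correlations(ParcelTimeSeries(x),
                                 MotionSeries(fd_series=fd))
        assert r[1] == pytest.approx(1.0)

    def test_constant_fd_raises(self, rng):
        fd = np.zeros(20)
        with pytest.raises(ValueError, match="constant FD"):
            bold_fd_correlations(ParcelTimeSeries(rng.standard_normal((20, 3))),
                                 MotionSeries(fd_series=fd))

    def test_null_distribution_sd_matches_fisher_theory(self, rng):
        # independent series: pooled r has sd ~ 1/sqrt(T-3)
        t, p = 300, 200
        x = rng.standard_normal((t, p))
        fd = np.concatenate([[0.0], np.abs(rng.standard_normal(t - 1))])
        r = bold_fd_correlations(ParcelTimeSeries(x),
                                 MotionSeries(fd_series=fd))
        expected_sd = 1.0 / np.sqrt(t - 1 - 3)  # first frame dropped
        assert np.std(r) == pytest.approx(expected_sd, rel=0.25)
        assert abs(np.mean(r)) < 4 * expected_sd / np.sqrt(p)

    def test_constant_parcel_flagged_nan(self, rng):
        t = 30
        x = rng.standard_normal((t, 3))
        x[1:, 2] = 3.14
        fd = np.concatenate([[0.0], np.abs(rng.standard_normal(t - 1))])
        r = bold_fd_correlations(ParcelTimeSeries(x),
                                 MotionSeries(fd_series=fd))
        assert np.isnan(r[2]) and np.isfinite(r[:2]).all()


def _ecdf_gap(a, b):
    """Brute-force maximum ECDF gap over all sample points."""
    pts = np.concatenate([a, b])
    return max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts)


class TestKSCompare:
    def test_identical_samples_give_zero(self, rng):
        s = rng.standard_normal(30)
        d, _ = ks_compare(s, s)
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        d, _ = ks_compare([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == pytest.approx(1.0)

    def test_matches_ecdf_scan_oracle(self):
        a = [0.12, -0.4, 0.33, 0.5, -0.1, 0.05, 0.61, -0.25, 0.18, 0.44]
        b = [0.52, 0.13, -0.3, 0.72, 0.41, 0.09, 0.35, 0.6, -0.05, 0.2]
        d, p = ks_compare(a, b)
        assert d == pytest.approx(_ecdf_gap(np.array(a), np.array(b)), abs=1e-12)
        assert 0 <= p <= 1

    def test_fisher_transform_preserves_d(self, rng):
        # the r-to-z map is strictly monotone, so D is unchanged
        a = rng.uniform(-0.8, 0.8, 40)
        b = rng.uniform(-0.5, 0.9, 35)
        d_raw, _ = ks_compare(a, b, fisher_transform=False)
        d_z, _ = ks_compare(a, b, fisher_transform=True)
        assert d_raw == pytest.approx(d_z, abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_compare([], [1.0])
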