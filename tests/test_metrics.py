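"""FD, DVARS, outlier rules and motion-R²: hand oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mocolab.containers import Bold4D, DataError, FDSeries, NumericalError, OutlierMask
from mocolab.metrics import (
    detect_outliers_dvars,
    detect_outliers_fd,
    dvars,
    framewise_displacement,
    mean_fd_variants,
    motion_variance_explained,
)


def brute_force_fd(params, radius=50.0):
    out = [0.0]
    for i in range(1, len(params)):
        s = 0.0
        for j in range(3):
            s += abs(params[i - 1][j] - params[i][j])
        for j in range(3, 6):
            s += radius * abs(params[i - 1][j] - params[i][j])
        out.append(s)
    return np.array(out)


class TestFramewiseDisplacement:
    def test_constant_trace_gives_zero(self):
        fd = framewise_displacement(np.ones((10, 6)) * 0.3)
        assert not fd.values.any()

    def test_single_translation_step(self):
        p = np.zeros((10, 6))
        p[5:, 0] = 0.1  # +0.1 mm in x from frame 5 on
        fd = framewise_displacement(p)
        expected = np.zeros(10)
        expected[5] = 0.1
        np.testing.assert_allclose(fd.values, expected, atol=1e-15)

    def test_rotation_arc_conversion(self):
        p = np.zeros((10, 6))
        p[5:, 3] = 0.002  # +2 mrad pitch; 50 mm radius → 0.1 mm arc
        fd = framewise_displacement(p, rotation_radius=50.0)
        assert fd.values[5] == pytest.approx(0.1, rel=1e-12)
        assert fd.values[6] == 0.0

    def test_matches_brute_force(self, rng):
        p = rng.normal(size=(50, 6)) * [1, 1, 1, 0.01, 0.01, 0.01]
        fd = framewise_displacement(p)
        np.testing.assert_allclose(fd.values, brute_force_fd(p), rtol=1e-12)

    def test_invariant_to_constant_offset(self, rng):
        p = rng.normal(size=(30, 6))
        shifted = p + rng.normal(size=6)
        np.testing.assert_allclose(
            framewise_displacement(p).values,
            framewise_displacement(shifted).values, rtol=1e-9, atol=1e-12)

    def test_scales_linearly(self, rng):
        p = rng.normal(size=(30, 6))
        np.testing.assert_allclose(
            framewise_displacement(3.0 * p).values,
            3.0 * framewise_displacement(p).values, rtol=1e-12)

    def test_nonfinite_rejected(self):
        p = np.zeros((5, 6))
        p[2, 1] = np.nan
        with pytest.raises(DataError):
            framewise_displacement(p)


class TestMeanFDVariants:
    def test_worked_example(self):
        fd = FDSeries(values=np.array([0.0, 0.1, 0.9, 0.1]))
        mask = OutlierMask(flags=np.array([0, 0, 1, 0], bool), metric="fd", threshold=0.5)
        mean, prime, dp = mean_fd_variants(fd, mask)
        assert mean == pytest.approx(0.275)
        assert prime == pytest.approx(0.2 / 3)
        assert dp == pytest.approx(0.9)

    def test_empty_spike_set(self):
        fd = FDSeries(values=np.array([0.0, 0.2, 0.3]))
        mask = OutlierMask(flags=np.zeros(3, bool), metric="fd", threshold=0.5)
        mean, prime, dp = mean_fd_variants(fd, mask)
        assert prime == mean
        assert dp is None

    def test_full_spike_set(self):
        fd = FDSeries(values=np.array([0.0, 0.2, 0.3]))
        mask = OutlierMask(flags=np.ones(3, bool), metric="fd", threshold=0.0001)
        mean, prime, dp = mean_fd_variants(fd, mask)
        assert dp == mean
        assert prime is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 5), min_size=2, max_size=40), st.data())
    def test_mean_between_subset_means(self, values, data):
        """meanFD lies between meanFD' and meanFD'' when both exist."""
        flags = np.array(
            [data.draw(st.booleans()) for _ in values], dtype=bool)
        fd = FDSeries(values=np.array(values))
        mask = OutlierMask(flags=flags, metric="fd", threshold=0.5)
        mean, prime, dp = mean_fd_variants(fd, mask)
        if prime is not None and dp is not None:
            lo, hi = min(prime, dp), max(prime, dp)
            assert lo - 1e-12 <= mean <= hi + 1e-12


class TestFDOutliers:
    def test_strict_inequality_at_threshold(self):
        fd = FDSeries(values=np.array([0.0, 0.6, 0.5, 0.51, 0.2]))
        mask = detect_outliers_fd(fd, threshold=0.5)
        assert list(mask.indices) == [1, 3]

    def test_no_flags_below_threshold(self):
        fd = FDSeries(values=np.full(10, 0.4))
        assert detect_outliers_fd(fd).n_outliers == 0


def _bold_from_matrix(ts):
    """(n_voxels, T) matrix -> Bold4D of shape (n,1,1,T) with full mask."""
    arr = np.asarray(ts, float)[:, np.newaxis, np.newaxis, :]
    return Bold4D(data=arr, mask=np.ones(arr.shape[:3], bool))


class TestDvars:
    def test_two_voxel_hand_example(self):
        """Volumes (1,1) then (3,1): raw RMS difference is sqrt((4+0)/2)."""
        bold = _bold_from_matrix([[1.0, 3.0], [1.0, 1.0]])
        dv = dvars(bold)
        scale = np.median([2.0, 1.0])  # per-voxel temporal means
        assert dv.values[1] * scale / 100.0 == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert dv.values[0] == 0.0

    def test_identical_volumes_give_zero(self):
        bold = _bold_from_matrix([[2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        assert not dvars(bold).values.any()

    def test_global_shift_peaks_once(self, rng):
        ts = np.full((20, 10), 100.0)
        ts[:, 4:] *= 1.01  # +1% step at volume 4
        dv = dvars(_bold_from_matrix(ts))
        assert np.argmax(dv.values) == 4
        assert np.count_nonzero(dv.values > 1e-12) == 1

    def test_raw_value_invariant_to_additive_offset(self, rng):
        ts = rng.normal(100, 5, size=(30, 12))
        a, b = dvars(_bold_from_matrix(ts)), dvars(_bold_from_matrix(ts + 37.0))
        med = lambda x: np.median(x.mean(axis=1))
        np.testing.assert_allclose(a.values * med(ts), b.values * med(ts + 37.0),
                                   rtol=1e-10)

    def test_normalized_value_invariant_to_scaling(self, rng):
        ts = rng.normal(100, 5, size=(30, 12))
        a, b = dvars(_bold_from_matrix(ts)), dvars(_bold_from_matrix(ts * 4.0))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_matches_brute_force(self, rng):
        ts = rng.normal(100, 5, size=(25, 9))
        dv = dvars(_bold_from_matrix(ts))
        for i in range(1, 9):
            raw = np.sqrt(np.mean([(ts[v, i] - ts[v, i - 1]) ** 2
                                   for v in range(25)]))
            expected = raw / np.median(ts.mean(axis=1)) * 100
            assert dv.values[i] == pytest.approx(expected, rel=1e-10)

    def test_empty_mask_rejected(self):
        bold = Bold4D(data=np.ones((2, 2, 2, 3)), mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(DataError):
            dvars(bold)


class TestDvarsOutliers:
    def test_degenerate_constant_series_unflagged(self):
        dv_vals = np.full(10, 1.3)
        from mocolab.containers import DvarsSeries

        mask = detect_outliers_dvars(DvarsSeries(values=dv_vals))
        assert mask.n_outliers == 0  # IQR 0, strict inequality

    def test_single_extreme_frame(self):
        from mocolab.containers import DvarsSeries

        dv = DvarsSeries(values=np.array([1.0] * 7 + [10.0]))
        mask = detect_outliers_dvars(dv)
        assert list(mask.indices) == [7]
        # brute-force boxplot threshold with linear-interpolation percentiles
        p75, p25 = np.percentile(dv.values, [75, 25])
        assert mask.threshold == pytest.approx(p75 + 1.5 * (p75 - p25))

    def test_too_short_series_rejected(self):
        from mocolab.containers import DvarsSeries

        with pytest.raises(DataError):
            detect_outliers_dvars(DvarsSeries(values=np.array([1.0, 2.0])))


def brute_force_r2adj(b, x, adjusted=True):
    """Normal-equations oracle for the motion-explained-variance statistic."""
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(design.T @ design, design.T @ b)
    resid = b - design @ beta
    ss_res = resid @ resid
    ss_tot = ((b - b.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    if not adjusted:
        return r2
    return 1 - (n - 1) / (n - p - 1) * (ss_res / ss_tot)


class TestMotionVarianceExplained:
    def test_signal_in_span_gives_one(self, rng):
        x = rng.normal(size=(40, 4))
        b = x @ rng.normal(size=4) + 2.5
        assert motion_variance_explained(b, x) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_regressors_give_known_negative_value(self, rng):
        """SS_res equals SS_tot when regressors explain nothing, so the
        adjusted value is 1 - 99/93 for N=100, P=6."""
        n = 100
        b = rng.normal(size=n)
        b -= b.mean()
        x = rng.normal(size=(n, 6))
        # orthogonalize columns against the demeaned signal
        x -= x.mean(axis=0)
        x -= np.outer(b, b @ x) / (b @ b)
        r2 = motion_variance_explained(b + 5.0, x)
        assert r2 == pytest.approx(1 - 99 / 93, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(50, 3))
            b = rng.normal(size=50) + 0.3 * x[:, 0]
            assert motion_variance_explained(b, x) == pytest.approx(
                brute_force_r2adj(b, x), rel=1e-10)
            assert motion_variance_explained(b, x, adjusted=False) == pytest.approx(
                brute_force_r2adj(b, x, adjusted=False), rel=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=(30, 3))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(NumericalError, match="collinear"):
            motion_variance_explained(rng.normal(size=30), x,
                                      labels=["a", "b", "c", "dup"])

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(DataError):
            motion_variance_explained(rng.normal(size=5), rng.normal(size=(5, 6)))

    def test_unadjusted_monotone_under_nesting(self, rng):
        """Plain R² cannot decrease when columns are added."""
        for _ in range(5):
            x = rng.normal(size=(60, 8))
            b = rng.normal(size=60) + x[:, :2] @ [0.5, -0.3]
            r_small = motion_variance_explained(b, x[:, :4], adjusted=False)
            r_big = motion_variance_explained(b, x, adjusted=False)
            assert r_big >= r_small - 1e-12
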