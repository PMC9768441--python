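"""HRF, design construction, filtering, voxelwise fit, Z maps, thresholding."""

import numpy as np
import pytest
from scipy import stats

from mocolab.containers import Bold4D, DataError, PhantomSpec, StatMap, TaskDesign
from mocolab.glm import (
    build_design,
    canonical_hrf,
    contrast_zmap,
    dct_drift_basis,
    fit_glm,
    highpass,
    percent_signal_change,
    smooth,
    t_to_z,
    threshold_map,
)
from mocolab.synthetic import default_localizer_roi, generate_phantom, make_task_design


class TestCanonicalHRF:
    def test_peak_location(self):
        h = canonical_hrf(0.1)
        assert 4.0 <= np.argmax(h) * 0.1 <= 6.0

    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(1.0)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_undershoot_window_and_positive_sum(self):
        h = canonical_hrf(0.1)
        t_min = np.argmin(h) * 0.1
        assert 10.0 <= t_min <= 20.0
        assert 0 < h.sum() < np.inf

    def test_agrees_with_independent_double_gamma(self):
        """Cross-check against nilearn's canonical double-gamma (spm_hrf)."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(0.1)
        theirs = nilearn_hrf.spm_hrf(1.0, oversampling=10, time_length=32)
        n = min(ours.size, theirs.size)
        r = np.corrcoef(ours[:n], theirs[:n])[0, 1]
        assert r > 0.999


class TestBuildDesign:
    def test_localizer_has_two_task_columns(self):
        d = build_design(make_task_design("localizer"), hp_cutoff=24)
        assert d.roles.count("task") == 2
        assert d.roles.count("intercept") == 1

    def test_bm_has_three_task_columns(self):
        d = build_design(make_task_design("bm_a"), hp_cutoff=80)
        assert d.roles.count("task") == 3

    def test_drift_column_count_closed_form(self):
        d = build_design(make_task_design("localizer"), hp_cutoff=24)
        assert d.roles.count("drift") == int(2 * 192 * 1.0 / 24)  # 16

    def test_empty_condition_warns_and_keeps_zero_column(self):
        design = TaskDesign(conditions=["a", "b"], events=[("a", 5.0, 5.0)],
                            run_length=40, tr=1.0)
        with pytest.warns(UserWarning, match="no events"):
            d = build_design(design, hp_cutoff=None)
        col = d.matrix[:, d.column_index("b")]
        assert not col.any()

    def test_task_columns_are_convolved_boxcars(self):
        d = build_design(make_task_design("localizer"), hp_cutoff=None)
        col = d.matrix[:, d.column_index("moving")]
        assert col[:12].max() == 0.0  # nothing before the first event responds
        assert col.max() > 0


class TestSmoothing:
    def test_zero_fwhm_identity(self, small_phantom):
        bold, _, _ = small_phantom
        out = smooth(bold, fwhm=0.0)
        np.testing.assert_array_equal(out.data, bold.data)

    def test_delta_half_maximum_at_expected_radius(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        bold = Bold4D(data=data, voxel_size=(2.0, 2.0, 2.0))
        out = smooth(bold, fwhm=4.7)
        prof = out.data[:, 10, 10, 0]
        half = prof[10] / 2
        # half-maximum at ±2.35 mm ≈ ±1.17 voxels: between voxel 1 and 2 away
        assert prof[9] > half > prof[8]

    def test_interior_mass_conserved(self):
        data = np.zeros((25, 25, 25, 1))
        data[12, 12, 12, 0] = 1.0
        bold = Bold4D(data=data, voxel_size=(2.0, 2.0, 2.0))
        out = smooth(bold, fwhm=3.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-3)


class TestHighpass:
    def _sine_bold(self, period, t=192, phase=0.0):
        x = np.sin(2 * np.pi * np.arange(t) / period + phase)
        return Bold4D(data=x[np.newaxis, np.newaxis, np.newaxis, :], tr=1.0)

    @staticmethod
    def _rms(bold):
        return float(np.sqrt(np.mean(bold.data**2)))

    def test_slow_oscillation_removed(self):
        """A 96 s drift at a 24 s cutoff loses >95% of its RMS amplitude at
        every phase relative to the DCT span."""
        for phase in np.linspace(0, 2 * np.pi, 9):
            bold = self._sine_bold(96.0, phase=phase)
            out = highpass(bold, cutoff=24.0)
            assert self._rms(out) < 0.05 * self._rms(bold)

    def test_fast_oscillation_preserved(self):
        bold = self._sine_bold(12.0)
        out = highpass(bold, cutoff=24.0)
        assert self._rms(out) > 0.95 * self._rms(bold)

    def test_constant_series_unchanged(self):
        bold = Bold4D(data=np.full((2, 2, 2, 50), 7.0), tr=1.0)
        np.testing.assert_allclose(highpass(bold, 24.0).data, bold.data, atol=1e-10)

    def test_cutoff_must_exceed_nyquist_period(self):
        with pytest.raises(DataError):
            dct_drift_basis(100, 1.0, 1.5)


class TestFitGLM:
    def test_matches_normal_equations_oracle(self, rng):
        t, k = 60, 4
        x = np.column_stack([rng.normal(size=(t, k - 1)), np.ones(t)])
        design = build_design(
            TaskDesign(conditions=[], events=[], run_length=t, tr=1.0),
            hp_cutoff=None)
        # overwrite with a random full design, keeping the intercept label
        design.matrix = x
        design.labels = [f"c{i}" for i in range(k - 1)] + ["intercept"]
        design.roles = ["task"] * (k - 1) + ["intercept"]
        y = rng.normal(size=(10, t))
        bold = Bold4D(data=y[:, np.newaxis, np.newaxis, :])
        fit = fit_glm(bold, design)
        beta_oracle = np.linalg.solve(x.T @ x, x.T @ y.T)
        np.testing.assert_allclose(fit.beta[:, 0, 0, :], beta_oracle.T, atol=1e-8)
        assert fit.dof == t - k

    def test_recovers_injected_amplitude(self, block_design):
        spec = PhantomSpec(shape=(14, 14, 14), n_volumes=80, noise_sd_pct=0.2,
                           activation_rois=[default_localizer_roi((14, 14, 14))],
                           seed=9)
        bold, truth = generate_phantom(spec, block_design)
        # hp drift columns model the phantom's slow scanner drift
        fit = fit_glm(bold, build_design(block_design, hp_cutoff=24))
        psc = percent_signal_change(fit, "moving")
        roi = truth["moving"] > 0
        assert psc[roi].mean() == pytest.approx(2.0, rel=0.1)

    def test_null_betas_center_on_zero(self, block_design):
        spec = PhantomSpec(shape=(14, 14, 14), n_volumes=80, drift_amplitude_pct=0,
                           seed=10)
        bold, _ = generate_phantom(spec, block_design)
        fit = fit_glm(bold, build_design(block_design, hp_cutoff=None))
        k = fit.design.column_index("moving")
        betas = fit.beta[..., k][bold.mask]
        assert abs(betas.mean()) < 3 * betas.std() / np.sqrt(betas.size)


class TestContrastZmap:
    def test_t_zero_maps_to_z_zero(self):
        assert t_to_z(np.array([0.0]), 20)[0] == 0.0

    def test_large_dof_limit(self):
        z = t_to_z(np.array([1.96]), 10**6)[0]
        assert z == pytest.approx(1.96, abs=1e-3)

    def test_probit_matching_against_cdf_oracle(self):
        t_val, dof = 2.5, 30
        expected = stats.norm.ppf(stats.t.cdf(t_val, dof))
        assert t_to_z(np.array([t_val]), dof)[0] == pytest.approx(expected, rel=1e-10)
        assert t_to_z(np.array([-t_val]), dof)[0] == pytest.approx(-expected, rel=1e-10)

    def test_extreme_t_clipped_finite(self):
        z = t_to_z(np.array([1e6, -1e6]), 100)
        assert np.isfinite(z).all()
        assert z[0] <= 38.0 and z[1] >= -38.0


class TestThresholdMap:
    def _null_map(self, rng, n=16):
        z = rng.standard_normal((n, n, n))
        mask = np.ones((n, n, n), bool)
        return StatMap(z=z, contrast=np.array([1.0]), dof=100, mask=mask)

    def test_bonferroni_familywise_error_rate(self, rng):
        """Over 200 simulated null Z maps, the fraction with any surviving
        voxel stays at or below the nominal 5% (Bonferroni guarantee)."""
        hits = 0
        for _ in range(200):
            thr = threshold_map(self._null_map(rng), voxel_alpha=0.05, cluster_min=1)
            hits += bool(thr.clusters)
        assert hits / 200 <= 0.05 + 0.03  # binomial slack at n=200

    def test_true_activation_cluster_survives(self, block_design):
        spec = PhantomSpec(shape=(14, 14, 14), n_volumes=80, noise_sd_pct=0.5,
                           activation_rois=[default_localizer_roi((14, 14, 14))],
                           seed=11)
        bold, truth = generate_phantom(spec, block_design)
        fit = fit_glm(bold, build_design(block_design, hp_cutoff=None))
        zmap = contrast_zmap(fit, {"moving": 1.0})
        thr = threshold_map(zmap, voxel_alpha=0.05, cluster_min=2)
        assert thr.clusters
        roi_center = np.array(default_localizer_roi((14, 14, 14)).center)
        assert any((c.voxels == roi_center).all(axis=1).any() for c in thr.clusters)

    def test_all_zero_map_has_no_clusters(self):
        m = StatMap(z=np.zeros((8, 8, 8)), contrast=np.array([1.0]), dof=50,
                    mask=np.ones((8, 8, 8), bool))
        assert not threshold_map(m).clusters

    def test_thresholding_preserves_z_and_partitions_suprathreshold(self, rng):
        m = self._null_map(rng)
        thr = threshold_map(m, voxel_alpha=0.99, cluster_min=1)
        np.testing.assert_array_equal(thr.z, m.z)
        supra = np.argwhere((m.z > thr.voxel_threshold) & m.mask)
        union = thr.surviving_voxels
        assert len(union) == len(supra)
        assert {tuple(v) for v in union} == {tuple(v) for v in supra}

    def test_rethresholding_rejected(self, rng):
        thr = threshold_map(self._null_map(rng))
        with pytest.raises(DataError):
            threshold_map(thr)

    def test_cluster_ordering(self):
        z = np.zeros((10, 10, 10))
        z[1, 1, 1] = 6.0                       # small cluster, high peak
        z[6:9, 6, 6] = 5.0                     # larger cluster, lower peak
        m = StatMap(z=z, contrast=np.array([1.0]), dof=50,
                    mask=np.ones((10, 10, 10), bool))
        thr = threshold_map(m, voxel_alpha=0.05, cluster_min=1)
        assert [c.peak_z for c in thr.clusters] == [6.0, 5.0]


def test_null_phantom_zscores_standard_normal(block_design):
    """Pure-noise phantom: pooled voxelwise Z is consistent with N(0,1)."""
    spec = PhantomSpec(shape=(22, 22, 22), n_volumes=80, drift_amplitude_pct=0,
                       noise_smooth_vox=0.0, seed=12)
    bold, _ = generate_phantom(spec, block_design)
    bold.mask = None  # pool every voxel; noise fills the whole grid
    fit = fit_glm(bold, build_design(block_design, hp_cutoff=24))
    z = contrast_zmap(fit, {"moving": 1.0, "static": -1.0}).z.ravel()
    assert stats.kstest(z, "norm").pvalue > 0.01
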