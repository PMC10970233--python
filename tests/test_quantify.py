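"""Line-profile Gaussian fits and the per-telomere feature equations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qfish3d import (
    FWHM_FACTOR,
    DetectionParams,
    GaussianProfileFit,
    ImageStack3D,
    ProfileParams,
    VoxelGeometry,
    brightest_plane,
    compute_features,
    extract_profiles,
    find_spots,
    fit_profile,
    quantify_nucleus,
)
from qfish3d.quantify import SpotTooCloseToBorder, _gauss
from qfish3d.simulate import SimulationConfig, simulate_nucleus_stack

from conftest import render_single_spot


def _fit(a=2.0, b=52.0, c=8.0, d=1.9, r2=0.95, axis="x"):
    return GaussianProfileFit(a=a, b=b, c=c, d=d, r2=r2, axis=axis)


class TestBrightestPlane:
    def test_symmetric_spot_returns_center_plane(self):
        stack = render_single_spot(center=(7.0, 24.0, 24.0))
        (spot,) = find_spots(stack)
        assert brightest_plane(stack, spot) == 7

    def test_axial_center_between_planes_picks_nearer(self):
        stack = render_single_spot(center=(4.35, 24.0, 24.0))
        (spot,) = find_spots(stack)
        assert brightest_plane(stack, spot) == 4

    def test_single_plane_spot(self):
        vox = np.zeros((5, 32, 32), dtype=np.int64)
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        vox[2] = np.rint(60 * np.exp(-0.5 * (((yy - 16) / 2) ** 2 + ((xx - 16) / 2) ** 2)))
        stack = ImageStack3D(vox)
        (spot,) = find_spots(stack)
        assert brightest_plane(stack, spot) == 2


class TestExtractProfiles:
    def test_uniform_image_gives_constant_profiles(self):
        vox = np.full((5, 40, 40), 9, dtype=np.int64)
        vox[2, 20, 20] = 60  # a seed so detection finds something
        stack = ImageStack3D(vox)
        (spot,) = find_spots(stack, DetectionParams(min_spot_voxels=1))
        xp, yp = extract_profiles(stack, spot)
        assert xp.size == yp.size == 16
        assert np.all(xp[np.arange(16) != 8] == 9)

    def test_profile_maximum_near_center(self):
        stack = render_single_spot(noise_seed=2)
        (spot,) = find_spots(stack)
        xp, yp = extract_profiles(stack, spot)
        half = 16 // 2
        assert abs(int(np.argmax(xp)) - half) <= 1
        assert abs(int(np.argmax(yp)) - half) <= 1

    def test_border_spot_rejected(self):
        stack = render_single_spot(center=(7.0, 24.0, 2.0), shape=(15, 48, 48))
        (spot,) = find_spots(stack)
        with pytest.raises(SpotTooCloseToBorder):
            extract_profiles(stack, spot)


class TestFitProfile:
    def test_exact_model_recovered_to_machine_precision(self):
        x = np.arange(16, dtype=float)
        profile = _gauss(x, 2.0, 50.0, 8.0, 1.9)  # a=2, b=52, c=8, d=1.9
        fit = fit_profile(profile)
        assert fit.a == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(52.0, rel=1e-6)
        assert fit.c == pytest.approx(8.0, rel=1e-6)
        assert fit.d == pytest.approx(1.9, rel=1e-6)
        assert fit.r2 > 1 - 1e-12

    def test_constant_profile_is_insufficient(self):
        fit = fit_profile(np.full(16, 5.0))
        assert fit.r2 == 0.0
        assert not fit.converged

    def test_poisson_noise_median_width_within_10pct(self):
        rng = np.random.default_rng(77)
        x = np.arange(16, dtype=float)
        truth = _gauss(x, 2.0, 48.0, 8.0, 1.8667)
        ds = []
        for _ in range(200):
            fit = fit_profile(rng.poisson(truth).astype(float))
            if fit.r2 > 0.8:
                ds.append(fit.d)
        assert np.median(ds) == pytest.approx(1.8667, rel=0.10)

    def test_too_short_profile_raises(self):
        with pytest.raises(ValueError):
            fit_profile(np.array([1.0, 2.0, 3.0]))


class TestComputeFeatures:
    geometry = VoxelGeometry()

    def test_fwhm_equation_reproduces_mean_size(self):
        # d = 1.8686 px at 30 nm pixels -> FWHM = 132.0 nm
        feat = compute_features(_fit(d=1.8686), _fit(d=1.8686, axis="y"), self.geometry)
        assert feat.fwhm_x_nm == pytest.approx(132.0, abs=0.05)
        assert FWHM_FACTOR == pytest.approx(2.35482, abs=1e-5)

    def test_ellipsoid_volume_hand_calculation(self):
        d = 100.0 / (FWHM_FACTOR * 30.0)  # both FWHM exactly 100 nm
        feat = compute_features(_fit(d=d), _fit(d=d, axis="y"), self.geometry)
        assert feat.fwhm_z_nm == pytest.approx(100.0)
        assert feat.volume_um3 == pytest.approx((math.pi / 6) * 1e6 * 1e-9, rel=1e-9)
        assert feat.volume_um3 == pytest.approx(5.236e-4, rel=1e-3)

    def test_integrated_brightness_hand_calculation(self):
        feat = compute_features(
            _fit(a=0, b=10, d=2.0), _fit(a=0, b=10, d=2.0, axis="y"), self.geometry
        )
        assert feat.integrated_brightness == pytest.approx(2 * math.pi * 10 * 4, rel=1e-9)
        assert feat.integrated_brightness == pytest.approx(251.33, abs=0.01)

    def test_single_sufficient_fit_uses_better_axis_only(self):
        feat = compute_features(
            _fit(r2=0.9), _fit(r2=0.5, axis="y", b=99.0), self.geometry
        )
        assert feat.quality_flag == "single_fit"
        assert feat.brightness_peak == 52.0  # from the x fit
        assert feat.fwhm_x_nm is not None and feat.fwhm_y_nm is None
        assert feat.integrated_brightness is None and feat.signal_density is None

    def test_both_insufficient_is_rejected(self):
        feat = compute_features(_fit(r2=0.3), _fit(r2=0.2, axis="y"), self.geometry)
        assert feat.quality_flag == "rejected"
        assert feat.brightness_peak is None

    def test_background_shift_moves_b_not_amplitude(self):
        x = np.arange(16, dtype=float)
        base = _gauss(x, 2.0, 50.0, 8.0, 1.9)
        f0 = fit_profile(base)
        f1 = fit_profile(base + 7.0)
        assert f1.b - f0.b == pytest.approx(7.0, abs=1e-5)
        assert (f1.b - f1.a) == pytest.approx(f0.b - f0.a, abs=1e-5)

    @given(scale=st.floats(0.25, 4.0))
    def test_fwhm_and_volume_scale_equivariance(self, scale):
        g1 = VoxelGeometry(30.0, 30.0, 200.0)
        g2 = VoxelGeometry(30.0 * scale, 30.0 * scale, 200.0 * scale)
        f1 = compute_features(_fit(), _fit(axis="y", d=2.1), g1)
        f2 = compute_features(_fit(), _fit(axis="y", d=2.1), g2)
        assert f2.fwhm_x_nm == pytest.approx(scale * f1.fwhm_x_nm)
        assert f2.fwhm_z_nm == pytest.approx(scale * f1.fwhm_z_nm)
        assert f2.volume_um3 == pytest.approx(scale**3 * f1.volume_um3)
        assert f2.signal_density == pytest.approx(f1.signal_density / scale**3)


class TestQuantifyNucleus:
    def test_empty_masked_stack_gives_empty_record(self):
        stack = ImageStack3D(np.zeros((5, 32, 32), dtype=np.int64))
        rec = quantify_nucleus(stack, cell_id="c0", phase="interphase")
        assert rec.features == []
        assert rec.phase == "interphase"

    def test_interphase_scale_count_recovered(self):
        cfg = SimulationConfig(n_spots=90, seed=42)
        stack, truths, mask = simulate_nucleus_stack(cfg)
        rec = quantify_nucleus(stack, mask)
        n_ok = sum(1 for f in rec.features if f.quality_flag != "rejected")
        assert n_ok == pytest.approx(90, rel=0.05)
        fwhms = [f.fwhm_x_nm for f in rec.features if f.fwhm_x_nm]
        assert np.mean(fwhms) == pytest.approx(FWHM_FACTOR * 56.0, abs=7.0)

    def test_border_spots_kept_as_rejected(self):
        stack = render_single_spot(center=(7.0, 24.0, 3.0), shape=(15, 48, 48))
        rec = quantify_nucleus(stack)
        assert len(rec.features) == 1
        assert rec.features[0].quality_flag == "rejected"
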