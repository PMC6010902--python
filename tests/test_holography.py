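import numpy as np
import pytest

from nanoholo import holography as holo
from nanoholo.volume import Volume3D

# Scan-parameter table rows used throughout (D1 values in mm)
D1_ALL = (80.533, 52.346, 54.592, 63.575, 82.226, 20.133, 20.997, 24.452,
          31.625, 10.066, 10.499, 12.226, 15.812, 40.266, 41.994, 48.904, 63.251)


class TestMagnification:
    def test_sample_at_detector_gives_unit_magnification(self):
        d = holo.magnification(1208.0, 1208.0, detector_pixel_um=3.0)
        assert d.m == pytest.approx(1.0)
        assert d.effective_pixel_nm == pytest.approx(3000.0)

    def test_calibrated_total_distance(self):
        # total = detector_pixel * D1 / l from the 200 nm prescan row
        total = 3.0e3 * 80.533 / 200.0
        assert total == pytest.approx(1208.0, abs=0.01)
        assert holo.DEFAULT_FOCUS_DETECTOR_MM == pytest.approx(1208.0, abs=0.01)

    def test_25nm_row_effective_pixel(self):
        d = holo.magnification(10.066, holo.DEFAULT_FOCUS_DETECTOR_MM)
        assert round(d.effective_pixel_nm) == 25

    def test_magnification_times_pixel_is_detector_pixel(self):
        for d1 in D1_ALL:
            d = holo.magnification(d1, holo.DEFAULT_FOCUS_DETECTOR_MM, 3.0)
            assert d.m * d.effective_pixel_nm == pytest.approx(3000.0, rel=1e-12)

    def test_geometry_errors(self):
        with pytest.raises(holo.GeometryError):
            holo.magnification(-1.0, 1208.0)
        with pytest.raises(holo.GeometryError):
            holo.magnification(1300.0, 1208.0)


class TestPhotonBudget:
    @pytest.mark.parametrize("n,p,d,expected", [
        (1800, 500, 4, 3.6),
        (2000, 600, 4, 4.8),
        (1200, 600, 1, 0.7),  # 0.72 rounded to one decimal
    ])
    def test_table_rows(self, n, p, d, expected):
        assert holo.photons_per_pixel_scan_megaphotons(n, p, d) == expected

    def test_raw_product(self):
        assert holo.photons_per_pixel_scan(1200, 500, 1) == 600_000

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            holo.photons_per_pixel_scan(0, 500, 4)


class TestFresnelPropagate:
    LAM = holo.HC_EV_NM / 17e3  # 17 keV

    def test_plane_wave_uniform_intensity(self):
        out = holo.fresnel_propagate(np.zeros((64, 64)), 1.0, self.LAM, 0.5, 100.0)
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_zero_distance_identity(self):
        phase = np.random.default_rng(0).normal(0, 0.2, (32, 32))
        amp = np.random.default_rng(1).uniform(0.5, 1.5, (32, 32))
        out = holo.fresnel_propagate(phase, amp, self.LAM, 0.0, 100.0)
        assert np.allclose(out, amp**2)

    def test_weak_object_transfer_function(self):
        # intensity spectrum at the grating frequency scales as 2 sin(chi) phi
        n, pix, k = 256, 100.0, 10
        f = k / (n * pix)
        phase = 0.05 * np.cos(2 * np.pi * f * np.arange(n) * pix)
        phase = np.tile(phase, (n, 1))
        d_mm = 0.5
        out = holo.fresnel_propagate(phase, 1.0, self.LAM, d_mm, pix)
        measured = 2 * np.abs(np.fft.fft2(out - 1.0)[0, k]) / n**2
        chi = np.pi * self.LAM * d_mm * 1e6 * f**2
        assert measured == pytest.approx(abs(2 * np.sin(chi) * 0.05), rel=0.01)

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(2)
        amp = 1.0 + 0.1 * rng.normal(size=(64, 64))
        phase = 0.3 * rng.normal(size=(64, 64))
        before = np.sum(amp**2)
        out = holo.fresnel_propagate(phase, amp, self.LAM, 0.2, 100.0)
        assert np.sum(out) == pytest.approx(before, rel=1e-6)

    def test_undersampling_warns(self):
        with pytest.warns(UserWarning, match="undersampled"):
            holo.fresnel_propagate(np.zeros((64, 64)), 1.0, self.LAM, 50.0, 25.0)


def _weak_phantom(n=128):
    yy, xx = np.mgrid[0:n, 0:n]
    return 0.1 * np.exp(-((yy - n / 2) ** 2 + (xx - n / 2) ** 2) / (2 * (n / 6) ** 2))


@pytest.fixture(scope="module")
def cerebellum_geometry():
    return holo.AcquisitionGeometry()  # 25 nm row defaults


class TestHologramSeries:
    def test_noiseless_matches_direct_propagation(self, cerebellum_geometry):
        import dataclasses
        geom = dataclasses.replace(cerebellum_geometry,
                                   photons_per_pixel_projection=None)
        phase = _weak_phantom()
        with pytest.warns(UserWarning, match="undersampled"):
            hset = holo.simulate_hologram_series(phase, geom, rng_seed=0)
            der = geom.derived(0)
            direct = holo.fresnel_propagate(phase, 1.0, geom.wavelength_nm,
                                            der.d_eff_mm, der.effective_pixel_nm)
        assert np.allclose(hset.holograms[0], direct)
        assert all(np.allclose(f, 1.0) for f in hset.flats)

    def test_flat_field_mean_matches_photon_count(self, cerebellum_geometry):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            hset = holo.simulate_hologram_series(_weak_phantom(), cerebellum_geometry,
                                                 rng_seed=3)
        flat = np.concatenate([f.ravel() for f in hset.flats])
        assert flat.mean() == pytest.approx(500.0, rel=0.01)

    def test_seeded_repeat_identical(self, cerebellum_geometry):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            h1 = holo.simulate_hologram_series(_weak_phantom(), cerebellum_geometry, 9)
            h2 = holo.simulate_hologram_series(_weak_phantom(), cerebellum_geometry, 9)
        for a, b in zip(h1.holograms, h2.holograms):
            assert np.array_equal(a, b)


class TestNormalizeAndAlign:
    def test_identity_when_same_magnification(self):
        rng = np.random.default_rng(0)
        imgs = [rng.poisson(500, (32, 32)).astype(float) for _ in range(2)]
        flats = [np.full((32, 32), 500.0)] * 2
        hset = holo.HologramSet(imgs, flats, [1.0, 1.0], [25.0, 25.0], [1.0, 1.0])
        stack = holo.normalize_and_align(hset)
        assert np.allclose(stack[0], imgs[0] / 500.0)

    def test_zero_flat_rejected(self):
        flats = [np.zeros((8, 8))]
        hset = holo.HologramSet([np.ones((8, 8))], flats, [1.0], [25.0], [1.0])
        with pytest.raises(holo.NormalizationError):
            holo.normalize_and_align(hset)

    def test_magnification_rescale(self):
        # coarse rendering of a smooth pattern upsampled to the fine grid
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        fine = 1.0 + 0.1 * np.sin(2 * np.pi * yy / n) * np.cos(2 * np.pi * xx / n)
        coarse = fine[::2, ::2]
        hset = holo.HologramSet([fine, coarse], [np.ones_like(fine), np.ones_like(coarse)],
                                [2.0, 1.0], [25.0, 50.0], [1.0, 1.0])
        stack = holo.normalize_and_align(hset)
        diff = np.abs(stack[1][:n - 4, :n - 4] - fine[:n - 4, :n - 4])
        assert diff.max() < 0.02 * 0.2  # < 2% of the contrast range

    def test_injected_shift_removed(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage
        base = ndimage.gaussian_filter(rng.normal(1.0, 0.1, (64, 64)), 2)
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        hset = holo.HologramSet([base, shifted],
                                [np.ones_like(base)] * 2,
                                [1.0, 1.0], [25.0, 25.0], [1.0, 1.0])
        stack = holo.normalize_and_align(hset)
        assert np.abs(stack[1] - base).mean() < 0.5 * np.abs(shifted - base).mean()


class TestCtfRetrieval:
    def test_zero_contrast_gives_zero_phase(self):
        stack = np.ones((4, 32, 32))
        out = holo.ctf_phase_retrieval(stack, 0.073, [10, 11, 12, 13], 25.0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_round_trip_on_weak_phantom(self, cerebellum_geometry):
        import dataclasses
        import warnings
        geom = dataclasses.replace(cerebellum_geometry,
                                   photons_per_pixel_projection=None)
        phase = 0.1 * np.exp(
            -((np.mgrid[0:256, 0:256][0] - 128) ** 2
              + (np.mgrid[0:256, 0:256][1] - 128) ** 2) / (2 * 40**2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            hset = holo.simulate_hologram_series(phase, geom, 0)
            stack = holo.normalize_and_align(hset)
        ret = holo.ctf_phase_retrieval(stack, geom.wavelength_nm, hset.d_eff_mm,
                                       hset.effective_pixels_nm[0])
        ret = ret - ret.mean() + phase.mean()
        rmse = np.sqrt(np.mean((ret - phase) ** 2))
        assert rmse < 0.1 * (phase.max() - phase.min())

    def test_single_distance_at_ctf_maximum(self):
        # place a single spatial frequency at chi = pi/2 where sin(chi) = 1
        n, k = 128, 16
        lam = holo.HC_EV_NM / 17e3
        pix = 50.0
        f = k / (n * pix)
        d_nm = 0.5 * np.pi / (np.pi * lam * f**2)
        amp0 = 0.02
        phase = amp0 * np.cos(2 * np.pi * f * np.arange(n) * pix)
        phase = np.tile(phase, (n, 1))
        intensity = holo.fresnel_propagate(phase, 1.0, lam, d_nm / 1e6, pix)
        ret = holo.ctf_phase_retrieval(intensity[None], lam, [d_nm / 1e6], pix,
                                       regularization=1e-12)
        measured = 2 * np.abs(np.fft.fft2(ret)[0, k]) / n**2
        assert measured == pytest.approx(amp0, rel=0.02)

    def test_monotone_improvement_with_photons(self, cerebellum_geometry):
        import dataclasses
        import warnings
        phase = _weak_phantom(128)
        errors = []
        for photons in (1e2, 1e3, 1e4):
            seed_err = []
            for seed in range(3):
                geom = dataclasses.replace(cerebellum_geometry,
                                           photons_per_pixel_projection=photons)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    hset = holo.simulate_hologram_series(phase, geom, seed)
                    stack = holo.normalize_and_align(hset)
                ret = holo.ctf_phase_retrieval(stack, geom.wavelength_nm,
                                               hset.d_eff_mm,
                                               hset.effective_pixels_nm[0])
                ret = ret - ret.mean() + phase.mean()
                seed_err.append(np.sqrt(np.mean((ret - phase) ** 2)))
            errors.append(np.mean(seed_err))
        assert errors[0] > errors[1] > errors[2]

    def test_zero_regularization_guard(self):
        stack = np.ones((1, 16, 16)) * 1.1
        with pytest.raises(ZeroDivisionError):
            holo.ctf_phase_retrieval(stack, 0.073, [10.0], 25.0, regularization=0.0)


class TestFbp:
    def test_zero_sinogram_gives_zero_volume(self):
        angles = np.linspace(0, 180, 30, endpoint=False)
        vol = holo.fbp_reconstruct(np.zeros((2, 30, 33)), angles)
        assert np.allclose(vol.voxels, 0.0, atol=1e-12)

    def test_disk_round_trip_correlation(self):
        from skimage.transform import radon
        n = 65
        yy, xx = np.mgrid[0:n, 0:n]
        disk = (((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= 15**2).astype(float)
        angles = np.linspace(0, 180, 360, endpoint=False)
        sino = radon(disk, theta=angles, circle=True).T  # (n_angles, n_det)
        rec = holo.fbp_reconstruct(sino[None], angles).voxels[0]
        support = ((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= (n // 2 - 2) ** 2
        corr = np.corrcoef(rec[support], disk[support])[0, 1]
        assert corr > 0.95

    def test_more_angles_reduce_error(self):
        from skimage.transform import radon
        n = 65
        rng = np.random.default_rng(0)
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), 3)
        yy, xx = np.mgrid[0:n, 0:n]
        support = ((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= (n // 2 - 2) ** 2
        img = img * support
        errs = []
        for n_ang in (45, 90):
            angles = np.linspace(0, 180, n_ang, endpoint=False)
            sino = radon(img, theta=angles, circle=True).T
            rec = holo.fbp_reconstruct(sino[None], angles).voxels[0]
            errs.append(np.sqrt(np.mean((rec[support] - img[support]) ** 2)))
        assert errs[1] < errs[0]

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            holo.fbp_reconstruct(np.zeros((1, 1, 16)), [0.0])
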