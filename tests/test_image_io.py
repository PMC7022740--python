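import numpy as np
import pytest

from tuberspec.image_io import (
    CalibrationPair,
    DegenerateReferenceError,
    DimensionError,
    Hypercube,
    Mask,
    build_mask,
    calibrate,
    extract_spectra,
    read_envi_cube,
    trim_bands,
    write_envi_cube,
)


def _cube(data, wl=None, **kw):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[2], dtype=float) if wl is None else wl
    return Hypercube(data, wl, **kw)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bsq", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_write_read_identity(self, tmp_path, interleave, dtype, rng):
        data = (rng.uniform(0, 100, (4, 5, 6))).astype(dtype)
        cube = Hypercube(data, np.linspace(400, 900, 6), "raw", interleave)
        hdr = write_envi_cube(cube, tmp_path / "cube")
        back = read_envi_cube(hdr)
        np.testing.assert_array_equal(back.data, data)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths, atol=1e-4)
        assert back.interleave == interleave

    def test_interleaves_agree_after_read(self, tmp_path, rng):
        data = rng.uniform(size=(3, 4, 5)).astype(np.float32)
        wl = np.linspace(500, 600, 5)
        cubes = {}
        for il in ("bil", "bsq"):
            hdr = write_envi_cube(Hypercube(data, wl, "raw", il), tmp_path / il)
            cubes[il] = read_envi_cube(hdr).data
        np.testing.assert_array_equal(cubes["bil"], cubes["bsq"])

    def test_payload_dimension_mismatch_raises(self, tmp_path, rng):
        cube = _cube(rng.uniform(size=(2, 3, 10)), wl=np.arange(10.0))
        hdr = write_envi_cube(cube, tmp_path / "bad")
        dat = str(tmp_path / "bad.dat")
        payload = np.fromfile(dat, dtype="<f4")[:-6]  # drop one band worth
        payload.tofile(dat)
        with pytest.raises(DimensionError):
            read_envi_cube(hdr)

    def test_missing_wavelengths_raises(self, tmp_path):
        hdr = tmp_path / "nolambda.hdr"
        hdr.write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 2\n"
            "data type = 4\ninterleave = bil\n"
        )
        np.zeros(8, dtype="<f4").tofile(tmp_path / "nolambda.dat")
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(hdr)


class TestCalibrate:
    def test_white_dark_and_midpoint_identities(self, rng):
        wl = np.arange(5.0)
        dark = _cube(np.full((3, 3, 5), 100.0), wl)
        white = _cube(100.0 + rng.uniform(500, 900, (3, 3, 5)), wl)
        pair = CalibrationPair(white, dark)
        assert np.allclose(calibrate(white, pair).data, 1.0)
        assert np.allclose(calibrate(dark, pair).data, 0.0)
        mid = _cube((white.data + dark.data) / 2, wl)
        assert np.allclose(calibrate(mid, pair).data, 0.5)
        assert calibrate(mid, pair).kind == "reflectance"

    def test_degenerate_reference_rejected(self):
        wl = np.arange(3.0)
        white = _cube(np.full((2, 2, 3), 50.0), wl)
        dark = _cube(np.full((2, 2, 3), 50.0), wl)
        with pytest.raises(DegenerateReferenceError):
            calibrate(white, CalibrationPair(white, dark))

    def test_invariant_to_common_pixel_gain(self, rng):
        # (g*raw - g*dark) / (g*white - g*dark) == (raw-dark)/(white-dark)
        wl = np.arange(4.0)
        dark = rng.uniform(50, 100, (3, 2, 4))
        white = dark + rng.uniform(200, 500, (3, 2, 4))
        raw = dark + rng.uniform(0, 1, (3, 2, 4)) * (white - dark)
        gain = rng.uniform(0.5, 2.0, (3, 2, 1))
        r1 = calibrate(_cube(raw, wl), CalibrationPair(_cube(white, wl), _cube(dark, wl)))
        r2 = calibrate(
            _cube(gain * raw, wl),
            CalibrationPair(_cube(gain * white, wl), _cube(gain * dark, wl)),
        )
        np.testing.assert_allclose(r1.data, r2.data, atol=1e-12)


class TestMaskExtract:
    def test_uniform_low_cube_gives_empty_mask(self):
        cube = _cube(np.full((4, 4, 3), 0.05), wl=np.array([580.0, 590.0, 600.0]))
        assert build_mask(cube).n_pixels == 0

    def test_zero_threshold_selects_everything(self):
        cube = _cube(np.full((4, 4, 3), 0.05), wl=np.array([580.0, 590.0, 600.0]))
        assert build_mask(cube, threshold=0.0).n_pixels == 16

    def test_mask_records_provenance_and_band_range(self):
        cube = _cube(np.ones((2, 2, 3)), wl=np.array([580.0, 590.0, 600.0]))
        assert build_mask(cube).provenance == (590.0, 0.1)
        with pytest.raises(ValueError):
            build_mask(cube, band_nm=1000.0)

    def test_nearest_band_tie_prefers_lower(self):
        cube = _cube(np.ones((1, 1, 2)), wl=np.array([580.0, 600.0]))
        assert cube.band_index(590.0) == 0

    def test_extract_mean_of_two_pixels(self):
        data = np.zeros((1, 3, 4))
        data[0, 0] = [1, 2, 3, 4]
        data[0, 2] = [3, 4, 5, 6]
        cube = _cube(data)
        mask = Mask(np.array([[True, False, True]]))
        matrix, mean = extract_spectra(cube, mask)
        assert matrix.n_spectra == 2
        np.testing.assert_allclose(mean, [2, 3, 4, 5])

    def test_full_mask_mean_equals_spatial_mean(self, rng):
        cube = _cube(rng.uniform(size=(5, 6, 7)))
        _, mean = extract_spectra(cube, Mask(np.ones((5, 6), dtype=bool)))
        np.testing.assert_allclose(mean, cube.data.mean(axis=(0, 1)))

    def test_empty_mask_rejected(self):
        cube = _cube(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            extract_spectra(cube, Mask(np.zeros((2, 2), dtype=bool)))


class TestTrimBands:
    def test_trim_retains_window_and_matches_linear_scan(self):
        wl = np.linspace(380, 1030, 511)
        cube = _cube(np.ones((2, 2, 511)), wl)
        trimmed = trim_bands(cube, 477, 947)
        assert trimmed.wavelengths.min() >= 477
        assert trimmed.wavelengths.max() <= 947
        expected = sum(1 for w in wl if 477 <= w <= 947)  # brute-force count
        assert trimmed.data.shape[2] == expected

    def test_trim_full_range_is_identity(self, rng):
        cube = _cube(rng.uniform(size=(2, 2, 10)))
        out = trim_bands(cube, cube.wavelengths[0], cube.wavelengths[-1])
        np.testing.assert_array_equal(out.data, cube.data)

    def test_trim_then_extract_commutes_with_extract_then_trim(self, rng):
        wl = np.linspace(400, 1000, 20)
        cube = _cube(rng.uniform(size=(4, 4, 20)), wl)
        mask = Mask(rng.uniform(size=(4, 4)) > 0.5)
        a, _ = extract_spectra(trim_bands(cube, 500, 900), mask)
        b_mat, _ = extract_spectra(cube, mask)
        b = trim_bands(b_mat, 500, 900)
        np.testing.assert_allclose(a.data, b.data)

    def test_empty_window_rejected(self):
        cube = _cube(np.ones((1, 1, 3)), wl=np.array([500.0, 510.0, 520.0]))
        with pytest.raises(ValueError):
            trim_bands(cube, 600, 700)
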