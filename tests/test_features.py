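"""Feature-extraction geometry, oracles and invariances."""

import numpy as np
import pytest

import gazedecode as gd
from gazedecode.features import _hog_cell_histograms, _spectrum_geometry


def make_grating(width=200, cpi=8, orientation_deg=0.0, contrast=0.4):
    yy, xx = np.mgrid[0:width, 0:width]
    a = np.radians(orientation_deg)
    phase = 2 * np.pi * cpi * (np.cos(a) * xx + np.sin(a) * yy) / width
    return gd.StimulusImage(0.5 + contrast * np.sin(phase))


class TestFourier:
    def test_canonical_length(self, noise_image):
        assert len(gd.fourier_features(noise_image)) == 384

    def test_constant_image_is_all_zero(self):
        img = gd.StimulusImage(np.full((200, 200), 0.7))
        assert np.allclose(gd.fourier_features(img).values, 0.0)

    def test_grating_lands_in_single_band(self):
        """A pure sinusoid concentrates all energy in the one band pair
        containing its frequency and orientation; the band value equals the
        brute-force sum of the raw spectrum over that band."""
        img = make_grating(cpi=8, orientation_deg=0.0)
        binning = gd.FourierBinning()
        v = gd.fourier_features(img, binning).values

        # brute-force: full discrete spectrum summed over the band pair
        mag = np.abs(np.fft.fftshift(np.fft.fft2(img.pixels)))
        sf_band, orient_band, keep = _spectrum_geometry(binning)
        expected_idx = 1 * binning.n_orientation_bands + 0  # 8 cpi -> band 1
        mask = keep & (sf_band == 1) & (orient_band == 0)
        assert v[expected_idx] == pytest.approx(mag[mask].sum())
        assert v[expected_idx] > 0
        others = np.delete(v, expected_idx)
        assert np.all(others < 1e-6 * v[expected_idx])

    def test_translation_invariance(self, noise_image):
        """Magnitude spectra discard phase, so circular shifts leave the
        binned features unchanged."""
        v0 = gd.fourier_features(noise_image).values
        shifted = gd.StimulusImage(np.roll(noise_image.pixels, (17, -31), (0, 1)))
        v1 = gd.fourier_features(shifted).values
        np.testing.assert_allclose(v0, v1, rtol=1e-9, atol=1e-9)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            gd.StimulusImage(np.zeros((100, 200)))


class TestApertureMask:
    @pytest.mark.parametrize("cell,expected_cells", [(10, 276), (20, 60), (40, 9)])
    def test_kept_cell_counts(self, cell, expected_cells):
        assert len(gd.aperture_cell_mask(200, cell)) == expected_cells

    def test_cell40_is_central_3x3(self):
        assert gd.aperture_cell_mask(200, 40) == [
            (i, j) for i in (1, 2, 3) for j in (1, 2, 3)]

    @pytest.mark.parametrize("cell", [10, 20, 40])
    def test_agrees_with_pixel_membership(self, cell):
        """A kept cell must have every pixel center inside the disc; a
        dropped cell must have at least one corner outside."""
        kept = set(gd.aperture_cell_mask(200, cell))
        c, r2 = 100.0, 100.0**2
        for i in range(200 // cell):
            for j in range(200 // cell):
                xs = np.arange(j * cell, (j + 1) * cell) + 0.5
                ys = np.arange(i * cell, (i + 1) * cell) + 0.5
                px, py = np.meshgrid(xs, ys)
                all_px_inside = np.all((px - c) ** 2 + (py - c) ** 2 <= r2)
                if (i, j) in kept:
                    assert all_px_inside
                else:
                    corners = [(j * cell + dx * cell, i * cell + dy * cell)
                               for dx in (0, 1) for dy in (0, 1)]
                    assert any((x - c) ** 2 + (y - c) ** 2 > r2
                               for x, y in corners)

    def test_oversize_aperture_keeps_all(self):
        mask = gd.aperture_cell_mask(200, 20, aperture_diameter_px=300)
        assert len(mask) == 100

    def test_non_divisible_width_rejected(self):
        with pytest.raises(ValueError):
            gd.aperture_cell_mask(200, 33)


class TestHOG:
    @pytest.mark.parametrize("cell,expected", [(10, 2484), (20, 540), (40, 81)])
    def test_feature_counts(self, noise_image, cell, expected):
        spec = gd.HOGSpec(cell_size_px=cell)
        assert len(gd.hog_features(noise_image, spec)) == expected

    def test_total_and_excluded_at_10px(self):
        spec = gd.HOGSpec(cell_size_px=10)
        assert spec.n_features_total == 3600
        assert spec.n_features_total - spec.n_features == 1116

    def test_constant_image_zero_histograms(self):
        img = gd.StimulusImage(np.full((200, 200), 0.3))
        assert np.allclose(gd.hog_features(img).values, 0.0)

    def test_matches_naive_per_pixel_oracle(self, rng):
        """Vectorized histograms equal a direct per-pixel loop (centered
        differences, bilinear orientation votes, per-cell L2)."""
        px = rng.random((40, 40))
        spec = gd.HOGSpec(cell_size_px=20, width_px=40,
                          aperture_diameter_px=200)  # keep all cells
        got = _hog_cell_histograms(px, spec)

        gy, gx = np.gradient(px)
        expected = np.zeros((2, 2, 9))
        for y in range(40):
            for x in range(40):
                m = np.hypot(gx[y, x], gy[y, x])
                th = np.degrees(np.arctan2(gy[y, x], gx[y, x])) % 180.0
                pos = th / 20.0
                lo = int(np.floor(pos)) % 9
                frac = pos - np.floor(pos)
                expected[y // 20, x // 20, lo] += m * (1 - frac)
                expected[y // 20, x // 20, (lo + 1) % 9] += m * frac
        expected /= np.sqrt((expected**2).sum(axis=2, keepdims=True) + 1e-12)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_vertical_edge_votes_vertical_bin(self):
        """A vertical luminance edge has horizontal gradient -> unsigned
        orientation 0 -> all its mass in bin 0 of the cells it crosses."""
        px = np.zeros((40, 40))
        px[:, 20:] = 1.0
        spec = gd.HOGSpec(cell_size_px=20, width_px=40, aperture_diameter_px=200)
        hist = _hog_cell_histograms(px, spec)
        assert hist[0, 0, 0] > 0.99 and hist[0, 0, 1:].max() < 0.01
        assert hist[0, 1, 0] > 0.99


class TestTrialDifference:
    def _fv(self, values):
        binning = gd.FourierBinning(n_sf_bands=1, n_orientation_bands=2)
        return gd.FeatureVector(np.asarray(values, dtype=float), "fourier", binning)

    def test_arithmetic_and_label(self):
        td = gd.trial_difference(self._fv([1, 2]), self._fv([3, 1]), "right")
        np.testing.assert_array_equal(td.diff.values, [2, -1])
        assert td.label == 1

    def test_same_image_zero_diff(self):
        td = gd.trial_difference(self._fv([4, 5]), self._fv([4, 5]), "left")
        assert np.allclose(td.diff.values, 0) and td.label == 0

    def test_antisymmetry_under_swap(self):
        l, r = self._fv([1.5, -2.0]), self._fv([0.5, 3.0])
        td = gd.trial_difference(l, r, "right")
        sw = gd.trial_difference(r, l, "left")
        np.testing.assert_allclose(sw.diff.values, -td.diff.values)
        assert sw.label == 1 - td.label

    def test_geometry_mismatch_rejected(self):
        other = gd.FeatureVector(np.zeros(81), "hog", gd.HOGSpec(cell_size_px=40))
        with pytest.raises(ValueError):
            gd.trial_difference(self._fv([0, 0]), other, "left")


def test_feature_table_headers_encode_geometry(small_faces):
    df = gd.feature_table(small_faces[:3], gd.fourier_features, gd.FourierBinning())
    assert df.shape == (3, 2 + 384)
    assert df.columns[2] == "sf00_or00" and df.columns[-1] == "sf23_or15"
    spec = gd.HOGSpec(cell_size_px=40)
    df2 = gd.feature_table(small_faces[:2], gd.hog_features, spec)
    assert df2.columns[2] == "r01c01_or0"


def test_geometry_json_roundtrip(tmp_path):
    import json
    p = tmp_path / "geom.json"
    gd.geometry_to_json(gd.FourierBinning(), p)
    d = json.loads(p.read_text())
    assert d["n_sf_bands"] == 24 and len(d["sf_band_edges"]) == 25
    d2 = json.loads(gd.geometry_to_json(gd.HOGSpec(cell_size_px=20)))
    assert len(d2["kept_cells"]) == 60


def test_load_stimulus_roundtrip(tmp_path, small_faces):
    from PIL import Image
    im = small_faces[0]
    arr = (np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)
    p = tmp_path / "face.png"
    Image.fromarray(arr).save(p)
    loaded = gd.load_stimulus(p, identity="x", expression="happy")
    assert loaded.width_px == 200
    yy, xx = np.mgrid[0:200, 0:200]
    inside = (xx - 99.5) ** 2 + (yy - 99.5) ** 2 <= 100.0**2
    # in-aperture content survives the 8-bit roundtrip; the background is
    # replaced by the mean in-aperture intensity on load
    assert np.abs(loaded.pixels - im.pixels)[inside].max() < 2 / 255 + 1e-9
    outside = loaded.pixels[~inside]
    assert np.all(outside == outside[0])
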