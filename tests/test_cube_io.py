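"""ENVI round trips, header validation, and white-reference correction."""

import numpy as np
import pytest

from pomonet.cube_io import (HyperCube, WavelengthGrid, WhiteReference,
                             read_envi, white_correct, write_envi)


class TestWavelengthGrid:
    def test_default_grid_span_and_count(self):
        grid = WavelengthGrid.default()
        assert grid.count == 360
        assert grid.values[0] == pytest.approx(395.0)
        assert grid.values[-1] == pytest.approx(1008.0)
        spacing = np.diff(grid.values)
        assert np.allclose(spacing, spacing[0])

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid(np.array([400.0, 400.0, 500.0]))
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid(np.array([500.0, 400.0]))

    def test_nearest_band(self):
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        assert grid.nearest_band(510.0) == 1
        assert grid.nearest_band(400.0) == 0
        with pytest.raises(ValueError, match="outside grid range"):
            grid.nearest_band(350.0)


class TestHyperCube:
    def test_band_count_must_match_grid(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        with pytest.raises(ValueError, match="bands"):
            HyperCube(np.zeros((4, 4, 3)), grid)

    def test_rejects_unknown_kind(self):
        grid = WavelengthGrid(np.array([400.0]))
        with pytest.raises(ValueError, match="kind"):
            HyperCube(np.zeros((2, 2, 1)), grid, kind="corrected")


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_round_trip_preserves_data(self, tmp_path, rng, interleave):
        grid = WavelengthGrid(np.linspace(400, 900, 7))
        data = rng.random((5, 6, 7)).astype(np.float32)
        cube = HyperCube(data, grid)
        write_envi(cube, tmp_path / "cube.hdr", interleave=interleave)
        back = read_envi(tmp_path / "cube.hdr")
        assert back.shape == (5, 6, 7)
        np.testing.assert_array_equal(back.data, data)
        np.testing.assert_allclose(back.grid.values, grid.values, atol=1e-5)

    def test_missing_wavelengths_rejected(self, tmp_path):
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\n"
            "data type = 4\ninterleave = bsq\n")
        np.zeros(4, dtype="<f4").tofile(tmp_path / "c.img")
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(tmp_path / "c.hdr")

    def test_band_count_mismatch_rejected(self, tmp_path):
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 2\n"
            "data type = 4\ninterleave = bsq\n"
            "wavelength = { 500.0 }\n")
        np.zeros(8, dtype="<f4").tofile(tmp_path / "c.img")
        with pytest.raises(ValueError, match="wavelengths"):
            read_envi(tmp_path / "c.hdr")

    def test_size_mismatch_rejected(self, tmp_path):
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\n"
            "data type = 4\ninterleave = bsq\n"
            "wavelength = { 500.0 }\n")
        np.zeros(3, dtype="<f4").tofile(tmp_path / "c.img")
        with pytest.raises(ValueError, match="header implies"):
            read_envi(tmp_path / "c.hdr")

    def test_multiline_wavelength_block(self, tmp_path):
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 3\n"
            "data type = 4\ninterleave = bip\n"
            "wavelength = { 400.0,\n 500.0,\n 600.0 }\n")
        np.arange(3, dtype="<f4").tofile(tmp_path / "c.img")
        cube = read_envi(tmp_path / "c.hdr")
        np.testing.assert_allclose(cube.grid.values, [400, 500, 600])


class TestWhiteCorrect:
    def test_formula(self):
        grid = WavelengthGrid(np.array([500.0, 600.0]))
        raw = HyperCube(np.array([[[30.0, 60.0]]]), grid)
        ref = WhiteReference(np.array([110.0, 110.0]),
                             dark=np.array([10.0, 10.0]))
        out = white_correct(raw, ref)
        assert out.kind == "reflectance"
        np.testing.assert_allclose(out.data[0, 0], [0.2, 0.5])

    def test_clipping_bounds(self):
        grid = WavelengthGrid(np.array([500.0]))
        raw = HyperCube(np.array([[[500.0], [-20.0]]]), grid)
        ref = WhiteReference(np.array([100.0]))
        out = white_correct(raw, ref, headroom=0.1)
        assert out.data.max() == pytest.approx(1.1)
        assert out.data.min() == pytest.approx(0.0)

    def test_zero_denominator_rejected(self):
        grid = WavelengthGrid(np.array([500.0, 600.0]))
        raw = HyperCube(np.zeros((1, 1, 2)), grid)
        with pytest.raises(ValueError, match="not above dark"):
            WhiteReference(np.array([100.0, 10.0]),
                           dark=np.array([10.0, 10.0]))

    def test_requires_raw_cube(self):
        grid = WavelengthGrid(np.array([500.0]))
        cube = HyperCube(np.zeros((1, 1, 1)), grid, kind="reflectance")
        with pytest.raises(ValueError, match="raw"):
            white_correct(cube, WhiteReference(np.array([1.0])))

    def test_band_count_checked(self):
        grid = WavelengthGrid(np.array([500.0]))
        raw = HyperCube(np.zeros((1, 1, 1)), grid)
        with pytest.raises(ValueError, match="bands"):
            white_correct(raw, WhiteReference(np.array([1.0, 2.0])))
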