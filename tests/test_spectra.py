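"""Spectrum model, I/O round trips, replicate averaging, baseline correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ftirclass as fc
from ftirclass.spectra import SpectrumError


class TestSpectrumModel:
    def test_stored_descending_regardless_of_input_direction(self):
        wn = np.array([3996.0, 3998.0, 4000.0])
        ab = np.array([0.1, 0.2, 0.3])
        s = fc.Spectrum(wn, ab)
        assert s.wavenumbers[0] == 4000.0 and s.wavenumbers[-1] == 3996.0
        np.testing.assert_array_equal(s.absorbance, ab[::-1])
        s2 = fc.Spectrum(wn[::-1], ab[::-1])
        np.testing.assert_array_equal(s.absorbance, s2.absorbance)

    @pytest.mark.parametrize(
        "wn, ab",
        [
            ([4000.0, 3998.0], [0.1]),  # length mismatch
            ([4000.0], [0.1]),  # too short
            ([4000.0, 3998.0, 3998.0], [0.1, 0.2, 0.3]),  # not strictly monotonic
            ([4000.0, 3998.0, 3999.0], [0.1, 0.2, 0.3]),  # direction change
            ([4000.0, 3998.0], [0.1, np.nan]),  # non-finite
        ],
    )
    def test_invalid_spectra_rejected(self, wn, ab):
        with pytest.raises(SpectrumError):
            fc.Spectrum(np.array(wn), np.array(ab))

    def test_spectrum_set_requires_common_grid(self):
        a = fc.Spectrum(np.array([4000.0, 3998.0]), np.array([0.1, 0.2]))
        b = fc.Spectrum(np.array([4000.0, 3996.0]), np.array([0.1, 0.2]))
        with pytest.raises(SpectrumError):
            fc.SpectrumSet([a, b])


class TestFileIO:
    def test_csv_rows_echoed_descending(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("4000,0.1\n3998,0.2\n3996,0.1\n")
        s = fc.read_spectrum(p, format="csv")
        assert len(s) == 3
        np.testing.assert_array_equal(s.wavenumbers, [4000.0, 3998.0, 3996.0])
        np.testing.assert_array_equal(s.absorbance, [0.1, 0.2, 0.1])

    def test_csv_ascending_gives_identical_spectrum(self, tmp_path):
        (tmp_path / "d.csv").write_text("4000,0.1\n3998,0.2\n3996,0.1\n")
        (tmp_path / "a.csv").write_text("3996,0.1\n3998,0.2\n4000,0.1\n")
        d = fc.read_spectrum(tmp_path / "d.csv")
        a = fc.read_spectrum(tmp_path / "a.csv")
        np.testing.assert_array_equal(d.wavenumbers, a.wavenumbers)
        np.testing.assert_array_equal(d.absorbance, a.absorbance)

    def test_csv_with_header_and_tabs(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("wavenumber\tabsorbance\n4000\t0.1\n3998\t0.2\n")
        s = fc.read_spectrum(p, format="csv")
        assert len(s) == 2

    @pytest.mark.parametrize("fmt", ["csv", "jcamp"])
    def test_write_read_round_trip(self, fmt, tmp_path, templates, grid):
        spec = fc.render_spectrum(templates[0], grid, fc.NoiseModel(seed=3))
        path = tmp_path / ("rt.csv" if fmt == "csv" else "rt.jdx")
        fc.write_spectrum(spec, path, format=fmt)
        back = fc.read_spectrum(path, format=fmt)
        np.testing.assert_array_equal(back.wavenumbers, spec.wavenumbers)
        assert np.max(np.abs(back.absorbance - spec.absorbance)) <= 1e-6

    def test_jcamp_xydata_affn(self, tmp_path):
        p = tmp_path / "x.jdx"
        p.write_text(
            "##TITLE=test\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
            "##FIRSTX=4000\n##LASTX=3990\n##DELTAX=-2\n##NPOINTS=6\n"
            "##XYDATA=(X++(Y..Y))\n"
            "4000 0.1 0.2 0.3\n3994 0.4 0.5 0.6\n##END=\n"
        )
        s = fc.read_spectrum(p, format="jcamp")
        assert len(s) == 6
        np.testing.assert_allclose(s.wavenumbers, [4000, 3998, 3996, 3994, 3992, 3990])
        np.testing.assert_allclose(s.absorbance, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_jcamp_compressed_data_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "sqz.jdx"
        p.write_text(
            "##TITLE=t\n##FIRSTX=4000\n##LASTX=3996\n##DELTAX=-2\n##NPOINTS=3\n"
            "##XYDATA=(X++(Y..Y))\n4000 A1J2K3\n##END=\n"
        )
        with pytest.raises(SpectrumError, match=r":7:"):
            fc.read_spectrum(p, format="jcamp")

    def test_missing_file_and_malformed_csv(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fc.read_spectrum(tmp_path / "nope.csv")
        p = tmp_path / "bad.csv"
        p.write_text("4000,0.1,9\n3998,0.2,9\n")
        with pytest.raises(SpectrumError, match="2 columns"):
            fc.read_spectrum(p, format="csv")


class TestAverageReplicates:
    def test_mean_of_identical_is_identity_and_midpoint(self, grid):
        s = fc.Spectrum(grid, np.full(grid.size, 0.3))
        m = fc.average_replicates([s, s, s])
        np.testing.assert_array_equal(m.absorbance, s.absorbance)
        assert m.meta["n_replicates"] == 3
        z = fc.Spectrum(grid, np.zeros(grid.size))
        o = fc.Spectrum(grid, np.ones(grid.size))
        np.testing.assert_array_equal(
            fc.average_replicates([z, o]).absorbance, np.full(grid.size, 0.5)
        )

    def test_noise_shrinks_as_sqrt_n(self):
        # Monte-Carlo oracle: std of the mean of 3 replicates ~ sigma/sqrt(3)
        rng = np.random.default_rng(11)
        wn = np.arange(3000.0, 1000.0, -2.0)
        truth = np.zeros(wn.size)
        reps = [fc.Spectrum(wn, truth + rng.normal(0, 0.01, wn.size)) for _ in range(3)]
        resid = fc.average_replicates(reps).absorbance - truth
        assert resid.std() == pytest.approx(0.01 / np.sqrt(3), rel=0.10)

    def test_mismatched_grids_rejected(self):
        a = fc.Spectrum(np.array([4000.0, 3998.0]), np.array([0.1, 0.2]))
        b = fc.Spectrum(np.array([4000.0, 3996.0]), np.array([0.1, 0.2]))
        with pytest.raises(SpectrumError):
            fc.average_replicates([a, b])
        with pytest.raises(SpectrumError):
            fc.average_replicates([])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(perm=st.permutations(range(4)))
    def test_permutation_invariant(self, perm):
        wn = np.arange(2000.0, 1000.0, -2.0)
        rng = np.random.default_rng(2)
        reps = [fc.Spectrum(wn, rng.normal(0.2, 0.05, wn.size)) for _ in range(4)]
        base = fc.average_replicates(reps).absorbance
        shuffled = fc.average_replicates([reps[i] for i in perm]).absorbance
        # permutation-invariant up to floating-point summation order
        np.testing.assert_allclose(shuffled, base, rtol=1e-12)


class TestAutobaseline:
    def test_constant_offset_removed(self, grid):
        s = fc.Spectrum(grid, np.full(grid.size, 0.3))
        out = fc.autobaseline(s, "rubberband")
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_linear_ramp_removed(self, grid):
        ramp = 1e-4 * (grid - grid.min())
        out = fc.autobaseline(fc.Spectrum(grid, ramp), "rubberband")
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_peak_on_ramp_recovered_within_1pct(self, grid):
        peak = fc.BandSpec(center=2300.0, fwhm=60.0, amplitude=0.5, shape="gaussian")
        clean = peak.profile(grid)
        ramp = 0.1 + 1e-4 * (grid - grid.min())
        out = fc.autobaseline(fc.Spectrum(grid, clean + ramp), "rubberband")
        assert out.absorbance.max() == pytest.approx(clean.max(), rel=0.01)

    @pytest.mark.parametrize("method", ["rubberband", "polynomial"])
    def test_idempotent(self, method, grid, templates):
        spec = fc.render_spectrum(templates[1], grid, fc.NoiseModel(seed=9))
        once = fc.autobaseline(spec, method)
        twice = fc.autobaseline(once, method)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-9)

    def test_rubberband_minimum_nonnegative(self, grid, templates):
        spec = fc.render_spectrum(templates[2], grid, fc.NoiseModel(seed=4))
        out = fc.autobaseline(spec, "rubberband")
        assert out.absorbance.min() >= -1e-9

    def test_invalid_degree_and_method(self, grid):
        s = fc.Spectrum(grid, np.zeros(grid.size))
        with pytest.raises(SpectrumError):
            fc.autobaseline(s, "polynomial", degree=-1)
        with pytest.raises(SpectrumError):
            fc.autobaseline(s, "polynomial", degree=grid.size)
        with pytest.raises(SpectrumError):
            fc.autobaseline(s, "savgol")
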