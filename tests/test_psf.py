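"""Image formation: channel normalization, interferometer nulls, pixelation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polarsliver import (
    InterferometerImperfections,
    OpticalConfig,
    amplitude_psf,
    dipole_pupil,
    get_engine,
    method_psf,
    pixelate,
    sliver_split,
)
from polarsliver.psf import METHODS, _CHANNEL_SPECS
from polarsliver.pupil import collected_energy, dipole_field_set, invert


class TestChannelSets:
    @pytest.mark.parametrize("method", METHODS)
    def test_on_axis_channels_sum_to_one(self, small_config, method):
        psf = method_psf(small_config, method)
        assert psf.total == pytest.approx(1.0, abs=1e-9)
        for ch in psf.channels:
            assert np.all(ch.values >= -1e-15)

    @pytest.mark.parametrize("method", METHODS)
    def test_offset_channels_sum_near_one(self, small_config, method):
        psf = method_psf(small_config, method, emitter_offset=(60.0, -40.0))
        assert psf.total == pytest.approx(1.0, abs=1e-3)

    def test_split_weights_are_exact_fractions(self):
        assert _CHANNEL_SPECS["SLIVER+DD"][0][1] == Fraction(1, 2)
        assert _CHANNEL_SPECS["SLIVER+DD"][1][1] == Fraction(1, 4)
        assert _CHANNEL_SPECS["PolarSLIVER"][1][1] == Fraction(1, 2)
        assert [w for _, w in _CHANNEL_SPECS["SLIVER"]] == [Fraction(1, 2)] * 2

    def test_sliver_dd_hybrid_dd_channel_carries_half(self, small_config):
        psf = method_psf(small_config, "SLIVER+DD")
        dd = next(ch for ch in psf.channels if ch.channel_label == "DD")
        assert dd.values.sum() == pytest.approx(0.5, abs=1e-9)

    def test_polar_sliver_sym_channel_is_null(self, small_config):
        """Azimuthal fields are odd ⇒ total destructive interference."""
        psf = method_psf(small_config, "PolarSLIVER")
        sym = next(ch for ch in psf.channels if ch.channel_label == "Sym-A")
        assert sym.values.sum() == pytest.approx(0.0, abs=1e-28)

    def test_dda_ddr_totals_match_pupil_fractions(self):
        """Channel totals approach the radial/azimuthal pupil energy split.

        The radial PSF has heavier power-law tails, so the agreement is
        field-of-view-truncation limited and improves with image size.
        """
        cfg = OpticalConfig(pupil_grid_n=41, image_size=100)
        fields, _ = dipole_field_set(cfg)
        e_r = sum(float(np.sum(np.abs(fields[j]["R"]) ** 2)) for j in "xyz")
        e_a = sum(float(np.sum(np.abs(fields[j]["A"]) ** 2)) for j in "xyz")
        psf = method_psf(cfg, "DDA+DDR")
        got_r = psf.channels[0].values.sum()
        got_a = psf.channels[1].values.sum()
        assert got_r / (got_r + got_a) == pytest.approx(e_r / (e_r + e_a), abs=5e-3)

    def test_unknown_method_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown method"):
            method_psf(small_config, "SPADE")


class TestSliverSplit:
    def test_even_field_has_null_asym(self, small_config):
        h = dipole_pupil(small_config, "x", "H").values
        sym, asym = sliver_split(h)
        assert np.max(np.abs(asym)) == 0
        np.testing.assert_array_equal(sym, h)

    def test_odd_field_has_null_sym(self, small_config):
        a = dipole_pupil(small_config, "y", "A").values
        sym, asym = sliver_split(a)
        assert np.max(np.abs(sym)) == 0
        np.testing.assert_array_equal(asym, a)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        phase=st.floats(-np.pi, np.pi),
        r=st.floats(0.05, 0.95),
        r2=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**16),
    )
    def test_energy_conserved_for_any_imperfection(self, phase, r, r2, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=(9, 9)) + 1j * rng.normal(size=(9, 9))
        imp = InterferometerImperfections(
            split_ratio=r, second_split_ratio=r2, phase=phase
        )
        sym, asym = sliver_split(h, imp)
        total = np.sum(np.abs(sym) ** 2 + np.abs(asym) ** 2)
        assert total == pytest.approx(np.sum(np.abs(h) ** 2), rel=1e-12)

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sliver_split(np.ones((8, 8), dtype=complex))


class TestPixelate:
    def test_constant_field_stays_constant(self):
        out = pixelate(np.full((12, 12), 3.5), 3)
        np.testing.assert_allclose(out, 3.5)

    def test_oversampling_one_is_identity(self):
        arr = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(pixelate(arr, 1), arr)

    def test_integral_conserved(self):
        rng = np.random.default_rng(3)
        arr = rng.random((20, 20))
        out = pixelate(arr, 2)
        assert out.sum() * 4 == pytest.approx(arr.sum(), rel=1e-14)

    def test_non_integer_refinement_rejected(self):
        with pytest.raises(ValueError, match="integer refinement"):
            pixelate(np.ones((10, 10)), 3)


class TestAmplitudePSF:
    def test_even_pupil_gives_even_amplitude(self, small_config):
        f = dipole_pupil(small_config, "x", "H")
        amp = amplitude_psf(small_config, f).values
        np.testing.assert_allclose(amp, invert(amp), rtol=0, atol=1e-12 * np.abs(amp).max())

    def test_shift_theorem(self, small_config):
        """Offsetting the emitter translates the intensity PSF."""
        f = dipole_pupil(small_config, "x", "H")
        shift_px = 6  # whole subpixels: exact comparison via roll
        dx = shift_px * small_config.subpixel_size
        i0 = np.abs(amplitude_psf(small_config, f).values) ** 2
        i1 = np.abs(amplitude_psf(small_config, f, (dx, 0.0)).values) ** 2
        rolled = np.roll(i0, shift_px, axis=1)
        core = np.s_[:, shift_px:]
        np.testing.assert_allclose(i1[core], rolled[core], rtol=0, atol=1e-9 * i0.max())

    def test_offset_outside_fov_rejected(self, small_config):
        f = dipole_pupil(small_config, "x", "H")
        with pytest.raises(ValueError, match="field of view"):
            amplitude_psf(small_config, f, (small_config.field_of_view, 0.0))

    def test_parseval_for_well_confined_field(self):
        """Image energy equals pupil energy when truncation is negligible."""
        from polarsliver.pupil import PupilField, make_grid

        cfg = OpticalConfig(pupil_grid_n=41, image_size=80)
        grid = make_grid(cfg)
        kmax = np.abs(grid.kx).max()
        KX, KY = np.meshgrid(grid.kx, grid.ky)
        h = np.exp(-((KX**2 + KY**2) * (4.0 / kmax) ** 2)).astype(complex)
        f = PupilField("x", "H", h, grid)
        amp = amplitude_psf(cfg, f).values
        img_energy = np.sum(np.abs(amp) ** 2) * cfg.subpixel_size**2
        pupil_energy = np.sum(np.abs(h) ** 2) * grid.dk**2 / (2 * np.pi) ** 2
        assert img_energy == pytest.approx(pupil_energy, rel=1e-6)

    def test_dd_psf_of_rotating_dipole_is_circular(self, small_config):
        """Pixels at exactly equal radii agree to < 1%.

        The 8 symmetry-equivalent pixels (±a, ±b)/(±b, ±a) all sit at the
        same distance from the axis, so circular symmetry makes them equal.
        """
        psf = method_psf(small_config, "DD").channels[0].values
        n = psf.shape[0]
        assert n % 2 == 0
        # pixel (a, b) offsets measured from the grid centre between pixels
        for a, b in ((0, 2), (1, 3), (2, 5), (0, 7)):
            vals = []
            for dy, dx in {(a, b), (b, a), (-a - 1, b), (b, -a - 1),
                           (a, -b - 1), (-b - 1, a), (-a - 1, -b - 1),
                           (-b - 1, -a - 1)}:
                vals.append(psf[n // 2 + dy, n // 2 + dx])
            vals = np.array(vals)
            assert vals.std() / vals.mean() < 0.01


class TestPolychromatic:
    def test_narrow_band_converges_to_monochromatic(self):
        mono = OpticalConfig(pupil_grid_n=31, image_size=24)
        band = mono.replace(bandwidth=0.5, n_wavelengths=5)
        p0 = method_psf(mono, "PolarSLIVER").channels[0].values
        p1 = method_psf(band, "PolarSLIVER").channels[0].values
        np.testing.assert_allclose(p1, p0, atol=2e-5 * p0.max())

    def test_bandwidth_fills_polar_sliver_null(self):
        """A chromatic VWP leaks even field into the symmetric channel."""
        from polarsliver import VWPModel

        cfg = OpticalConfig(pupil_grid_n=31, image_size=24, bandwidth=30.0,
                            n_wavelengths=5)
        vwp = VWPModel(design_wavelength=cfg.wavelength, ideal=False)
        psf = method_psf(cfg, "PolarSLIVER", vwp=vwp)
        sym = next(ch for ch in psf.channels if ch.channel_label == "Sym-A")
        assert sym.values.sum() > 1e-6
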