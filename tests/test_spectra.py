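"""Broadening, difference spectra, peak areas, band centers, histograms."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vibexciton as vx
from vibexciton.exciton import StickSpectrum
from vibexciton.spectra import BroadenedSpectrum


def gaussian(grid, center, sigma, area=1.0):
    return area / (sigma * np.sqrt(2 * np.pi)) * \
        np.exp(-0.5 * ((grid - center) / sigma) ** 2)


class TestBroadenEnsemble:
    def test_single_line_normalization(self):
        sticks = [StickSpectrum([1213.0], [2.5])]
        spec = vx.broaden_ensemble(sticks, (1100.0, 1320.0, 0.5),
                                   width_floor=3.0)
        assert spec.integral() == pytest.approx(2.5, rel=1e-6)

    def test_two_snapshot_width_convention(self):
        """Band at 1210/1214: center 1212, sigma = 2 x population std = 4."""
        sticks = [StickSpectrum([1210.0], [1.0]),
                  StickSpectrum([1214.0], [1.0])]
        spec = vx.broaden_ensemble(sticks, (1100.0, 1320.0, 0.5))
        expected = gaussian(spec.grid, 1212.0, 4.0)
        np.testing.assert_allclose(spec.values, expected, atol=1e-12)

    def test_width_floor_for_single_snapshot(self):
        sticks = [StickSpectrum([1200.0], [1.0])]
        spec = vx.broaden_ensemble(sticks, (1150.0, 1250.0, 0.5),
                                   width_floor=1.0)
        expected = gaussian(spec.grid, 1200.0, 1.0)
        np.testing.assert_allclose(spec.values, expected, atol=1e-12)

    def test_all_dark_lines_give_zero_spectrum(self):
        sticks = [StickSpectrum([1200.0, 1210.0], [0.0, 0.0])]
        spec = vx.broaden_ensemble(sticks, (1150.0, 1250.0, 0.5))
        assert np.all(spec.values == 0.0)

    def test_total_integral_matches_stick_sum(self, band_modes):
        cfg = vx.make_2d_sheet(3, 2, 30.0, band_modes)
        ens = vx.jitter_ensemble(cfg, 0.2, 0.1, 3.0, 5, seed=8)
        sticks = [vx.stick_spectrum(
            vx.diagonalize(vx.build_hamiltonian(s), s)) for s in ens]
        spec = vx.broaden_ensemble(sticks, (950.0, 1450.0, 0.5))
        mean_total = np.mean([s.intensities.sum() for s in sticks])
        assert spec.integral() == pytest.approx(mean_total, rel=1e-4)

    def test_mode_label_assignment_pools_bands(self):
        sticks = [StickSpectrum([1150.0, 1250.0], [1.0, 2.0],
                                labels=["lo", "hi"]),
                  StickSpectrum([1154.0, 1254.0], [1.0, 2.0],
                                labels=["lo", "hi"])]
        spec = vx.broaden_ensemble(sticks, (1050.0, 1350.0, 0.5),
                                   band_assignment="mode_label")
        expected = gaussian(spec.grid, 1152.0, 4.0, area=1.0) + \
            gaussian(spec.grid, 1252.0, 4.0, area=2.0)
        np.testing.assert_allclose(spec.values, expected, atol=1e-12)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            vx.broaden_ensemble([], (1000.0, 1100.0, 0.5))
        with pytest.raises(ValueError, match="equal"):
            vx.broaden_ensemble([StickSpectrum([1.0], [1.0]),
                                 StickSpectrum([1.0, 2.0], [1.0, 1.0])],
                                (0.0, 10.0, 0.5))
        with pytest.raises(ValueError, match="width"):
            vx.broaden_ensemble([StickSpectrum([1200.0], [1.0])],
                                (1100.0, 1300.0, 0.5), width_floor=0.0)


class TestDifferenceSpectrum:
    def test_identical_spectra_give_zero(self):
        grid = vx.wavenumber_grid(1100.0, 1280.0)
        spec = BroadenedSpectrum(grid, gaussian(grid, 1200.0, 5.0))
        dI = vx.difference_spectrum(spec, spec)
        assert np.all(dI.delta == 0.0)
        assert dI.window == (1100.0, 1280.0)

    def test_zero_couplings_give_zero_delta(self):
        """Dark dipoles: coupled pipeline reduces to the uncoupled one."""
        dark = vx.MonomerModeSet(("d",), np.array([1213.0]),
                                 np.array([[0.0, 0.0, 0.0]]))
        cfg = vx.make_2d_sheet(3, 3, 30.0, dark)
        ens = vx.jitter_ensemble(cfg, 0.2, 0.0, 4.0, 4, seed=2)
        grid = (1100.0, 1320.0, 0.5)
        I = vx.broaden_ensemble([vx.stick_spectrum(
            vx.diagonalize(vx.build_hamiltonian(s), s)) for s in ens], grid)
        I0 = vx.broaden_ensemble([vx.stick_spectrum(vx.uncoupled_states(s))
                                  for s in ens], grid)
        dI = vx.difference_spectrum(I, I0)
        np.testing.assert_allclose(dI.delta, 0.0, atol=1e-12)

    def test_dimer_signature(self, z_mode):
        """Coupled dimer: depletion at omega0, gain at the bright branch."""
        cfg = vx.make_2d_sheet(2, 1, 25.0, z_mode)
        H = vx.build_hamiltonian(cfg)
        J = H.matrix[0, 1]
        grid = (2800.0, 3050.0, 0.5)
        sticks_c = [vx.stick_spectrum(vx.diagonalize(H, cfg))]
        sticks_u = [vx.stick_spectrum(vx.uncoupled_states(cfg))]
        I = vx.broaden_ensemble(sticks_c, grid, width_floor=1.0)
        I0 = vx.broaden_ensemble(sticks_u, grid, width_floor=1.0)
        dI = vx.difference_spectrum(I, I0, window=(2800.0, 3050.0))
        at = lambda w: dI.delta[np.argmin(np.abs(dI.grid - w))]
        assert at(2918.0) < 0          # parent band depleted
        assert at(2918.0 + J) > 0      # bright exciton branch gains

    def test_grid_mismatch_rejected(self):
        a = BroadenedSpectrum(vx.wavenumber_grid(1100, 1280),
                              np.zeros(361))
        b = BroadenedSpectrum(vx.wavenumber_grid(1100.5, 1280.5),
                              np.zeros(361))
        with pytest.raises(ValueError, match="grid"):
            vx.difference_spectrum(a, b)


class TestPeakArea:
    def test_zero_spectrum(self):
        grid = vx.wavenumber_grid(1100, 1300)
        spec = BroadenedSpectrum(grid, np.zeros_like(grid))
        assert vx.integrate_peak_area(spec, 1118.0, 1266.5) == 0.0

    def test_linear_baseline_removes_straight_line(self):
        grid = vx.wavenumber_grid(1100, 1300)
        spec = BroadenedSpectrum(grid, 0.3 * grid - 100.0)
        area = vx.integrate_peak_area(spec, 1118.0, 1266.5)
        assert abs(area) <= 1e-10 * 1e3

    def test_unit_gaussian_area(self):
        grid = vx.wavenumber_grid(1100, 1300, 0.5)
        spec = BroadenedSpectrum(grid, gaussian(grid, 1200.0, 6.0))
        assert vx.integrate_peak_area(spec, 1118.0, 1266.5, baseline="none") \
            == pytest.approx(1.0, rel=1e-6)

    def test_window_outside_grid_rejected(self):
        grid = vx.wavenumber_grid(1100, 1300)
        spec = BroadenedSpectrum(grid, np.zeros_like(grid))
        with pytest.raises(ValueError, match="outside"):
            vx.integrate_peak_area(spec, 1000.0, 1200.0)


class TestBandCenters:
    def test_single_gaussian(self):
        grid = vx.wavenumber_grid(1100, 1320, 0.5)
        spec = BroadenedSpectrum(grid, gaussian(grid, 1213.0, 5.0))
        assert vx.find_band_centers(spec, 1) == [1213.0]

    def test_three_band_synthesis(self):
        """Synthetic three-band C–F spectrum: centers recovered on-grid."""
        grid = vx.wavenumber_grid(1100, 1320, 0.5)
        truth = [1254.0, 1214.0, 1153.0]
        vals = sum(gaussian(grid, c, 7.0, area=a)
                   for c, a in zip(truth, (0.6, 1.0, 0.5)))
        centers = vx.find_band_centers(BroadenedSpectrum(grid, vals), 3)
        np.testing.assert_allclose(centers, truth, atol=0.5)

    def test_flat_spectrum_warns_and_returns_empty(self):
        grid = vx.wavenumber_grid(1100, 1320, 0.5)
        spec = BroadenedSpectrum(grid, np.zeros_like(grid))
        with pytest.warns(UserWarning):
            assert vx.find_band_centers(spec, 2) == []

    def test_fewer_peaks_than_requested_warns(self):
        grid = vx.wavenumber_grid(1100, 1320, 0.5)
        spec = BroadenedSpectrum(grid, gaussian(grid, 1200.0, 5.0))
        with pytest.warns(UserWarning, match="found only"):
            centers = vx.find_band_centers(spec, 3)
        assert centers == [1200.0]


class TestHistogram:
    def test_single_state_single_cell(self, aa_mode):
        cfg = vx.make_2d_sheet(1, 1, 36.0, aa_mode)
        states = vx.uncoupled_states(cfg)
        h = vx.energy_intensity_histogram(
            [states], np.arange(2900, 2940, 2.0), np.linspace(0, 0.1, 11))
        assert h.counts.sum() == 1.0
        assert np.count_nonzero(h.counts) == 1

    def test_uncoupled_zero_disorder_single_column(self, aa_mode):
        cfg = vx.make_2d_sheet(3, 3, 36.0, aa_mode)
        states = vx.uncoupled_states(cfg)
        h = vx.energy_intensity_histogram(
            [states], np.arange(2900, 2940, 2.0), np.linspace(0, 0.1, 11))
        assert h.occupied_energy_columns() == 1

    def test_coupling_spreads_energy_columns(self, aa_mode):
        cfg = vx.make_2d_sheet(5, 5, 25.0, aa_mode,
                               orientation_policy="random", seed=4)
        coupled = vx.diagonalize(vx.build_hamiltonian(cfg), cfg)
        uncoupled = vx.uncoupled_states(cfg)
        e = np.arange(2880.0, 2960.0, 2.0)
        i = np.linspace(0.0, 1.0, 30)
        hc = vx.energy_intensity_histogram([coupled], e, i)
        hu = vx.energy_intensity_histogram([uncoupled], e, i)
        assert hc.occupied_energy_columns() > hu.occupied_energy_columns()

    def test_paired_difference_variant(self, aa_mode):
        cfg = vx.make_2d_sheet(3, 3, 25.0, aa_mode)
        coupled = vx.diagonalize(vx.build_hamiltonian(cfg), cfg)
        uncoupled = vx.uncoupled_states(cfg)
        e = np.arange(2880.0, 2960.0, 2.0)
        d = np.linspace(-0.7, 0.7, 41)
        h = vx.energy_intensity_histogram([coupled], e, d,
                                          paired_uncoupled=[uncoupled])
        assert h.counts.sum() == pytest.approx(coupled.n_states, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vx.energy_intensity_histogram([], np.arange(3), np.arange(3))


class TestWeakModeFraction:
    def test_worked_example(self):
        sticks = StickSpectrum([1, 2, 3, 4], [10.0, 0.5, 0.5, 5.0])
        assert vx.weak_mode_fraction(sticks) == 0.5

    def test_all_equal_intensities(self):
        sticks = StickSpectrum([1, 2, 3], [2.0, 2.0, 2.0])
        assert vx.weak_mode_fraction(sticks) == 0.0

    @pytest.mark.parametrize("n_dark", [1, 9, 99])
    def test_one_bright_many_dark(self, n_dark):
        sticks = StickSpectrum(np.arange(n_dark + 1.0),
                               np.r_[5.0, np.zeros(n_dark)])
        assert vx.weak_mode_fraction(sticks) == \
            pytest.approx(n_dark / (n_dark + 1))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_invariant_under_rescaling(self, scale):
        intens = np.array([10.0, 0.5, 0.5, 5.0, 0.01])
        a = vx.weak_mode_fraction(StickSpectrum(np.arange(5.0), intens))
        b = vx.weak_mode_fraction(StickSpectrum(np.arange(5.0),
                                                intens * scale))
        assert a == b

    def test_all_dark_rejected(self):
        with pytest.raises(ValueError, match="all-dark"):
            vx.weak_mode_fraction(StickSpectrum([1.0, 2.0], [0.0, 0.0]))


class TestReflectanceAbsorbance:
    def test_known_values(self):
        R0 = np.array([0.4, 0.4, 0.4])
        Rm = np.array([0.4, 0.2, 4.0])
        ra = vx.reflectance_absorbance(Rm, R0)
        np.testing.assert_allclose(ra, [0.0, np.log10(2.0), -1.0],
                                   rtol=1e-12)

    def test_nonpositive_reflectivity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            vx.reflectance_absorbance([0.0, 1.0], [1.0, 1.0])


class TestSpreadInvariant:
    def test_coupled_never_narrower_for_parallel_sheets(self, aa_mode):
        """Intensity-weighted variance: coupled >= uncoupled (parallel dipoles).

        Holds for positional/orientational disorder; site-frequency
        disorder is excluded because exchange narrowing can legitimately
        shrink the coupled lineshape below the uncoupled one.
        """
        for area in (25.0, 36.0, 60.0):
            cfg = vx.make_2d_sheet(4, 4, area, aa_mode)
            ens = vx.jitter_ensemble(cfg, 0.2, 0.05, 0.0, 6, seed=13)
            grid = (2800.0, 3050.0, 0.5)
            I = vx.broaden_ensemble([vx.stick_spectrum(
                vx.diagonalize(vx.build_hamiltonian(s), s))
                for s in ens], grid)
            I0 = vx.broaden_ensemble([vx.stick_spectrum(
                vx.uncoupled_states(s)) for s in ens], grid)
            assert I.moments()[1] >= I0.moments()[1] - 1e-9
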