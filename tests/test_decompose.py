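"""FSD, derivative peak picking and staged band fitting."""

import numpy as np
import pytest

from protamide.bands import BandComponent, pseudo_voigt_profile
from protamide.decompose import (
    FitConfig,
    FsdConfig,
    component_area,
    fit_bands,
    fsd,
    locate_bands,
    measure_fwhm,
    pick_peaks,
    second_derivative,
)
from protamide.spectra import Spectrum
from protamide.synthetic import synthesize_spectrum


def lorentzian(grid, center, fwhm, area=1.0):
    return synthesize_spectrum([BandComponent(center, fwhm, area, 1.0)], grid)


class TestFsd:
    grid = np.arange(1200.0, 2200.25, 0.5)

    def test_enhancement_one_is_identity(self):
        s = lorentzian(self.grid, 1700.0, 14.0)
        out = fsd(s, FsdConfig(assumed_fwhm=14.0, enhancement=1.0))
        assert np.allclose(out.intensities, s.intensities, rtol=1e-6, atol=1e-12)

    def test_matched_lorentzian_narrowed_by_two(self):
        s = lorentzian(self.grid, 1700.0, 14.0)
        out = fsd(s, FsdConfig(assumed_fwhm=14.0, enhancement=2.0))
        width = measure_fwhm(self.grid, out.intensities)
        assert width == pytest.approx(7.0, abs=0.7)
        area_in = np.trapezoid(s.intensities, self.grid)
        area_out = np.trapezoid(out.intensities, self.grid)
        assert area_out == pytest.approx(area_in, rel=0.01)
        centre = self.grid[np.argmax(out.intensities)]
        assert abs(centre - 1700.0) <= 0.5

    def test_resolves_two_overlapped_lorentzians(self):
        s = synthesize_spectrum(
            [BandComponent(1652.0, 14.0, 1.0, 1.0), BandComponent(1642.0, 14.0, 1.0, 1.0)],
            self.grid,
        )
        # effectively unresolved before deconvolution: the central dip is
        # within ~3% of the peaks
        m = (self.grid > 1620) & (self.grid < 1675)
        from scipy.signal import find_peaks

        y = s.intensities[m]
        mid = y[(self.grid[m] > 1644) & (self.grid[m] < 1650)].min()
        assert mid > 0.96 * y.max()
        out = fsd(s, FsdConfig(assumed_fwhm=14.0, enhancement=2.0))
        after, _ = find_peaks(out.intensities[m],
                              prominence=0.1 * out.intensities[m].max())
        found = self.grid[m][after]
        assert len(found) == 2
        assert np.min(np.abs(found - 1652.0)) <= 1.0
        assert np.min(np.abs(found - 1642.0)) <= 1.0
        dip = out.intensities[m][(self.grid[m] > 1644) & (self.grid[m] < 1650)].min()
        assert dip < 0.8 * out.intensities[m].max()

    def test_area_conserved_for_lorentzian_sums(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            bands = [
                BandComponent(float(c), 14.0, float(a), 1.0)
                for c, a in zip(rng.uniform(1550, 1850, 4), rng.uniform(5, 40, 4))
            ]
            s = synthesize_spectrum(bands, self.grid)
            out = fsd(s, FsdConfig(assumed_fwhm=14.0, enhancement=2.0))
            assert np.trapezoid(out.intensities, self.grid) == pytest.approx(
                np.trapezoid(s.intensities, self.grid), rel=0.01
            )

    def test_non_uniform_grid_rejected(self):
        g = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(ValueError, match="uniform"):
            fsd(Spectrum(g, np.zeros_like(g)), FsdConfig())


class TestSecondDerivative:
    def test_quadratic_gives_constant(self, uniform_grid):
        a = 0.002
        s = Spectrum(uniform_grid, a * uniform_grid ** 2)
        d2 = second_derivative(s)
        assert np.allclose(d2.intensities[10:-10], 2 * a, rtol=1e-8)

    def test_line_gives_zero(self, uniform_grid):
        s = Spectrum(uniform_grid, 3.0 * uniform_grid - 5.0)
        d2 = second_derivative(s)
        assert np.allclose(d2.intensities, 0.0, atol=1e-9)

    def test_gaussian_minimum_at_centre(self, uniform_grid):
        s = synthesize_spectrum([BandComponent(1650.0, 20.0, 5.0, 0.0)], uniform_grid)
        d2 = second_derivative(s)
        at_min = uniform_grid[np.argmin(d2.intensities)]
        assert abs(at_min - 1650.0) <= 0.5

    def test_even_window_rejected(self, uniform_grid):
        s = Spectrum(uniform_grid, np.zeros_like(uniform_grid))
        with pytest.raises(ValueError, match="odd"):
            second_derivative(s, window_pts=14)


class TestPickPeaks:
    def test_flat_spectrum_empty(self, uniform_grid):
        s = Spectrum(uniform_grid, np.zeros_like(uniform_grid))
        assert pick_peaks(s, (1550, 1750)) == []

    def test_two_separated_bands(self, uniform_grid):
        s = synthesize_spectrum(
            [BandComponent(1620.0, 12.0, 5.0, 0.3), BandComponent(1700.0, 12.0, 5.0, 0.3)],
            uniform_grid,
        )
        centres = pick_peaks(s, (1550, 1750))
        assert len(centres) == 2
        assert centres[0] == pytest.approx(1700.0, abs=1.0)  # descending order
        assert centres[1] == pytest.approx(1620.0, abs=1.0)

    def test_close_peaks_merged(self, uniform_grid):
        s = synthesize_spectrum(
            [BandComponent(1650.0, 4.0, 5.0, 0.0), BandComponent(1653.0, 4.0, 5.0, 0.0)],
            uniform_grid,
        )
        centres = pick_peaks(s, (1550, 1750), min_prominence_frac=0.001)
        assert len(centres) == 1
        assert centres[0] == pytest.approx(1651.5, abs=1.0)

    def test_empty_region_rejected(self, uniform_grid):
        s = Spectrum(uniform_grid, np.zeros_like(uniform_grid))
        with pytest.raises(ValueError, match="empty"):
            pick_peaks(s, (900, 950))


class TestLocateBands:
    def test_salmine_fixture_five_centres(self, salmine_fixture):
        """Deconvolution + second derivative find all five generating bands."""
        from protamide.pipeline import PipelineConfig, _prepare

        nucleus, dna, truth = salmine_fixture
        s, _ = _prepare(PipelineConfig(outdir=""), nucleus, dna)
        wide = Spectrum(
            s.wavenumbers[(s.wavenumbers >= 1550) & (s.wavenumbers <= 1760)],
            s.intensities[(s.wavenumbers >= 1550) & (s.wavenumbers <= 1760)],
        )
        centres = locate_bands(wide, FsdConfig(assumed_fwhm=16.0, enhancement=3.0))
        assert len(centres) == 5
        for expected in (1674.0, 1663.0, 1652.0, 1642.0, 1609.0):
            assert min(abs(c - expected) for c in centres) <= 2.0


class TestComponentArea:
    @pytest.mark.parametrize(
        "height,fwhm,mix,expected",
        [
            (1.0, 10.0, 0.0, 10.6447),
            (1.0, 10.0, 1.0, 15.70796),
            (0.0, 10.0, 0.5, 0.0),
        ],
    )
    def test_closed_forms(self, height, fwhm, mix, expected):
        assert component_area(height, fwhm, mix) == pytest.approx(expected, abs=2e-4)

    def test_matches_numeric_integration(self):
        grid = np.arange(-4000.0, 4000.0, 0.01)
        for mix in (0.0, 0.3, 1.0):
            w = 12.0
            gauss = np.exp(-4 * np.log(2) * (grid / w) ** 2)
            lor = 1.0 / (1.0 + 4 * (grid / w) ** 2)
            y = (1 - mix) * gauss + mix * lor
            assert np.trapezoid(y, grid) == pytest.approx(
                component_area(1.0, w, mix), rel=0.001
            )


class TestFitBands:
    grid = np.arange(1550.0, 1750.25, 0.5)

    def _spectrum(self, bands):
        return synthesize_spectrum(bands, self.grid)

    def test_two_band_exact_recovery(self):
        truth = [BandComponent(1650.0, 16.0, 20.0, 0.3),
                 BandComponent(1665.0, 18.0, 10.0, 0.3)]
        s = self._spectrum(truth)
        cfg = FitConfig(region=(1595.0, 1700.0))
        fit = fit_bands(s, [1650.0, 1665.0], cfg)
        peak = float(s.intensities.max())
        assert fit.residual_rms < 1e-6 * peak
        got = sorted(fit.components, key=lambda b: b.center)
        for b, t in zip(got, truth):
            assert b.area == pytest.approx(t.area, rel=0.001)
            assert b.center == pytest.approx(t.center, abs=0.05)

    def test_single_band_recovery(self):
        truth = [BandComponent(1652.0, 14.0, 30.0, 0.4)]
        fit = fit_bands(self._spectrum(truth), [1652.0])
        assert fit.components[0].area == pytest.approx(30.0, rel=0.001)
        assert fit.components[0].mix == pytest.approx(0.4, abs=0.01)

    def test_init_outside_region_rejected(self):
        s = self._spectrum([BandComponent(1650.0, 14.0, 30.0, 0.3)])
        with pytest.raises(ValueError, match="outside fit region"):
            fit_bands(s, [1750.0], FitConfig(region=(1595.0, 1700.0)))

    def test_rms_non_increasing_across_stages(self, salmine_run, squid_run):
        for fit, _, _, _ in (salmine_run, squid_run):
            r = fit.rms_per_stage
            assert r[0] >= r[1] >= r[2]

    def test_displaced_inits_walk_to_truth(self):
        """Centres more than the bound away are reached by bound walking."""
        truth = [BandComponent(1640.0, 24.0, 25.0, 0.3),
                 BandComponent(1652.0, 16.0, 40.0, 0.3)]
        s = self._spectrum(truth)
        fit = fit_bands(s, [1630.0, 1652.0])
        got = sorted(fit.components, key=lambda b: b.center)
        assert got[0].center == pytest.approx(1640.0, abs=0.2)
        assert got[0].area == pytest.approx(25.0, rel=0.01)
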