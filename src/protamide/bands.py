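"""Pseudo-Voigt band model shared by the generator and the fitter.

A band is parameterized by centre, full width at half maximum (FWHM),
integrated area and a Gauss-Lorentz mixing fraction ``mix`` (0 = pure
Gaussian, 1 = pure Lorentzian).  The profile is the area-weighted sum of
a unit-area Gaussian and a unit-area Lorentzian of equal FWHM, the
standard band shape for amide I decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandComponent", "pseudo_voigt_profile", "component_area"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class BandComponent:
    """One spectral component band.

    center : cm^-1; fwhm : cm^-1 (> 0); area : a.u.*cm^-1 (>= 0);
    mix : Gauss-Lorentz fraction in [0, 1].
    """

    center: float
    fwhm: float
    area: float
    mix: float = 0.3

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if not 0.0 <= self.mix <= 1.0:
            raise ValueError(f"mix must be in [0, 1], got {self.mix}")

    @property
    def height(self) -> float:
        """Peak height at the band centre."""
        g = (2.0 / self.fwhm) * np.sqrt(_LN2 / np.pi)
        l = 2.0 / (np.pi * self.fwhm)
        return self.area * ((1.0 - self.mix) * g + self.mix * l)


def pseudo_voigt_profile(grid: np.ndarray, band: BandComponent) -> np.ndarray:
    """Evaluate the band on ``grid``; integrates to ``band.area``."""
    grid = np.asarray(grid, dtype=float)
    u = (grid - band.center) / band.fwhm
    gauss = (2.0 / band.fwhm) * np.sqrt(_LN2 / np.pi) * np.exp(-4.0 * _LN2 * u * u)
    lor = (2.0 / (np.pi * band.fwhm)) / (1.0 + 4.0 * u * u)
    return band.area * ((1.0 - band.mix) * gauss + band.mix * lor)


def component_area(height: float, fwhm: float, mix: float) -> float:
    """Area of a height-parameterized pseudo-Voigt band.

    For the unit-height mixture ``h * [(1-mix) g(nu) + mix l(nu)]`` with
    unit-height Gaussian/Lorentzian of equal FWHM:
    ``area = h * w * [(1-mix)/2 * sqrt(pi/ln 2) + mix * pi/2]``.
    """
    return height * fwhm * (
        (1.0 - mix) * 0.5 * np.sqrt(np.pi / _LN2) + mix * np.pi / 2.0
    )
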