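"""Synthetic sperm-nucleus spectra with known ground truth.

Experimental nucleoprotamine FTIR spectra are not publicly deposited, so
recovery tests run on synthetic nuclei assembled from the published band
inventory: four amide I' component bands per protamine (positions and
relative areas as reported for salmon protamine and squid protamine in
140 mM NaCl), an arginine side-chain band at 1609 cm^-1 (larger for
squid, which also has tyrosine absorbance nearby), a DNA contribution
carrying the symmetric phosphate marker band at 1087 cm^-1 plus
base-carbonyl absorbance inside the amide region, a linear baseline and
additive Gaussian noise.

The generator's defaults are the study conditions: band widths are
chosen so that neighbouring components merge into one smooth amide I'
envelope (as observed experimentally) yet remain separable by Fourier
self-deconvolution, and the mixing fraction is the common 0.3
Gauss-Lorentz value of amide I practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandComponent, pseudo_voigt_profile
from .spectra import Spectrum

__all__ = [
    "FixtureTruth",
    "synthesize_spectrum",
    "dna_reference",
    "make_nucleus_fixture",
    "synthesize_cd",
    "FIXTURE_BANDS",
    "SYNTHETIC_SEQUENCES",
]

# (center cm^-1, relative area) per protamine, plus the published class
# percentages they imply. Default widths: turns 18, helix 16, coil 24.
FIXTURE_BANDS = {
    "salmine": {
        "protein": [
            BandComponent(1674.0, 18.0, 16.0, 0.3),
            BandComponent(1663.0, 18.0, 22.0, 0.3),
            BandComponent(1652.0, 16.0, 20.0, 0.3),
            BandComponent(1642.0, 24.0, 42.0, 0.3),
        ],
        "side_chain": [BandComponent(1609.0, 16.0, 25.0, 0.3)],
        "percentages": {"turns": 38.0, "alpha_helix": 20.0, "random_coil": 42.0},
    },
    "squid": {
        "protein": [
            BandComponent(1669.0, 18.0, 17.0, 0.3),
            BandComponent(1662.0, 18.0, 20.0, 0.3),
            BandComponent(1650.0, 16.0, 40.0, 0.3),
            BandComponent(1640.0, 24.0, 23.0, 0.3),
        ],
        "side_chain": [BandComponent(1609.0, 16.0, 40.0, 0.3)],
        "percentages": {"turns": 37.0, "alpha_helix": 40.0, "random_coil": 23.0},
    },
}

#: Synthetic stand-in protamine sequences. These are NOT the published
#: sequences (which appear only in a figure not distributed with the
#: text); they are constructed to match the stated length and
#: composition: salmine-like 32 residues with 21 Arg (~66%) and 3 Pro in
#: short arginine tracks; Sp2-like 58 residues with 46 Arg (79.3%),
#: 4 Tyr and 1 Pro in longer tracks.
SYNTHETIC_SEQUENCES = {
    # 32 residues, 21 Arg (65.6%), 3 Pro
    "salmine_synthetic": "PRRRRSSRPVRRRRRRGGRRRRSPVRRRRRRA",
    # 58 residues, 46 Arg (79.3%), 4 Tyr, 1 Pro
    "sp2_synthetic": "ARRRRRRYGRRRRRRRYRRRRRRRRPSRRRRRRRYGRRRRRRRSKRRRRRRYVRRRRR",
}


@dataclass
class FixtureTruth:
    """Generating parameters of a synthetic nucleus spectrum."""

    name: str
    protein_bands: list
    side_chain_bands: list
    dna_scale: float
    true_percentages: dict
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.true_percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"true percentages sum to {total}, not 100")


def synthesize_spectrum(bands, grid, baseline=(0.0, 0.0), noise_sd: float = 0.0,
                        seed: int = 0, axis_label: str = "absorbance") -> Spectrum:
    """Sum of band profiles + linear baseline + i.i.d. Gaussian noise.

    ``baseline`` is ``(slope, intercept)`` in intensity units per cm^-1.
    The grid must be uniform; the same seed reproduces the same trace.
    """
    grid = np.asarray(grid, dtype=float)
    d = np.diff(grid)
    if not np.allclose(d, d[0], rtol=1e-8, atol=0.0):
        raise ValueError("synthesize_spectrum requires a uniform grid")
    slope, intercept = baseline
    y = slope * grid + intercept
    for band in bands:
        y = y + pseudo_voigt_profile(grid, band)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, y, axis_label)


DNA_BANDS = (
    BandComponent(1087.0, 20.0, 1.0, 0.5),   # symmetric phosphate stretch
    BandComponent(1665.0, 35.0, 0.5, 0.3),   # base carbonyl, amide region
    BandComponent(1649.0, 30.0, 0.3, 0.3),
)


def dna_reference(grid) -> Spectrum:
    """Deterministic DNA reference spectrum on ``grid``.

    Carries the 1087 cm^-1 phosphate marker band used to scale the DNA
    subtraction, plus base-carbonyl bands inside the amide I' region so
    that skipping the subtraction visibly biases the protein envelope.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 1040.0 or grid[-1] < 1700.0:
        raise ValueError("dna_reference grid must span at least 1040-1700 cm^-1")
    return synthesize_spectrum(DNA_BANDS, grid)


def make_nucleus_fixture(name: str, dna_scale: float = 0.7, noise_sd: float = 0.0,
                         seed: int = 0):
    """Build a synthetic nucleus spectrum with known decomposition.

    Returns ``(nucleus, dna_ref, truth)``.  The nucleus is
    protein + side chain + dna_scale * DNA reference + noise on the grid
    1000-1800 cm^-1, step 0.5.
    """
    if name not in FIXTURE_BANDS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_BANDS)}")
    if dna_scale < 0:
        raise ValueError("dna_scale must be >= 0")
    spec = FIXTURE_BANDS[name]
    grid = np.arange(1000.0, 1800.0 + 0.25, 0.5)
    dna = dna_reference(grid)
    protein = spec["protein"]
    side = spec["side_chain"]
    clean = synthesize_spectrum(list(protein) + list(side), grid)
    y = clean.intensities + dna_scale * dna.intensities
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, grid.size)
    nucleus = Spectrum(grid, y)
    truth = FixtureTruth(
        name=name,
        protein_bands=list(protein),
        side_chain_bands=list(side),
        dna_scale=dna_scale,
        true_percentages=dict(spec["percentages"]),
        noise_sd=noise_sd,
        seed=seed,
    )
    return nucleus, dna, truth


def synthesize_cd(helix_pct: float, n_bonds: int, grid=None) -> Spectrum:
    """Synthetic far-UV CD trace with a prescribed helicity.

    The mean-residue ellipticity at 222 nm is set exactly to the value
    the Chen relation assigns to ``helix_pct`` for a chain with
    ``n_bonds`` peptide bonds; the spectral shape away from 222 nm is a
    schematic double-minimum helix signature.
    """
    if n_bonds < 3:
        raise ValueError("n_bonds must be >= 3")
    if not 0.0 <= helix_pct <= 100.0:
        raise ValueError("helix_pct must be in [0, 100]")
    if grid is None:
        grid = np.arange(190.0, 260.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    theta222 = -395.0 * helix_pct * (1.0 - 2.57 / n_bonds)
    # two negative lobes (208, 222 nm) and a positive band near 193 nm
    shape = (
        -np.exp(-0.5 * ((grid - 222.0) / 9.0) ** 2)
        - 0.95 * np.exp(-0.5 * ((grid - 208.0) / 7.0) ** 2)
        + 1.6 * np.exp(-0.5 * ((grid - 193.0) / 6.0) ** 2)
    )
    at222 = (
        -1.0
        - 0.95 * np.exp(-0.5 * ((222.0 - 208.0) / 7.0) ** 2)
        + 1.6 * np.exp(-0.5 * ((222.0 - 193.0) / 6.0) ** 2)
    )
    y = shape * (theta222 / at222) if theta222 != 0.0 else np.zeros_like(grid)
    return Spectrum(grid, y, axis_label="mean residue ellipticity (deg cm2 dmol-1)")
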