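# Methods

This note documents the models, parameter choices and numerical
behaviour of `protamide`, including the limits of what the synthetic
fixtures establish.

## Spectral model

Every component band is a pseudo-Voigt profile: the area-weighted sum
of a unit-area Gaussian and a unit-area Lorentzian of equal FWHM,
`f(ν) = A·[(1−m)·G(ν) + m·L(ν)]`, with mixing fraction `m ∈ [0,1]`
(0 = Gaussian).  This is the standard empirical line shape for
condensed-phase amide I work; the mixing fraction absorbs the unknown
balance of homogeneous and inhomogeneous broadening.  A spectrum is
modelled as a sum of such bands plus a linear baseline.

`component_area(height, fwhm, mix)` converts the alternative
height-parameterized convention (unit-*height* mixture) to an area:
`A = h·w·[(1−m)·√(π/ln2)/2 + m·π/2]`.

## Synthetic nucleus fixtures

Experimental nucleoprotamine spectra are not deposited anywhere, so
recovery tests run on synthetic nuclei with known decomposition.  The
fixture band inventories encode the published amide I' decomposition of
salmon and squid protamine in sperm nuclei at physiological salt:

| fixture  | turns          | α-helix   | random coil | side chain |
|----------|----------------|-----------|-------------|------------|
| salmine  | 1674 (16), 1663 (22) | 1652 (20) | 1642 (42) | 1609 (25) |
| squid    | 1669 (17), 1662 (20) | 1650 (40) | 1640 (23) | 1609 (40) |

(centre cm⁻¹, relative area in % of amide total).  Widths and shape are
not reported anywhere and are generator design choices: FWHM 18 cm⁻¹
for turn bands, 16 for helix, 24 for random coil, 16 for the side
chain, mixing 0.3 throughout — wide enough that neighbouring bands
merge into one smooth envelope (as in the experimental spectra), narrow
enough to be separable by self-deconvolution.  The side-chain band is
larger for squid (40 vs 25 per 100 amide units), reflecting its higher
arginine content plus tyrosine absorbance at 1614 cm⁻¹; only the
ordering, not the magnitude, has experimental support.

The DNA reference carries the symmetric phosphate stretch at 1087 cm⁻¹
(FWHM 20, unit area, mixing 0.5) and two invented base-carbonyl bands
inside the amide region (1665/0.5 and 1649/0.3) whose presence makes
the subtraction step consequential.  A nucleus spectrum is
protein + side chain + `dna_scale`·DNA + linear baseline + i.i.d.
Gaussian noise on the grid 1000–1800 cm⁻¹, step 0.5 cm⁻¹ (covers the
marker band and amide I' in one trace); fixtures are deterministic
given (name, dna_scale, noise_sd, seed).

What the fixtures deliberately do **not** model: H/D exchange kinetics,
water-vapour rotational lines, Mie scattering, detector nonlinearity,
or any mismatch between the DNA reference and the DNA actually in the
nucleus.  Passing recovery tests therefore shows the *algorithm chain*
is correct and self-consistent, not that real spectra decompose this
cleanly.

The packaged protamine sequences are synthetic stand-ins (flagged
`*_synthetic`): the real sequences are published only as a figure, so
the stand-ins reproduce the reported composition — 32 residues with
21 Arg and 3 Pro in short tracks (salmine-like), 58 residues with
46 Arg (79.3%), 4 Tyr, 1 Pro in longer tracks (Sp2-like) — but not the
actual residue order.

## DNA subtraction

The subtraction weight cancels the marker-band area of the difference
spectrum.  `marker_band_area` integrates above a chord across
1087 ± 40 cm⁻¹; the chord anchors are window-edge values averaged over
5 cm⁻¹ so the estimate stays linear in the intensities but is robust to
point noise.  Linearity gives the closed-form weight
`area(nucleus)/area(reference)` and makes the post-subtraction marker
area zero identically; for a symmetric marker band this coincides (to
~1e-6 on tail-free mixtures) with the least-squares minimizer of the
windowed residual, which the tests use as an independent oracle.  With
protein Lorentzian tails reaching the window the two estimators differ
at the 1e-4 level — immaterial, since the DNA amide-region bands are
~1% of the protein area.  Baseline correction subtracts the line
through the mean points of two anchor windows flanking amide I'
(1588–1598 and 1702–1712 cm⁻¹).

## Self-deconvolution and band location

FSD multiplies the Fourier-domain signal by `exp(π·w·x)` (inverting a
Lorentzian decay of FWHM `w`, default 16 cm⁻¹) and a triangle-squared
apodization `(1−x/x_max)²`.  Instead of fixing analytic constants,
`x_max` is calibrated by root finding so that an isolated Lorentzian of
FWHM `w` comes out narrowed by exactly the enhancement factor `k`
(tolerance 10%); the calibration also measures the side-lobe amplitude
and rejects settings that ring beyond 20% of the peak.  Area is
conserved exactly at zero retardation.  Edge discontinuities are
suppressed by subtracting the endpoint-connecting line and zero-padding
4× before the FFT.

The attainable enhancement is SNR-limited (the boost at the
apodization edge amplifies noise by roughly `exp(π·w·x_max)`), so the
pipeline picks `k = log₁₀(SNR) − 0.3`, clipped to [1.5, 3], with the
noise level estimated robustly from second differences in the
band-free window 1730–1790 cm⁻¹; an explicitly configured `k`
overrides this.  For detection only, noisy spectra are pre-smoothed
with a 15-point cubic Savitzky–Golay filter.

Band centres are the minima of the 9-point Savitzky–Golay second
derivative of the deconvolved trace, picked by prominence (8% of the
regional maximum) inside 1599–1691 cm⁻¹ — inset from the fit region so
deconvolution edge artefacts cannot seed bands — and merged when closer
than 4 cm⁻¹.  The derivative-of-FSD detector is deliberate: the
dominant random-coil band never becomes a local *maximum* of the
deconvolved trace at these widths (it hides under the helix band), but
its curvature minimum is clear.

## Staged fitting and its acceptance gate

`fit_bands` fits the original (not deconvolved) envelope over
1595–1700 cm⁻¹, a region that includes the 1609 cm⁻¹ side-chain band so
its overlap with the amide bands is modelled rather than truncated:

* **Stage 1** — areas and baseline only; centres at the detected
  positions, widths 16 cm⁻¹, mixing 0.3.  Non-negative areas
  throughout.
* **Stage 2** — widths freed within [8, 40] cm⁻¹ plus one mixing
  fraction shared by all bands.
* **Stage 3** — centres freed within ±3 cm⁻¹ of their current values
  and per-band mixing untied.  While any centre sticks to a bound the
  bounds are re-centred and the solve repeated ("walking"), so a
  detection displaced by ~10 cm⁻¹ (the coil band under the squid helix)
  can still reach its true position.

Each stage starts from the previous optimum, so the per-stage rms is
non-increasing by construction.  Solutions use bounded trust-region
least squares; convergence is a relative cost reduction below 1e-10 or
1500 evaluations per solve.

Stage 3 is **gated**: its result replaces stage 2 only if it reduces
the squared residual at least four-fold.  On noiseless spectra the
centre refinement reduces the residual by many orders of magnitude and
is always accepted — recovery of the fixture percentages is then exact
to <1e-3 points.  At finite noise the free-centre fit merely reshuffles
parameters along a flat likelihood valley without beating the noise
floor, and the gate keeps the deconvolution-determined centres, which
is the stabler estimate (below).

Around the staged fit, `decompose_spectrum` iterates: a coherent
residual peak (prominence above 0.5% of the data maximum and 4× the
noise level, away from the region edges) adds a band at its position
and triggers a refit, up to four times; bands whose fitted area falls
below 0.2% of the total are pruned.  Fitted bands outside the
assignment coverage (1595–1696 cm⁻¹) are excluded from quantification
as edge artefacts.

## Quantification

Half-open assignment windows, chosen so the canonical positions fall in
their conventional classes: side chain [1595, 1616), β-sheet
[1616, 1638), random coil [1638, 1647), α-helix [1647, 1658), turns
[1658, 1696).  Class percentage = 100 × (class area) / (total
non-side-chain area); β-sheet is reported as 0 when no band falls in
its window rather than being undetectable.  Area fractions (not height
fractions) are used: with strongly overlapped bands, "percent of total
intensity" conventionally means integrated intensity.  The
high-wavenumber antiparallel β-sheet region (~1675–1695 cm⁻¹) overlaps
the turns window and maps to turns by default; the windows are
configurable.

## Noise and identifiability

The decomposition of four overlapped amide bands (separations
7–11 cm⁻¹ at FWHM 16–24 cm⁻¹) with free centres, widths and areas is
statistically degenerate at realistic noise.  At additive noise of
0.5% of the spectrum maximum, the Cramér–Rao bound at the true
parameters puts the standard deviation of the class percentages at
8–33 points (salmine) and 12–47 points (squid); empirically, a bounded
least-squares fit *started at the true parameters* drifts to mean
absolute class errors of 5–13 points, because coordinated
centre/width/area trades move area between classes at no cost in
residual.  Fixing the centres at their true positions collapses the
error to 0.2–0.5 points — but centre errors of ±1 cm⁻¹, the realistic
accuracy of any detector at the SNR-limited enhancement, already cost
3–7 points.  Per-class percentages at this noise level are therefore
reliable only to several points regardless of estimator; averaging over
repeated spectra (as routinely done experimentally by co-adding ~1000
scans) is the physical remedy, not a better fit.  The test suite
includes a 20-replicate noise-robustness check that documents this
behaviour.

## Chen helicity and sequences

`chen_helicity` implements %helix = 100·θ₂₂₂ / (−39500·(1 − 2.57/n))
with θ₂₂₂ the mean residue molar ellipticity at 222 nm
(deg·cm²·dmol⁻¹) and `n` the number of peptide bonds — residues − 1, a
classic off-by-one trap the CLI makes explicit by accepting
`--residues` and logging the conversion.  Values outside [0, 100] are
returned unclipped with a warning (they diagnose concentration or
path-length errors).  `helicity_to_theta222` is the exact inverse and
is used by the CD trace generator, which pins the 222 nm value exactly
and draws a schematic helix double-minimum shape elsewhere.
`arginine_tracks` returns maximal runs of R in order; track lengths sum
to the arginine count by construction.

## Numerical conventions

* Grids are stored ascending; descending files are reversed on read.
* Interpolation is linear only — band fitting, not interpolation, is
  the model of the data.
* csv2col files are written at full float precision (`repr`), so a
  write/read round trip is exact.
* All stochastic steps take explicit integer seeds
  (`numpy.random.default_rng`); fixtures and the pipeline are
  deterministic given their inputs, and output files embed a hash of
  the analysis configuration.
* FSD calibration results are memoized per (width, enhancement,
  spacing, length, tolerance).

## Known limitations

* The fit region boundary (1700 cm⁻¹) and the assignment coverage
  (1696 cm⁻¹) leave a 4 cm⁻¹ strip where a noise-driven band is fitted
  but not quantified; such bands are logged.
* JCAMP-DX support covers single-block `(X++(Y..Y))` tables only.
* The DNA subtraction assumes the reference matches the in-nucleus DNA
  spectrum up to a scale factor; no model for hypo/hyperchromicity or
  salt-dependent band shifts.
* The per-class noise sensitivity above means percentages from a single
  noisy spectrum should be quoted with several-point uncertainty.
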