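# protamide

Quantification of protamine secondary structure in sperm nuclei from
infrared spectra.

Protamines are small, extremely arginine-rich proteins that replace
histones and condense DNA in mature spermatozoa.  Whether the DNA-bound
protein carries secondary structure of its own is hard to probe: the
nucleoprotamine complex scatters light and resists crystallography, but
FTIR spectroscopy of whole nuclei is insensitive to turbidity.  The
amide I' band (the backbone C=O stretch measured in D₂O, 1600–1700 cm⁻¹)
is a superposition of component bands whose positions report
conformation: β-turns near 1660–1690 cm⁻¹, α-helix at the canonical
1652 cm⁻¹, random-coil/flexible regions near 1640 cm⁻¹, β-sheet at
1616–1638 cm⁻¹, plus an arginine side-chain band at 1609 cm⁻¹.

`protamide` implements the full analysis chain for such spectra:

1. **DNA subtraction** — the DNA reference spectrum is weighted so that
   the symmetric phosphate stretching band at 1087 cm⁻¹ cancels in the
   difference spectrum (the phosphate band is a pure DNA marker), then
   a linear baseline anchored outside the amide region is removed.
2. **Fourier self-deconvolution (FSD)** — band narrowing by dividing
   out an assumed Lorentzian decay in the retardation domain with a
   triangle-squared apodization; the cut-off is calibrated numerically
   so an isolated Lorentzian narrows by exactly the requested factor,
   and the factor itself adapts to the measured signal-to-noise ratio.
3. **Band location** — minima of the Savitzky–Golay second derivative
   of the deconvolved spectrum.
4. **Iterative curve fitting** — the *original* envelope is fitted as a
   sum of pseudo-Voigt bands plus a linear baseline by staged least
   squares (areas → widths and mixing → centres), growing bands from
   coherent fit residuals and pruning negligible ones.
5. **Quantification** — class percentages as area fractions of the
   total amide I' intensity, side-chain bands excluded.

Companion utilities cover CD helicity via the Chen relation,
%helix = 100·θ₂₂₂ / (−39500·(1 − 2.57/n)) with *n* the number of
peptide bonds, and protamine sequence statistics (residue composition,
arginine-track lengths).

Because no experimental nucleus spectra are publicly deposited, the
package ships a synthetic-data generator whose fixtures encode the
published decomposition of salmon protamine (salmine) and squid
protamine as ground truth; the pipeline is validated by recovering
those percentages from the raw synthetic spectra.

## Worked example

```sh
protamide simulate --fixture salmine --outdir fixture
protamide decompose fixture/nucleus.csv --dna-ref fixture/dna_ref.csv --outdir out
```

prints

```
dna_scale 0.699696
band  1609.00 cm-1  area    25.0000  side_chain
band  1642.00 cm-1  area    42.0000  random_coil
band  1652.00 cm-1  area    20.0000  alpha_helix
band  1663.00 cm-1  area    22.0003  turns
band  1674.00 cm-1  area    15.9999  turns
alpha_helix   20.00 %
beta_sheet     0.00 %
random_coil   42.00 %
turns         38.00 %
```

The DNA weight 0.6997 recovers the generating mixture (0.7; the small
deficit comes from protein band tails inside the marker window).  The
five fitted bands sit at the generating positions, and the class
percentages reproduce the fixture's ground truth — α-helix 20%, turns
16+22=38%, random coil 42%, no β-sheet — i.e. the salmon-protamine
decomposition.  `protamide simulate --fixture squid` gives the
helix-dominant squid pattern (40/37/23) the same way.

The Chen helicity utility:

```sh
$ protamide cd-helicity --theta222 -12316.6 --residues 32
using n = 31 peptide bonds (residues - 1)
helix 34.0 %
```

## Limitations

Class percentages from noiseless, well-modelled spectra are recovered
essentially exactly; at realistic noise levels the centre/width/area
trade-off of strongly overlapped bands becomes statistically degenerate
and per-class percentages carry errors of several points — see
`docs/methods.md` for the quantitative analysis and what the synthetic
fixtures do and do not establish about real spectra.
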