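"""Plain-text spectrum I/O and grid manipulation.

The :class:`Spectrum` container carries every trace handled by this
package: infrared absorbance spectra (wavenumber in cm^-1 vs. absorbance)
and circular-dichroism traces (wavelength in nm vs. mean residue
ellipticity).  Grids are stored ascending; files written in descending
order (the native direction of most FTIR exports) are reversed on read.

Two plain-text formats are supported: ``csv2col`` (two numeric columns,
comma or whitespace delimited, one optional header line) and a minimal
single-block ``##XYDATA=(X++(Y..Y))`` JCAMP-DX subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumError",
    "read_spectrum",
    "write_spectrum",
    "crop",
    "resample",
]


class SpectrumError(ValueError):
    """Raised for malformed spectrum files or invalid grid operations."""


@dataclass
class Spectrum:
    """A sampled trace: paired axis grid and intensity values.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing, finite axis values (cm^-1 for IR, nm for CD).
    intensities:
        Intensity at each grid point, same length as the grid.
    axis_label:
        Free-text unit tag, e.g. ``"absorbance"``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    axis_label: str = "absorbance"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        iy = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or iy.ndim != 1:
            raise SpectrumError("wavenumbers and intensities must be 1-D")
        if wn.size != iy.size:
            raise SpectrumError(
                f"grid/intensity length mismatch: {wn.size} vs {iy.size}"
            )
        if wn.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(iy))):
            raise SpectrumError("non-finite values in spectrum")
        if np.any(np.diff(wn) <= 0):
            if np.any(np.diff(wn) == 0) or np.unique(wn).size != wn.size:
                raise SpectrumError("duplicate wavenumber in grid")
            raise SpectrumError("grid must be strictly monotonic")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", iy)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Mean grid spacing (exact for uniform grids)."""
        return float((self.wavenumbers[-1] - self.wavenumbers[0]) / (len(self) - 1))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean())))

    def copy_with(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        self.axis_label)


def _parse_csv2col(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{lineno}: expected two columns")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1:  # single optional header line
                continue
            raise SpectrumError(f"{path}:{lineno}: non-numeric row {line!r}")
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def _parse_jcamp_simple(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a single-block ##XYDATA=(X++(Y..Y)) JCAMP-DX table."""
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_table = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                in_table = False
            header[key] = val.strip()
            continue
        if in_table and line:
            data_lines.append(line)
    if not data_lines:
        raise SpectrumError(f"{path}: no ##XYDATA table found")
    xfac = float(header.get("XFACTOR", "1"))
    yfac = float(header.get("YFACTOR", "1"))
    deltax = None
    if "DELTAX" in header:
        deltax = float(header["DELTAX"])
    elif {"FIRSTX", "LASTX", "NPOINTS"} <= header.keys():
        npts = int(float(header["NPOINTS"]))
        deltax = (float(header["LASTX"]) - float(header["FIRSTX"])) / (npts - 1)
    if deltax is None:
        raise SpectrumError(f"{path}: cannot determine DELTAX")
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(data_lines, start=1):
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise SpectrumError(f"{path}: non-numeric XYDATA line {lineno}")
        if len(vals) < 2:
            raise SpectrumError(f"{path}: XYDATA line {lineno} has no Y values")
        x0 = vals[0]
        for j, y in enumerate(vals[1:]):
            xs.append((x0 + j * deltax / xfac) * xfac)
            ys.append(y * yfac)
    return np.array(xs), np.array(ys)


def read_spectrum(path, format: str = "csv2col", axis_label: str = "absorbance") -> Spectrum:
    """Read a spectrum from a plain-text file.

    ``format`` is ``"csv2col"`` or ``"jcamp_simple"``.  Descending grids
    are reversed so the returned grid is ascending; duplicate wavenumbers
    are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if format == "csv2col":
        x, y = _parse_csv2col(text, str(path))
    elif format == "jcamp_simple":
        x, y = _parse_jcamp_simple(text, str(path))
    else:
        raise SpectrumError(f"unknown format {format!r}")
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    order = np.argsort(x, kind="stable")
    if not np.array_equal(order, np.arange(x.size)):
        x, y = x[order], y[order]
    return Spectrum(x, y, axis_label)


def write_spectrum(s: Spectrum, path) -> None:
    """Write ``s`` as a csv2col file at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in zip(s.wavenumbers, s.intensities):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep grid points with ``lo <= nu <= hi`` (at least 2 must remain)."""
    if lo >= hi:
        raise SpectrumError(f"crop bounds reversed: [{lo}, {hi}]")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 2:
        raise SpectrumError(f"fewer than 2 points in crop window [{lo}, {hi}]")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], s.axis_label)


def resample(s: Spectrum, spacing: float) -> Spectrum:
    """Linear interpolation onto a uniform grid spanning the input range."""
    if spacing <= 0:
        raise SpectrumError("spacing must be positive")
    lo, hi = float(s.wavenumbers[0]), float(s.wavenumbers[-1])
    if spacing > hi - lo:
        raise SpectrumError("spacing larger than the grid span")
    n = int(np.floor((hi - lo) / spacing)) + 1
    grid = lo + spacing * np.arange(n)
    vals = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, vals, s.axis_label)
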