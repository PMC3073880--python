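"""Circular-dichroism helicity and protamine sequence statistics.

Helical content is estimated from the mean residue molar ellipticity at
222 nm with the empirical Chen relation

    % helix = 100 * theta_222 / (-39500 * (1 - 2.57 / n)),

where ``n`` is the number of peptide bonds (residues minus one) and
-39500 deg cm^2 dmol^-1 is the limiting ellipticity of an infinite
helix.  Sequence utilities cover residue composition and the lengths of
consecutive-arginine tracks, the feature that distinguishes protamine
families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "CdMeasurement",
    "ProtamineSequence",
    "mean_residue_ellipticity",
    "chen_helicity",
    "helicity_to_theta222",
    "residue_composition",
    "arginine_tracks",
    "read_fasta",
]

CHEN_LIMIT = -39500.0
CHEN_LENGTH_CORRECTION = 2.57

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CdMeasurement:
    """theta222 in deg cm^2 dmol^-1; n_bonds = residues - 1 (>= 3)."""

    theta222: float
    n_bonds: int

    def __post_init__(self) -> None:
        if self.n_bonds < 3:
            raise ValueError(f"n_bonds must be >= 3, got {self.n_bonds}")


@dataclass(frozen=True)
class ProtamineSequence:
    """A named one-letter amino-acid sequence (standard alphabet only)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


def mean_residue_ellipticity(theta_obs: float, conc: float, path: float,
                             mrw: float) -> float:
    """[theta] = theta_obs(mdeg) * MRW / (10 * path(cm) * conc(mg/ml))."""
    if conc <= 0 or path <= 0 or mrw <= 0:
        raise ValueError("conc, path and mrw must be positive")
    return theta_obs * mrw / (10.0 * path * conc)


def chen_helicity(m: CdMeasurement) -> float:
    """Percent helix from theta222 via the Chen relation.

    Raw values outside [0, 100] are preserved (a warning is emitted);
    they flag calibration or concentration problems rather than being
    silently clipped.
    """
    pct = 100.0 * m.theta222 / (CHEN_LIMIT * (1.0 - CHEN_LENGTH_CORRECTION / m.n_bonds))
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"helicity {pct:.1f}% outside [0, 100]; check theta222/MRW inputs",
            stacklevel=2,
        )
    return pct


def helicity_to_theta222(pct: float, n_bonds: int) -> float:
    """Exact inverse of :func:`chen_helicity`."""
    if n_bonds < 3:
        raise ValueError(f"n_bonds must be >= 3, got {n_bonds}")
    return pct / 100.0 * CHEN_LIMIT * (1.0 - CHEN_LENGTH_CORRECTION / n_bonds)


def residue_composition(seq: ProtamineSequence) -> dict:
    """Residue -> fraction of sequence length (fractions sum to 1)."""
    n = len(seq)
    out: dict[str, float] = {}
    for aa in seq.residues:
        out[aa] = out.get(aa, 0.0) + 1.0
    return {aa: count / n for aa, count in sorted(out.items())}


def arginine_tracks(seq: ProtamineSequence) -> list[int]:
    """Lengths of maximal runs of consecutive R, in order of occurrence."""
    tracks: list[int] = []
    run = 0
    for aa in seq.residues:
        if aa == "R":
            run += 1
        elif run:
            tracks.append(run)
            run = 0
    if run:
        tracks.append(run)
    return tracks


def read_fasta(path) -> list[ProtamineSequence]:
    """Read sequences from FASTA; the first word of the header is the id."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProtamineSequence(rec.id, str(rec.seq)) for rec in records]
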