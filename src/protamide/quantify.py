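"""Secondary-structure class assignment and area percentages.

Each fitted amide I' component is assigned to a conformational class by
its centre wavenumber, using the standard D2O-exchanged assignment
windows: side chains (arginine/tyrosine) below 1616 cm^-1, beta-sheet
1616-1638, random coil / flexible regions 1638-1647, alpha-helix
1647-1658 (canonical position 1652), and turns 1658-1696.  Class
percentages are area fractions of the total amide area; the side-chain
band is excluded from the total.  A beta-sheet window is always carried
so that its absence is reported as 0% rather than being undetectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .decompose import FitResult

__all__ = [
    "AssignmentWindows",
    "StructureSummary",
    "assign_band",
    "structure_percentages",
    "recovery_report",
    "STRUCTURE_CLASSES",
]

STRUCTURE_CLASSES = ("turns", "alpha_helix", "random_coil", "beta_sheet")

_DEFAULT_WINDOWS = (
    (1595.0, 1616.0, "side_chain"),
    (1616.0, 1638.0, "beta_sheet"),
    (1638.0, 1647.0, "random_coil"),
    (1647.0, 1658.0, "alpha_helix"),
    (1658.0, 1696.0, "turns"),
)


@dataclass(frozen=True)
class AssignmentWindows:
    """Ordered half-open wavenumber intervals ``[lo, hi) -> class``."""

    windows: tuple = _DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        ws = sorted(self.windows)
        for (lo, hi, _), (lo2, _, _) in zip(ws, ws[1:]):
            if hi > lo2:
                raise ValueError("assignment windows overlap")
        object.__setattr__(self, "windows", tuple(ws))

    @property
    def span(self) -> tuple[float, float]:
        return self.windows[0][0], self.windows[-1][1]

    @classmethod
    def from_rows(cls, rows) -> "AssignmentWindows":
        """Build from ``(class, lo, hi)`` rows (e.g. a custom window table)."""
        return cls(tuple((float(lo), float(hi), str(name)) for name, lo, hi in rows))


def assign_band(center: float, windows: AssignmentWindows | None = None) -> str:
    """Class of the unique half-open window containing ``center``."""
    w = windows or AssignmentWindows()
    for lo, hi, name in w.windows:
        if lo <= center < hi:
            return name
    lo, hi = w.span
    raise ValueError(f"unassignable band at {center} cm^-1 (covered range [{lo}, {hi}))")


@dataclass
class StructureSummary:
    """Per-class area percentages and the underlying band table."""

    percentages: dict
    band_table: list            # (center, area, class) triples
    total_amide_area: float

    def __post_init__(self) -> None:
        if self.percentages:
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"percentages sum to {total}, not 100")
        if "side_chain" in self.percentages:
            raise ValueError("side_chain must not appear in percentages")


def structure_percentages(fit: FitResult,
                          windows: AssignmentWindows | None = None) -> StructureSummary:
    """Area percentages per class; side-chain bands excluded from the total.

    Classes covered by the windows but without a fitted band (typically
    beta-sheet) are reported as 0%.
    """
    w = windows or AssignmentWindows()
    table = []
    sums: dict[str, float] = {}
    total = 0.0
    for band in fit.components:
        cls = assign_band(band.center, w)
        table.append((band.center, band.area, cls))
        if cls != "side_chain":
            sums[cls] = sums.get(cls, 0.0) + band.area
            total += band.area
    if total <= 0:
        raise ValueError("no amide components (all bands are side-chain)")
    classes = [name for _, _, name in w.windows if name != "side_chain"]
    percentages = {c: 100.0 * sums.get(c, 0.0) / total for c in classes}
    return StructureSummary(percentages=percentages, band_table=table,
                            total_amide_area=total)


def recovery_report(observed: StructureSummary, truth) -> dict:
    """Observed-minus-true deviation per class, in percentage points.

    ``truth`` is a FixtureTruth or a plain class->percent mapping.
    Classes missing on either side count as 0.
    """
    true_pct = getattr(truth, "true_percentages", truth)
    classes = set(observed.percentages) | set(true_pct)
    report = {
        c: observed.percentages.get(c, 0.0) - true_pct.get(c, 0.0)
        for c in sorted(classes)
    }
    report["max_abs_deviation"] = max(abs(v) for v in report.values())
    return report
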