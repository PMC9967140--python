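"""Land-use change statistics.

Single-class dynamic degree K, comprehensive dynamic degree LC, class-area
tables and the class×class transfer matrix with its row-normalized
transition probabilities.

Conventions
-----------
* K = ((U_b − U_a) / U_a) · (1/T) · 100, in percent per year.
* LC uses the *gross* off-diagonal transfer area (requires the transfer
  matrix), halved, over the start-date total area.
* Period length T is caller-supplied; analyses of decadal snapshot series
  typically use T = 9 or 10 depending on the interval.
* Areas in km²; rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridMismatchError, LandUseRaster

__all__ = [
    "TransferMatrix",
    "dynamic_degree",
    "comprehensive_dynamic_degree",
    "transfer_matrix",
    "area_table",
]


@dataclass
class TransferMatrix:
    """Class×class cross-tabulation of area (km²) between two dates."""

    classes: list[int]
    areas: np.ndarray  # (n, n), entry [m, n] = area moving m -> n
    start_label: str = "t1"
    end_label: str = "t2"
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.classes)
        if self.areas.shape != (n, n):
            raise ValueError("areas must be square over classes")
        if (self.areas < 0).any():
            raise ValueError("transfer areas must be non-negative")

    @property
    def start_areas(self) -> np.ndarray:
        return self.areas.sum(axis=1)

    @property
    def end_areas(self) -> np.ndarray:
        return self.areas.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized transition probabilities; empty rows stay zero."""
        rows = self.start_areas
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows[:, None] > 0, self.areas / rows[:, None], 0.0)
        return p

    def off_diagonal_total(self) -> float:
        """Gross area that changed class (km²)."""
        return float(self.areas.sum() - np.trace(self.areas))

    def to_frame(self) -> pd.DataFrame:
        names = [self.legend.get(c, str(c)) for c in self.classes]
        return pd.DataFrame(self.areas, index=names, columns=names)


def dynamic_degree(u_a: float, u_b: float, t_years: float) -> float:
    """Annualized relative area change of one class, in %/yr."""
    if u_a <= 0:
        raise ValueError("start area must be positive for the dynamic degree")
    if t_years <= 0:
        raise ValueError("period length must be positive")
    return (u_b - u_a) / u_a / t_years * 100.0


def comprehensive_dynamic_degree(tm: TransferMatrix, t_years: float) -> float:
    """Annualized share of total area involved in gross conversion, %/yr."""
    if t_years <= 0:
        raise ValueError("period length must be positive")
    total = tm.total_area
    if total <= 0:
        raise ValueError("transfer matrix covers zero area")
    return (tm.off_diagonal_total() / 2.0) / total / t_years * 100.0


def transfer_matrix(
    r1: LandUseRaster,
    r2: LandUseRaster,
    start_label: str = "t1",
    end_label: str = "t2",
) -> TransferMatrix:
    """Cross-tabulate the two dates; nodata on either date is excluded."""
    r1.spec.require_same(r2.spec)
    if r1.legend != r2.legend:
        raise GridMismatchError("legends differ between dates")
    classes = r1.classes()
    valid = r1.valid & r2.valid
    n = len(classes)
    c1 = np.searchsorted(classes, r1.codes[valid])
    c2 = np.searchsorted(classes, r2.codes[valid])
    counts = np.bincount(c1 * n + c2, minlength=n * n).reshape(n, n)
    areas = counts * r1.spec.cell_area_km2
    return TransferMatrix(classes, areas, start_label, end_label,
                          legend=dict(r1.legend))


def area_table(r: LandUseRaster) -> pd.DataFrame:
    """Per-class area (km²) and percentage of total non-nodata area."""
    classes = r.classes()
    if not int(r.valid.sum()):
        raise ValueError("raster is entirely nodata")
    areas = np.array([np.sum(r.codes == c) for c in classes], dtype=float)
    areas *= r.spec.cell_area_km2
    total = areas.sum()
    return pd.DataFrame(
        {
            "code": classes,
            "name": [r.legend[c] for c in classes],
            "area_km2": areas,
            "percent": areas / total * 100.0,
        }
    ).set_index("code")
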