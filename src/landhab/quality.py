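"""Habitat degradation and quality from land use and distance-decayed threats.

Every cell of a threat class exerts a decayed influence on every habitat
cell within its maximum effective distance; influences are weight- and
sensitivity-scaled and summed into a degradation surface D, which maps to
quality through the half-saturation response Q = H · (1 − D^z / (D^z + k^z)).

Decay is linear, 1 − d/d_max, or exponential, exp(−2.99 d / d_max); both
are truncated to zero beyond d_max so the convolution kernel is finite and
identical to the brute-force definition.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .grid import ContinuousRaster, GridSpec, LandUseRaster

__all__ = [
    "ThreatDefinition",
    "SensitivityTable",
    "QualityConfig",
    "QualityResult",
    "decay_impact",
    "degradation",
    "quality",
    "classify_quality",
    "quality_change",
    "mean_quality",
    "run_habitat_quality",
    "read_threats_csv",
    "read_sensitivity_csv",
    "QUALITY_LEVELS",
    "CHANGE_CATEGORIES",
]

EXP_DECAY_RATE = 2.99  # impact falls to e^-2.99 ≈ 0.05 at d_max

QUALITY_LEVELS = ["low", "relatively_low", "medium", "relatively_high", "high"]
CHANGE_CATEGORIES = [
    "severe_degeneration",
    "slight_degeneration",
    "invariable",
    "slight_improvement",
    "obvious_improvement",
]


@dataclass(frozen=True)
class ThreatDefinition:
    """One threat class: weight, maximum effective distance and decay mode."""

    code: int
    name: str
    weight: float
    d_max_km: float
    decay: str  # "linear" | "exponential"

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("threat weight must be in (0, 1]")
        if self.d_max_km <= 0:
            raise ValueError("maximum effective distance must be positive")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"unknown decay mode {self.decay!r}")


@dataclass
class SensitivityTable:
    """Habitat suitability per land class and sensitivity to each threat."""

    suitability: dict[int, float]               # class code -> H in [0, 1]
    sensitivity: dict[int, dict[int, float]]    # class code -> threat code -> S

    def __post_init__(self) -> None:
        for c, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability of class {c} outside [0, 1]")
        for c, row in self.sensitivity.items():
            for t, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(
                        f"sensitivity of class {c} to threat {t} outside [0, 1]"
                    )

    def h_array(self, codes: np.ndarray, nodata: float = 0.0) -> np.ndarray:
        out = np.full(codes.shape, nodata, dtype=float)
        for c, h in self.suitability.items():
            out[codes == c] = h
        return out

    def s_array(self, codes: np.ndarray, threat_code: int) -> np.ndarray:
        out = np.zeros(codes.shape, dtype=float)
        for c, row in self.sensitivity.items():
            out[codes == c] = row.get(threat_code, 0.0)
        return out


@dataclass
class QualityConfig:
    half_saturation: float = 0.5
    exponent: float = 2.5
    # half_saturation_from_d: if set, k is replaced by ratio × max(D)
    half_saturation_from_d: float | None = None

    def __post_init__(self) -> None:
        if self.half_saturation <= 0:
            raise ValueError("half-saturation must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


@dataclass
class QualityResult:
    spec: GridSpec
    degradation: np.ndarray
    quality: np.ndarray
    levels: np.ndarray          # int level index, -1 on nodata
    mask: np.ndarray
    config: QualityConfig = field(default_factory=QualityConfig)


def decay_impact(d: np.ndarray | float, d_max: float, mode: str) -> np.ndarray:
    """Impact in [0, 1] of a threat cell at distance ``d`` (same unit as
    ``d_max``); zero beyond ``d_max``."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if mode == "linear":
        out = np.maximum(0.0, 1.0 - d / d_max)
    elif mode == "exponential":
        out = np.exp(-(EXP_DECAY_RATE / d_max) * d)
    else:
        raise ValueError(f"unknown decay mode {mode!r}")
    return np.where(d > d_max, 0.0, out)


def _threat_kernel(threat: ThreatDefinition, cell_size: float) -> np.ndarray:
    """Decayed-impact kernel over all integer offsets within d_max."""
    d_max_m = threat.d_max_km * 1000.0
    radius = int(np.floor(d_max_m / cell_size))
    offsets = np.arange(-radius, radius + 1)
    dist = np.hypot(offsets[:, None], offsets[None, :]) * cell_size
    return decay_impact(dist, d_max_m, threat.decay)


# direct convolution is exact (matches the brute-force definition to
# machine precision) but O(kernel × image); beyond this budget the FFT
# path takes over
_DIRECT_CONV_BUDGET = 20_000_000


def _influence(presence: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum of kernel-decayed impacts of every threat cell at every cell."""
    cost = presence.size * kernel.size
    if cost <= _DIRECT_CONV_BUDGET:
        return ndimage.convolve(
            presence.astype(float), kernel, mode="constant", cval=0.0
        )
    out = signal.fftconvolve(presence.astype(float), kernel, mode="same")
    return np.maximum(out, 0.0)


def degradation(
    lu: LandUseRaster,
    threats: list[ThreatDefinition],
    sens: SensitivityTable,
    access: ContinuousRaster | None = None,
) -> np.ndarray:
    """Degradation surface D (zero on nodata cells).

    D_x = Σ_r Σ_y (w_r / Σw) · r_y · i_rxy · β_x · S_{j(x),r} with y running
    over threat-class cells within the threat's maximum distance of x.
    """
    if not threats:
        return np.zeros(lu.spec.shape)
    w_sum = sum(t.weight for t in threats)
    beta = np.ones(lu.spec.shape) if access is None else access.values
    if access is not None:
        lu.spec.require_same(access.spec)
    d = np.zeros(lu.spec.shape)
    for threat in threats:
        if threat.code not in lu.legend:
            raise KeyError(
                f"threat class {threat.code} ({threat.name}) absent from legend"
            )
        presence = (lu.codes == threat.code) & lu.valid
        if not presence.any():
            continue
        kernel = _threat_kernel(threat, lu.spec.cell_size)
        influence = _influence(presence, kernel)
        s = sens.s_array(lu.codes, threat.code)
        d += (threat.weight / w_sum) * influence * beta * s
    d[lu.mask] = 0.0
    return d


def quality(
    d: np.ndarray, h: np.ndarray, cfg: QualityConfig | None = None
) -> np.ndarray:
    """Q = H · (1 − D^z / (D^z + k^z)), cellwise."""
    cfg = cfg or QualityConfig()
    k = cfg.half_saturation
    if cfg.half_saturation_from_d is not None:
        d_max = float(np.max(d))
        if d_max > 0:
            k = cfg.half_saturation_from_d * d_max
    dz = np.power(np.maximum(d, 0.0), cfg.exponent)
    return h * (1.0 - dz / (dz + k**cfg.exponent))


def classify_quality(q: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Equal-interval 5-level labels: [0,.2) [.2,.4) [.4,.6) [.6,.8) [.8,1].

    Returns integer level indices into :data:`QUALITY_LEVELS`; −1 on mask.
    """
    q = np.asarray(q, dtype=float)
    check = q if mask is None else q[~mask]
    if ((check < 0) | (check > 1)).any():
        raise ValueError("quality values must lie in [0, 1]")
    levels = np.searchsorted([0.2, 0.4, 0.6, 0.8], q, side="right")
    if mask is not None:
        levels = np.where(mask, -1, levels)
    return levels


def quality_change(
    q1: np.ndarray, q2: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Categorize ΔQ = Q2 − Q1 into the five change categories.

    Exactly zero → invariable; ±0.5 fall in the slight categories.
    Returns indices into :data:`CHANGE_CATEGORIES`; −1 on mask.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    if q1.shape != q2.shape:
        raise ValueError("quality lattices are not aligned")
    dq = q2 - q1
    cat = np.full(dq.shape, 2, dtype=int)          # invariable
    cat[(dq > 0) & (dq <= 0.5)] = 3                # slight improvement
    cat[dq > 0.5] = 4                              # obvious improvement
    cat[(dq < 0) & (dq >= -0.5)] = 1               # slight degeneration
    cat[dq < -0.5] = 0                             # severe degeneration
    if mask is not None:
        cat = np.where(mask, -1, cat)
    return cat


def mean_quality(q: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Area-weighted mean quality over non-nodata cells."""
    vals = q if mask is None else q[~mask]
    if vals.size == 0:
        raise ValueError("no valid cells")
    return float(np.mean(vals))


def run_habitat_quality(
    lu: LandUseRaster,
    threats: list[ThreatDefinition],
    sens: SensitivityTable,
    cfg: QualityConfig | None = None,
    access: ContinuousRaster | None = None,
) -> QualityResult:
    """Full chain: degradation → quality → 5-level classing."""
    cfg = cfg or QualityConfig()
    missing = [c for c in lu.legend if c not in sens.suitability]
    if missing:
        warnings.warn(f"classes {missing} have no suitability; treated as 0")
    d = degradation(lu, threats, sens, access)
    h = sens.h_array(lu.codes)
    q = quality(d, h, cfg)
    q[lu.mask] = 0.0
    levels = classify_quality(q, lu.mask)
    return QualityResult(lu.spec, d, q, levels, lu.mask.copy(), cfg)


def level_area_table(result: QualityResult) -> pd.DataFrame:
    """Area (km²) and share per quality level."""
    cell_area = result.spec.cell_area_km2
    counts = np.array(
        [(result.levels == i).sum() for i in range(len(QUALITY_LEVELS))],
        dtype=float,
    )
    areas = counts * cell_area
    total = areas.sum()
    share = areas / total * 100.0 if total > 0 else np.zeros_like(areas)
    return pd.DataFrame(
        {"level": QUALITY_LEVELS, "area_km2": areas, "percent": share}
    ).set_index("level")


def read_threats_csv(path: str | Path) -> list[ThreatDefinition]:
    """Columns: code,name,weight,d_max_km,decay."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ThreatDefinition(
                    code=int(row["code"]),
                    name=row["name"],
                    weight=float(row["weight"]),
                    d_max_km=float(row["d_max_km"]),
                    decay=row["decay"].strip().lower(),
                )
            )
    return out


def read_sensitivity_csv(path: str | Path) -> SensitivityTable:
    """Columns: code,name,suitability,then one s_<threat code> per threat."""
    suit: dict[int, float] = {}
    sens: dict[int, dict[int, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            code = int(row["code"])
            suit[code] = float(row["suitability"])
            sens[code] = {
                int(k[2:]): float(v)
                for k, v in row.items()
                if k.startswith("s_") and v != ""
            }
    return SensitivityTable(suit, sens)
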