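"""Seeded synthetic landscapes with known statistical structure.

A :class:`SyntheticScenario` generates (a) spatially autocorrelated driver
rasters — smoothed Gaussian fields for climate/terrain, Euclidean-distance
fields from seeded features for accessibility, slope derived from the
synthetic elevation field — and (b) a multi-date categorical land-use
series whose initial map follows the per-class argmax of linear driver
scores and whose temporal evolution follows a ground-truth Markov matrix,
with conversions placed preferentially where the gaining class scores
high.  Everything is reproducible from one master seed.

``fixture_tables`` holds verbatim transcriptions of published summary
tables (class areas per date, per-period dynamics, quality-level areas and
the forecast tables) used by the arithmetic acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ContinuousRaster, GridSpec, LandUseRaster
from .quality import SensitivityTable, ThreatDefinition

__all__ = [
    "CLASS_LEGEND",
    "SyntheticScenario",
    "generate_drivers",
    "generate_landuse_series",
    "default_threats",
    "default_sensitivity",
    "fixture_tables",
]

# class codes used throughout the synthetic pipeline
CULTIVATED, FOREST_GRASS, WATER, CONSTRUCTION, UNUSED, SANDY = 1, 2, 3, 4, 5, 6
CLASS_LEGEND = {
    CULTIVATED: "cultivated",
    FOREST_GRASS: "forest_grassland",
    WATER: "water",
    CONSTRUCTION: "construction",
    UNUSED: "unused",
    SANDY: "sandy",
}

DRIVER_NAMES = [
    "elevation",
    "slope",
    "temperature",
    "precipitation",
    "population",
    "gdp",
    "dist_road",
    "dist_river",
    "dist_settlement",
    "dist_railway",
]


def _default_coefficients() -> np.ndarray:
    """Class-score weights over the driver stack (classes × drivers).

    Chosen so every class has support somewhere: water hugs rivers,
    construction hugs settlements/roads, cultivated likes flat wet cells,
    sandy likes dry high ground, etc.
    """
    c = np.zeros((6, len(DRIVER_NAMES)))
    name = {n: i for i, n in enumerate(DRIVER_NAMES)}
    c[0, name["precipitation"]] = 1.0
    c[0, name["slope"]] = -0.8
    c[0, name["dist_river"]] = -0.6
    c[1, name["precipitation"]] = 0.8
    c[1, name["temperature"]] = 0.5
    c[1, name["elevation"]] = 0.3
    c[2, name["dist_river"]] = -2.5
    c[2, name["elevation"]] = -0.5
    c[3, name["dist_settlement"]] = -2.0
    c[3, name["dist_road"]] = -0.8
    c[3, name["gdp"]] = 0.6
    c[4, name["dist_settlement"]] = -0.4
    c[4, name["precipitation"]] = -0.5
    c[5, name["precipitation"]] = -1.2
    c[5, name["elevation"]] = 0.6
    c[5, name["dist_river"]] = 0.4
    return c


def _default_markov() -> np.ndarray:
    """Ground-truth transition matrix (rows = from class 1..6).

    Deliberately directional — strong sandy→forest recovery flows, modest
    water→cultivated loss, little offsetting churn — mirroring the kind of
    monotone desert-greening dynamics the simulator is meant to track.
    """
    return np.array(
        [
            [0.960, 0.025, 0.000, 0.010, 0.005, 0.000],
            [0.010, 0.975, 0.000, 0.005, 0.010, 0.000],
            [0.040, 0.010, 0.940, 0.005, 0.005, 0.000],
            [0.000, 0.000, 0.000, 1.000, 0.000, 0.000],
            [0.020, 0.040, 0.000, 0.010, 0.930, 0.000],
            [0.010, 0.100, 0.000, 0.005, 0.015, 0.870],
        ]
    )


@dataclass
class SyntheticScenario:
    """Everything needed to regenerate a synthetic study area."""

    spec: GridSpec = field(
        default_factory=lambda: GridSpec(200, 200, cell_size=30.0)
    )
    smoothing_sigma: float = 8.0
    n_point_features: int = 5
    score_noise: float = 0.1
    coefficients: np.ndarray = field(default_factory=_default_coefficients)
    markov: np.ndarray = field(default_factory=_default_markov)
    dates: tuple[int, ...] = (1991, 2000, 2010, 2019)
    seed: int = 0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _smooth_field(rng: np.random.Generator, spec: GridSpec,
                  sigma: float) -> np.ndarray:
    raw = rng.standard_normal(spec.shape)
    f = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _distance_field(rng: np.random.Generator, spec: GridSpec,
                    n_features: int, as_line: bool) -> np.ndarray:
    sources = np.zeros(spec.shape, dtype=bool)
    if as_line:
        # a random straight transect across the grid
        r0, c0 = rng.integers(0, spec.n_rows), 0
        r1, c1 = rng.integers(0, spec.n_rows), spec.n_cols - 1
        t = np.linspace(0, 1, 4 * spec.n_cols)
        rows = np.clip(np.rint(r0 + (r1 - r0) * t).astype(int), 0,
                       spec.n_rows - 1)
        cols = np.clip(np.rint(c0 + (c1 - c0) * t).astype(int), 0,
                       spec.n_cols - 1)
        sources[rows, cols] = True
    else:
        rr = rng.integers(0, spec.n_rows, size=n_features)
        cc = rng.integers(0, spec.n_cols, size=n_features)
        sources[rr, cc] = True
    return ndimage.distance_transform_edt(~sources, sampling=spec.cell_size)


def generate_drivers(scenario: SyntheticScenario) -> list[ContinuousRaster]:
    """Driver stack in :data:`DRIVER_NAMES` order."""
    spec = scenario.spec
    rng = scenario.rng(stream=1)
    sig = scenario.smoothing_sigma
    dem = _smooth_field(rng, spec, sig * 1.5)
    gy, gx = np.gradient(dem, spec.cell_size)
    slope = np.hypot(gx, gy)
    slope = (slope - slope.mean()) / (slope.std() or 1.0)
    fields = {
        "elevation": dem,
        "slope": slope,
        "temperature": _smooth_field(rng, spec, sig),
        "precipitation": _smooth_field(rng, spec, sig),
        "population": _smooth_field(rng, spec, sig / 2),
        "gdp": _smooth_field(rng, spec, sig / 2),
        "dist_road": _distance_field(rng, spec, 0, as_line=True),
        "dist_river": _distance_field(rng, spec, 0, as_line=True),
        "dist_settlement": _distance_field(
            rng, spec, scenario.n_point_features, as_line=False
        ),
        "dist_railway": _distance_field(rng, spec, 0, as_line=True),
    }
    out = []
    for name in DRIVER_NAMES:
        v = np.asarray(fields[name], dtype=float)
        if name.startswith("dist_"):
            v = v / (v.max() or 1.0)  # scale to [0, 1] for the score model
        out.append(ContinuousRaster(spec, v, np.zeros(spec.shape, bool), name))
    return out


def class_scores(
    scenario: SyntheticScenario, drivers: list[ContinuousRaster]
) -> np.ndarray:
    """(6, rows, cols) linear scores of each class on the driver stack."""
    cube = np.stack([d.values for d in drivers])
    return np.tensordot(scenario.coefficients, cube, axes=(1, 0))


def generate_landuse_series(
    scenario: SyntheticScenario,
    drivers: list[ContinuousRaster] | None = None,
) -> list[LandUseRaster]:
    """One land-use raster per scenario date.

    The initial map is the per-class argmax of score + Gumbel noise; each
    subsequent date converts, for every class pair (m → n), the
    ``round(N_m · P_mn)`` class-m cells where class n scores highest
    (after a small noise perturbation), so the realized transfer matrix
    tracks the ground-truth Markov matrix closely.
    """
    if drivers is None:
        drivers = generate_drivers(scenario)
    spec = scenario.spec
    rng = scenario.rng(stream=2)
    scores = class_scores(scenario, drivers)
    noisy = scores + scenario.score_noise * rng.gumbel(size=scores.shape)
    codes = np.argmax(noisy, axis=0).astype(np.int64) + 1
    support = np.unique(codes)
    if len(support) < len(CLASS_LEGEND):
        import warnings

        missing = sorted(set(CLASS_LEGEND) - set(support.tolist()))
        warnings.warn(f"classes {missing} have no initial support")
    series = [LandUseRaster(spec, codes, dict(CLASS_LEGEND))]
    p = scenario.markov
    for _ in scenario.dates[1:]:
        codes = _markov_step(codes, p, scores, scenario.score_noise, rng)
        series.append(LandUseRaster(spec, codes, dict(CLASS_LEGEND)))
    return series


def _markov_step(
    codes: np.ndarray,
    p: np.ndarray,
    scores: np.ndarray,
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    new = codes.copy()
    for m in range(1, 7):
        cells = np.flatnonzero((codes == m).ravel())
        if cells.size == 0:
            continue
        n_m = cells.size
        targets = [n for n in range(1, 7) if n != m and p[m - 1, n - 1] > 0]
        quotas = {n: int(round(n_m * p[m - 1, n - 1])) for n in targets}
        taken = np.zeros(cells.size, dtype=bool)
        for n in sorted(quotas, key=quotas.get, reverse=True):
            k = min(quotas[n], int((~taken).sum()))
            if k <= 0:
                continue
            pref = scores[n - 1].ravel()[cells] + noise * rng.gumbel(
                size=cells.size
            )
            pref[taken] = -np.inf
            chosen = np.argpartition(-pref, k - 1)[:k]
            new.ravel()[cells[chosen]] = n
            taken[chosen] = True
    return new


def default_threats() -> list[ThreatDefinition]:
    """Threat parameterization for the six-class legend: cultivated
    (4 km, 0.6, linear), construction (8 km, 0.9, exponential), unused
    (6 km, 0.5, linear), sandy (6 km, 0.75, exponential)."""
    return [
        ThreatDefinition(CULTIVATED, "cultivated", 0.6, 4.0, "linear"),
        ThreatDefinition(CONSTRUCTION, "construction", 0.9, 8.0, "exponential"),
        ThreatDefinition(UNUSED, "unused", 0.5, 6.0, "linear"),
        ThreatDefinition(SANDY, "sandy", 0.75, 6.0, "exponential"),
    ]


def default_sensitivity() -> SensitivityTable:
    """Habitat suitability and threat sensitivities of the six classes."""
    suit = {
        SANDY: 0.1,
        FOREST_GRASS: 1.0,
        WATER: 0.9,
        UNUSED: 0.1,
        CULTIVATED: 0.4,
        CONSTRUCTION: 0.0,
    }
    #       threat:   cultivated  construction  unused  sandy
    sens = {
        SANDY: {CULTIVATED: 0.1, CONSTRUCTION: 0.3, UNUSED: 0.3, SANDY: 0.1},
        FOREST_GRASS: {CULTIVATED: 0.7, CONSTRUCTION: 0.6, UNUSED: 0.6,
                       SANDY: 0.7},
        WATER: {CULTIVATED: 0.6, CONSTRUCTION: 0.2, UNUSED: 0.4, SANDY: 0.3},
        UNUSED: {CULTIVATED: 0.1, CONSTRUCTION: 0.3, UNUSED: 0.1, SANDY: 0.6},
        CULTIVATED: {CULTIVATED: 0.3, CONSTRUCTION: 0.5, UNUSED: 0.4,
                     SANDY: 0.3},
        CONSTRUCTION: {CULTIVATED: 0.1, CONSTRUCTION: 0.3, UNUSED: 0.2,
                       SANDY: 0.0},
    }
    return SensitivityTable(suit, sens)


# ---------------------------------------------------------------------------
# Published-table fixtures (verbatim numeric transcription)
# ---------------------------------------------------------------------------

_CLASS_ORDER = [
    "cultivated",
    "forest_grassland",
    "water",
    "construction",
    "unused",
    "sandy",
]

_LEVEL_ORDER = ["low", "relatively_low", "medium", "relatively_high", "high"]


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Transcribed summary tables keyed by name.

    * ``class_areas`` — class area (km²) and printed share (%) per date.
    * ``dynamics`` — printed per-period dynamic degrees (%/yr) and the
      comprehensive dynamics, plus printed per-period area changes.
    * ``quality_levels`` — quality-level areas (km²) and shares per date.
    * ``forecast_areas`` — class areas 2019 vs 2030 with printed change
      area and change rate.
    * ``forecast_levels`` — quality-level areas 2019 vs 2030.
    """
    class_areas = pd.DataFrame(
        {
            1991: [284.61, 5254.91, 583.42, 8.45, 162.08, 6718.67],
            2000: [394.73, 6260.96, 467.77, 11.42, 139.30, 5737.09],
            2010: [489.14, 7267.08, 376.69, 27.28, 44.55, 4806.61],
            2019: [511.67, 8827.41, 322.67, 50.76, 158.38, 3140.46],
        },
        index=_CLASS_ORDER,
    )
    class_percent = pd.DataFrame(
        {
            1991: [2.19, 40.39, 4.48, 0.06, 1.25, 51.63],
            2000: [3.03, 48.12, 3.60, 0.09, 1.07, 44.09],
            2010: [3.76, 55.85, 2.90, 0.21, 0.34, 36.94],
            2019: [3.93, 67.84, 2.48, 0.39, 1.22, 24.14],
        },
        index=_CLASS_ORDER,
    )
    dynamics = pd.DataFrame(
        {
            "1991-2000": [4.30, 2.13, -2.20, 3.91, -1.57, -1.62],
            "2000-2010": [2.39, 1.61, -1.95, 13.89, -6.80, -1.62],
            "2010-2019": [0.46, 2.15, -1.44, 8.61, 25.55, -3.47],
        },
        index=_CLASS_ORDER,
    )
    area_change = pd.DataFrame(
        {
            "1991-2000": [110.12, 1006.05, -115.65, 2.97, -22.78, -981.58],
            "2000-2010": [94.41, 1006.12, -91.08, 15.86, -94.75, -930.48],
            "2010-2019": [22.53, 1560.33, -54.09, 23.48, 113.83, -1666.15],
        },
        index=_CLASS_ORDER,
    )
    comprehensive = pd.Series(
        {"1991-2000": 1.22, "2000-2010": 1.08, "2010-2019": 1.69},
        name="comprehensive_dynamics",
    )
    period_years = pd.Series(
        {"1991-2000": 9, "2000-2010": 10, "2010-2019": 10}, name="t_years"
    )
    quality_levels = pd.DataFrame(
        {
            1991: [7046.91, 1287.31, 1068.57, 1317.91, 2290.10],
            2000: [1420.42, 5346.16, 764.41, 1299.37, 4180.95],
            2010: [912.78, 4841.59, 288.84, 1229.24, 5738.84],
            2019: [996.03, 3220.80, 395.16, 1462.02, 6937.29],
        },
        index=_LEVEL_ORDER,
    )
    quality_percent = pd.DataFrame(
        {
            1991: [54.16, 9.89, 8.21, 10.13, 17.60],
            2000: [10.92, 41.09, 5.87, 9.99, 32.13],
            2010: [7.02, 37.21, 2.22, 9.45, 44.11],
            2019: [7.66, 24.75, 3.04, 11.24, 53.32],
        },
        index=_LEVEL_ORDER,
    )
    forecast_areas = pd.DataFrame(
        {
            2019: [511.67, 8827.41, 322.67, 50.76, 158.38, 3140.46],
            2030: [522.35, 9719.40, 355.98, 55.72, 216.59, 2139.22],
            "change_km2": [10.68, 891.99, 33.31, 4.96, 58.21, -1001.24],
            "change_rate_pct": [2.09, 10.10, 10.32, 9.77, 36.75, -31.88],
        },
        index=_CLASS_ORDER,
    )
    forecast_levels = pd.DataFrame(
        {
            2019: [996.03, 3220.80, 395.16, 1462.02, 6937.29],
            2030: [355.99, 739.69, 2229.41, 320.71, 9363.58],
            "change_km2": [-640.04, -2481.11, 1834.25, -1141.31, 2426.29],
            "change_share_pct": [-4.92, -19.07, 14.10, -8.77, 18.66],
        },
        index=_LEVEL_ORDER,
    )
    mean_quality = pd.Series(
        {1991: 0.3565, 2000: 0.5108, 2010: 0.5879, 2019: 0.6482,
         2030: 0.6876},
        name="mean_quality",
    )
    return {
        "class_areas": class_areas,
        "class_percent": class_percent,
        "dynamics": dynamics,
        "area_change": area_change,
        "comprehensive_dynamics": comprehensive.to_frame(),
        "period_years": period_years.to_frame(),
        "quality_levels": quality_levels,
        "quality_percent": quality_percent,
        "forecast_areas": forecast_areas,
        "forecast_levels": forecast_levels,
        "mean_quality": mean_quality.to_frame(),
    }
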