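"""Raster data model and I/O.

All rasters in one analysis share a :class:`GridSpec`: row-major storage,
origin at the upper-left corner, 0-based indices.  Distances are measured
between cell centers; areas are always reported in km² regardless of the
cell-size unit (assumed meters).  Nodata cells are excluded from every
statistic downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "LandUseRaster",
    "ContinuousRaster",
    "GridMismatchError",
    "read_raster",
    "write_raster",
    "read_legend",
    "write_legend",
    "area_of",
    "euclidean_distance",
    "aligned_stack",
]

M2_PER_KM2 = 1_000_000.0


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster lattice.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice shape; both must be positive.
    cell_size : float
        Side length of a square cell in meters.
    origin : tuple of float
        (x, y) of the upper-left corner of the upper-left cell.
    nodata : int or float
        Sentinel used on disk for missing cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / M2_PER_KM2

    def same_grid(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same(self, other: "GridSpec") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.cell_size} vs "
                f"{other.shape}@{other.cell_size}"
            )


@dataclass
class LandUseRaster:
    """Categorical raster of integer land-class codes plus a legend."""

    spec: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise TypeError("land-use codes must be integers")
        if self.codes.shape != self.spec.shape:
            raise GridMismatchError("codes shape does not match GridSpec")
        if len(set(self.legend)) != len(self.legend):
            raise ValueError("legend codes must be distinct")
        present = set(np.unique(self.codes).tolist()) - {int(self.spec.nodata)}
        if self.legend:
            unknown = present - set(self.legend)
            if unknown:
                raise ValueError(f"codes {sorted(unknown)} missing from legend")
        else:
            self.legend = {c: f"class_{c}" for c in sorted(present)}

    @property
    def mask(self) -> np.ndarray:
        """True on nodata cells."""
        return self.codes == int(self.spec.nodata)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def classes(self) -> list[int]:
        return sorted(self.legend)


@dataclass
class ContinuousRaster:
    """Real-valued raster with an explicit nodata mask."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise GridMismatchError("values shape does not match GridSpec")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values) | (
                self.values == self.spec.nodata
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spec.shape:
            raise GridMismatchError("mask shape does not match GridSpec")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values off the nodata mask")

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid (text) and TIFF (via tifffile)
# ---------------------------------------------------------------------------

_ASC_SUFFIXES = {".asc", ".txt", ".agr"}
_TIF_SUFFIXES = {".tif", ".tiff"}


def _read_ascii(path: Path) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append(parts)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = float(header["cellsize"])
    nodata = header.get("nodata_value", -9999)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0))
    yll = header.get("yllcorner", header.get("yllcenter", 0.0))
    flat = [v for r in rows for v in r]
    if len(flat) != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} cells, got {len(flat)}")
    data = np.array(flat, dtype=float).reshape(nrows, ncols)
    # upper-left origin: yll is the bottom edge
    spec = GridSpec(nrows, ncols, cell, (xll, yll + nrows * cell), nodata)
    return data, spec


def _write_ascii(path: Path, data: np.ndarray, spec: GridSpec) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin[0]:.6f}\n")
        fh.write(f"yllcorner {spec.origin[1] - spec.n_rows * spec.cell_size:.6f}\n")
        fh.write(f"cellsize {spec.cell_size:.6f}\n")
        fh.write(f"NODATA_value {spec.nodata:g}\n")
        if np.issubdtype(data.dtype, np.integer):
            fmt = "%d"
        else:
            fmt = "%.10g"
        np.savetxt(fh, data, fmt=fmt)


def read_raster(
    path: str | Path,
    kind: str = "categorical",
    spec: GridSpec | None = None,
    legend: dict[int, str] | None = None,
) -> LandUseRaster | ContinuousRaster:
    """Read a raster file (ESRI ASCII grid or TIFF).

    Parameters
    ----------
    path : path
        ``.asc``/``.txt`` are parsed as ESRI ASCII grids; ``.tif``/``.tiff``
        through tifffile.  TIFF carries no grid geometry here, so ``spec``
        supplies cell size and origin (defaults otherwise).
    kind : {"categorical", "continuous"}
    spec : GridSpec, optional
        Reference grid; a mismatch raises :class:`GridMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _TIF_SUFFIXES:
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if data.ndim != 2:
            raise ValueError("only single-band rasters are supported")
        file_spec = GridSpec(
            data.shape[0],
            data.shape[1],
            spec.cell_size if spec else 30.0,
            spec.origin if spec else (0.0, 0.0),
            spec.nodata if spec else -9999,
        )
    elif suffix in _ASC_SUFFIXES:
        data, file_spec = _read_ascii(path)
    else:
        raise ValueError(f"unsupported raster format: {suffix}")
    if spec is not None:
        spec.require_same(file_spec)
        file_spec = spec
    if kind == "categorical":
        return LandUseRaster(file_spec, np.rint(data).astype(np.int64),
                             legend or {})
    if kind == "continuous":
        mask = data == file_spec.nodata
        return ContinuousRaster(file_spec, data, mask, name=path.stem)
    raise ValueError(f"unknown raster kind: {kind!r}")


def write_raster(path: str | Path, raster: LandUseRaster | ContinuousRaster) -> None:
    """Write to ESRI ASCII grid or TIFF, chosen by file suffix."""
    path = Path(path)
    if isinstance(raster, LandUseRaster):
        data = raster.codes
    else:
        data = np.where(raster.mask, raster.spec.nodata, raster.values)
    suffix = path.suffix.lower()
    if suffix in _TIF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(data))
    elif suffix in _ASC_SUFFIXES:
        _write_ascii(path, data, raster.spec)
    else:
        raise ValueError(f"unsupported raster format: {suffix}")


def read_legend(path: str | Path) -> dict[int, str]:
    """CSV legend with columns code,name."""
    legend: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            legend[int(row["code"])] = row["name"]
    return legend


def write_legend(path: str | Path, legend: dict[int, str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name"])
        for code in sorted(legend):
            writer.writerow([code, legend[code]])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def area_of(raster: LandUseRaster, code: int) -> float:
    """Area of one class in km² (cell count × cell area)."""
    if code not in raster.legend:
        raise KeyError(f"code {code} not in legend")
    return int(np.sum(raster.codes == code)) * raster.spec.cell_area_km2


def euclidean_distance(
    raster: LandUseRaster, codes: int | set[int] | list[int]
) -> ContinuousRaster:
    """Distance (m) from every cell center to the nearest cell of ``codes``.

    Zero on source cells.  Nodata cells receive a distance too (they can
    host threats in adjacent analyses) but carry the raster's nodata mask.
    """
    if isinstance(codes, int):
        codes = {codes}
    sources = np.isin(raster.codes, list(codes))
    if not sources.any():
        raise ValueError("no source cells for the requested codes")
    dist = ndimage.distance_transform_edt(
        ~sources, sampling=raster.spec.cell_size
    )
    return ContinuousRaster(raster.spec, np.asarray(dist, dtype=float),
                            raster.mask.copy(), name="distance")


def aligned_stack(
    rasters: list[ContinuousRaster],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack continuous rasters into (n_layers, rows, cols); verify alignment.

    Returns the value cube and the union nodata mask.
    """
    if not rasters:
        raise ValueError("empty stack")
    ref = rasters[0].spec
    for r in rasters[1:]:
        ref.require_same(r.spec)
    cube = np.stack([r.values for r in rasters])
    mask = np.any([r.mask for r in rasters], axis=0)
    return cube, mask
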