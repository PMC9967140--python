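"""Landscape pattern metrics computed from first principles.

Class level: NP, PD, LPI, LSI, AI.  Landscape level: NP, PD, LSI, SPLIT,
SHDI, AI, CONTAG.

Conventions (fixed so that the definitional oracle is unambiguous):

* Patches are connected components per class, 8-neighbor by default.
* Adjacency counts are rook (4-neighbor).  For AI each like pair is
  counted once (single count); for CONTAG each ordered pair is counted
  (double count), the usual contagion convention.
* The landscape boundary and nodata edges contribute to patch perimeter
  but never to adjacency counts.
* min-perimeter and max-like-adjacency of ``a`` cells use the integer
  quasi-square rule: with n = floor(sqrt(a)) and m = a − n²,
  min e = 4n (m = 0), 4n + 2 (0 < a ≤ n(n+1)), else 4n + 4;
  max g = 2n(n−1) + [0 if m = 0 else 2m − 1 if m ≤ n else 2m − 2].
* PD is reported in patches per km² (configurable denominator upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LandUseRaster

__all__ = [
    "PatchLabeling",
    "label_patches",
    "class_metrics",
    "landscape_metrics",
    "min_perimeter",
    "max_like_adjacencies",
]

_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


def min_perimeter(a: int) -> int:
    """Perimeter (cell edges) of the most compact arrangement of ``a`` cells."""
    if a <= 0:
        raise ValueError("patch size must be positive")
    n = math.isqrt(a)
    if n * n == a:
        return 4 * n
    if a <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def max_like_adjacencies(a: int) -> int:
    """Largest possible single-count like-adjacency total for ``a`` cells."""
    if a <= 0:
        raise ValueError("class size must be positive")
    n = math.isqrt(a)
    m = a - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


@dataclass
class PatchLabeling:
    """Connected-component labeling of every class of a land-use raster."""

    raster: LandUseRaster
    connectivity: int
    labels: np.ndarray            # 0 on nodata, 1..n_patches elsewhere
    patch_class: np.ndarray       # (n_patches,) class code per patch
    patch_cells: np.ndarray       # (n_patches,) cell count per patch
    patch_perimeter: np.ndarray   # (n_patches,) edge count per patch

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    def classes(self) -> list[int]:
        return self.raster.classes()


def _perimeters(codes: np.ndarray, labels: np.ndarray, n: int,
                valid: np.ndarray) -> np.ndarray:
    """Per-patch perimeter: edges facing a different class, nodata or border."""
    per = np.zeros(n + 1, dtype=np.int64)
    padded = np.pad(valid, 1, constant_values=False)
    pcodes = np.pad(codes, 1, constant_values=-1)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh_valid = np.roll(padded, shift, axis=axis)[1:-1, 1:-1]
        neigh_code = np.roll(pcodes, shift, axis=axis)[1:-1, 1:-1]
        exposed = valid & (~neigh_valid | (neigh_code != codes))
        per += np.bincount(labels[exposed], minlength=n + 1)
    return per[1:]


def label_patches(r: LandUseRaster, connectivity: int = 8) -> PatchLabeling:
    """Label maximal same-class connected components."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not r.valid.any():
        raise ValueError("raster is entirely nodata")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels = np.zeros(r.spec.shape, dtype=np.int64)
    patch_class: list[int] = []
    offset = 0
    for code in r.classes():
        mask = r.codes == code
        lab, n = ndimage.label(mask, structure=struct)
        labels[mask] = lab[mask] + offset
        patch_class.extend([code] * n)
        offset += n
    counts = np.bincount(labels[r.valid], minlength=offset + 1)[1:]
    perim = _perimeters(r.codes, labels, offset, r.valid)
    return PatchLabeling(
        raster=r,
        connectivity=connectivity,
        labels=labels,
        patch_class=np.asarray(patch_class, dtype=np.int64),
        patch_cells=counts.astype(np.int64),
        patch_perimeter=perim,
    )


def _like_adjacencies(codes: np.ndarray, valid: np.ndarray,
                      code: int) -> int:
    """Single-count rook like-adjacency pairs for one class."""
    mask = (codes == code) & valid
    horiz = mask[:, :-1] & mask[:, 1:]
    vert = mask[:-1, :] & mask[1:, :]
    return int(horiz.sum() + vert.sum())


def adjacency_matrix(r: LandUseRaster) -> tuple[list[int], np.ndarray]:
    """Double-count rook adjacency matrix g[i, k] between classes.

    Each ordered pair of valid neighboring cells contributes one count, so
    the matrix is symmetric with even diagonal; nodata/border edges are
    excluded.
    """
    classes = r.classes()
    n = len(classes)
    idx = np.searchsorted(classes, r.codes.clip(min=min(classes)))
    g = np.zeros((n, n), dtype=np.int64)
    valid = r.valid
    for (s1, s2) in (((slice(None), slice(0, -1)), (slice(None), slice(1, None))),
                     ((slice(0, -1), slice(None)), (slice(1, None), slice(None)))):
        ok = valid[s1] & valid[s2]
        a = idx[s1][ok]
        b = idx[s2][ok]
        np.add.at(g, (a, b), 1)
        np.add.at(g, (b, a), 1)
    return classes, g


def class_metrics(pl: PatchLabeling) -> pd.DataFrame:
    """Per-class NP, PD, LPI, LSI and AI.

    AI is NaN for a single-cell class (no arrangement has any like
    adjacency); empty classes are omitted entirely.
    """
    r = pl.raster
    cell_area = r.spec.cell_area_km2
    total_cells = int(r.valid.sum())
    total_area = total_cells * cell_area
    rows = []
    for code in pl.classes():
        sel = pl.patch_class == code
        if not sel.any():
            continue
        cells = int(pl.patch_cells[sel].sum())
        np_ = int(sel.sum())
        lpi = pl.patch_cells[sel].max() * cell_area / total_area * 100.0
        e_i = int(pl.patch_perimeter[sel].sum())
        lsi = e_i / min_perimeter(cells)
        g_ii = _like_adjacencies(r.codes, r.valid, code)
        max_g = max_like_adjacencies(cells)
        ai = g_ii / max_g * 100.0 if max_g > 0 else float("nan")
        rows.append(
            {
                "code": code,
                "name": r.legend[code],
                "NP": np_,
                "PD": np_ / total_area,
                "LPI": lpi,
                "LSI": lsi,
                "AI": ai,
                "area_km2": cells * cell_area,
            }
        )
    return pd.DataFrame(rows).set_index("code")


def _contagion(p: np.ndarray, g: np.ndarray) -> float:
    """Contagion (%) from class proportions and the double-count adjacency
    matrix; undefined (ValueError) for fewer than two classes."""
    m = len(p)
    if m < 2:
        raise ValueError("CONTAG requires at least two classes")
    row_tot = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_tot > 0, g / row_tot, 0.0)
    terms = p[:, None] * frac
    nz = terms > 0
    ent = float(np.sum(terms[nz] * np.log(terms[nz])))
    return (1.0 + ent / (2.0 * math.log(m))) * 100.0


def landscape_metrics(pl: PatchLabeling) -> dict[str, float]:
    """Landscape-level metric dictionary.

    Landscape LSI divides the total patch-edge length shared once per
    distinct-class adjacency (plus boundary/nodata edges) by the
    quasi-square minimum for the whole landscape; landscape AI is the
    area-weighted mean of class AI.  CONTAG is NaN for one class.
    """
    r = pl.raster
    cell_area = r.spec.cell_area_km2
    total_cells = int(r.valid.sum())
    total_area = total_cells * cell_area

    cm = class_metrics(pl)
    p = (cm["area_km2"] / total_area).to_numpy()

    shdi = float(-(p * np.log(p)).sum())
    split = total_area**2 / float(
        ((pl.patch_cells * cell_area) ** 2).sum()
    )
    # total edge: class perimeters double-count internal class-class edges
    # and single-count boundary/nodata edges -> recover single-count edges
    boundary = _boundary_edges(r)
    e_total = (int(pl.patch_perimeter.sum()) - boundary) // 2 + boundary
    lsi = e_total / min_perimeter(total_cells)

    ai_class = cm["AI"].to_numpy()
    ok = np.isfinite(ai_class)
    ai = float((ai_class[ok] * p[ok]).sum() / p[ok].sum()) if ok.any() else float("nan")

    classes, g = adjacency_matrix(r)
    try:
        contag = _contagion(p, g)
    except ValueError:
        contag = float("nan")

    return {
        "NP": int(pl.n_patches),
        "PD": pl.n_patches / total_area,
        "LSI": lsi,
        "SPLIT": split,
        "SHDI": shdi,
        "AI": ai,
        "CONTAG": contag,
    }


def _boundary_edges(r: LandUseRaster) -> int:
    """Cell edges on the landscape border or facing nodata."""
    valid = r.valid
    padded = np.pad(valid, 1, constant_values=False)
    total = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(padded, shift, axis=axis)[1:-1, 1:-1]
        total += int((valid & ~neigh).sum())
    return total
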