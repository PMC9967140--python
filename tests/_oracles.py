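"""Independent brute-force reference implementations used by the tests.

Everything here is written directly from the definitions (explicit loops,
flood fill, all-pairs scans) and deliberately shares no code with the
package, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_distance(sources: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs minimum center-to-center distance to any True cell."""
    rows, cols = sources.shape
    src = [(r, c) for r in range(rows) for c in range(cols) if sources[r, c]]
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            out[r, c] = min(
                math.hypot(r - sr, c - sc) for sr, sc in src
            ) * cell_size
    return out


def flood_fill_patches(codes: np.ndarray, valid: np.ndarray,
                       connectivity: int) -> np.ndarray:
    """BFS labeling of same-code components; 0 on invalid cells."""
    rows, cols = codes.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    labels = np.zeros((rows, cols), dtype=int)
    nxt = 0
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c] or labels[r, c]:
                continue
            nxt += 1
            stack = [(r, c)]
            labels[r, c] = nxt
            while stack:
                cr, cc = stack.pop()
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < rows and 0 <= nc < cols
                        and valid[nr, nc] and not labels[nr, nc]
                        and codes[nr, nc] == codes[cr, cc]
                    ):
                        labels[nr, nc] = nxt
                        stack.append((nr, nc))
    return labels


def patch_perimeter(codes: np.ndarray, valid: np.ndarray,
                    labels: np.ndarray, label: int) -> int:
    """Count edges of one patch facing a different class, nodata or border."""
    rows, cols = codes.shape
    per = 0
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] != label:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols):
                    per += 1
                elif not valid[nr, nc] or codes[nr, nc] != codes[r, c]:
                    per += 1
    return per


def like_adjacencies(codes: np.ndarray, valid: np.ndarray, code: int) -> int:
    """Single-count rook pairs of equal-code valid cells."""
    rows, cols = codes.shape
    g = 0
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c] or codes[r, c] != code:
                continue
            for dr, dc in ((0, 1), (1, 0)):  # each pair counted once
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < rows and 0 <= nc < cols
                    and valid[nr, nc] and codes[nr, nc] == code
                ):
                    g += 1
    return g


def adjacency_counts(codes: np.ndarray, valid: np.ndarray
                     ) -> dict[tuple[int, int], int]:
    """Double-count rook adjacency tallies between class codes."""
    rows, cols = codes.shape
    g: dict[tuple[int, int], int] = {}
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and valid[nr, nc]:
                    key = (int(codes[r, c]), int(codes[nr, nc]))
                    g[key] = g.get(key, 0) + 1
    return g


def quasi_square_min_perimeter(a: int) -> int:
    """Exhaustive check form: smallest perimeter over all rectangles-plus-
    remainder layouts equals the closed-form rule; evaluated by searching
    rectangle widths."""
    best = None
    for w in range(1, a + 1):
        h = a // w
        rem = a - w * h
        if h == 0:
            continue
        per = 2 * (w + h) + (2 if rem else 0)
        if best is None or per < best:
            best = per
    return best


def contagion(p: np.ndarray, g: dict[tuple[int, int], int],
              classes: list[int]) -> float:
    """Direct evaluation of the contagion double sum (double-count g)."""
    m = len(classes)
    total = 0.0
    for i, ci in enumerate(classes):
        row_sum = sum(g.get((ci, ck), 0) for ck in classes)
        for ck in classes:
            if row_sum == 0:
                continue
            term = p[i] * g.get((ci, ck), 0) / row_sum
            if term > 0:
                total += term * math.log(term)
    return (1 + total / (2 * math.log(m))) * 100.0


def degradation_quadruple_loop(
    codes: np.ndarray,
    valid: np.ndarray,
    cell_size: float,
    threats: list,          # objects with code, weight, d_max_km, decay
    sensitivity: dict,      # class -> {threat code -> S}
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Literal cell-by-cell, threat-cell-by-threat-cell evaluation."""
    rows, cols = codes.shape
    w_sum = sum(t.weight for t in threats)
    if beta is None:
        beta = np.ones((rows, cols))
    d = np.zeros((rows, cols))
    for t in threats:
        d_max = t.d_max_km * 1000.0
        threat_cells = [
            (r, c)
            for r in range(rows)
            for c in range(cols)
            if valid[r, c] and codes[r, c] == t.code
        ]
        for x_r in range(rows):
            for x_c in range(cols):
                if not valid[x_r, x_c]:
                    continue
                s = sensitivity.get(int(codes[x_r, x_c]), {}).get(t.code, 0.0)
                if s == 0.0:
                    continue
                acc = 0.0
                for y_r, y_c in threat_cells:
                    dist = math.hypot(x_r - y_r, x_c - y_c) * cell_size
                    if dist > d_max:
                        continue
                    if t.decay == "linear":
                        i_rxy = 1.0 - dist / d_max
                    else:
                        i_rxy = math.exp(-2.99 / d_max * dist)
                    acc += i_rxy
                d[x_r, x_c] += (t.weight / w_sum) * acc * beta[x_r, x_c] * s
    return d


def q_statistic(y: np.ndarray, strata: np.ndarray) -> float:
    """Direct within/total variance decomposition (population variances)."""
    y = np.asarray(y, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    n = y.size
    total_ss = n * y.var()
    within = 0.0
    for h in np.unique(strata):
        yh = y[strata == h]
        within += yh.size * yh.var()
    return 1.0 - within / total_ss
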