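"""Markov + cellular-automaton land-use simulation with validation scores.

Stages
------
1. ``markov_demand`` projects class areas with a row-stochastic transition
   matrix (usually the row-normalized transfer matrix of a calibration
   period).
2. ``fit_expansion_model`` learns a per-class development-probability
   surface from the cells that gained each class between two dates and a
   stack of driver rasters (any classifier with fit/predict_proba; an
   extremely-randomized-trees ensemble by default).
3. ``ca_simulate`` allocates the demanded area change cell by cell:
   transition score = suitability × neighborhood effect, with a stochastic
   seed term that lets new patches nucleate away from existing ones and a
   decreasing acceptance threshold that admits lower-probability cells as
   allocation stalls.  Same seed ⇒ identical output.
4. ``kappa`` / ``figure_of_merit`` score a simulation against an observed
   map (three-map FoM: misses, hits, wrong-class hits, false alarms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ContinuousRaster, LandUseRaster

__all__ = [
    "CAConfig",
    "SuitabilitySurfaces",
    "markov_demand",
    "fit_expansion_model",
    "ca_simulate",
    "confusion_matrix",
    "kappa",
    "figure_of_merit",
]


@dataclass
class SuitabilitySurfaces:
    """Per-class development probability surfaces on a shared grid."""

    classes: list[int]
    surfaces: np.ndarray  # (n_classes, rows, cols), each in [0, 1]

    def __post_init__(self) -> None:
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        if self.surfaces.shape[0] != len(self.classes):
            raise ValueError("one surface per class required")

    def for_class(self, code: int) -> np.ndarray:
        return self.surfaces[self.classes.index(code)]


@dataclass
class CAConfig:
    """Tuning knobs of the allocation automaton (defaults documented)."""

    neighborhood_radius: int = 1            # Moore window half-width
    neighborhood_weights: dict[int, float] = field(default_factory=dict)
    seed_probability: float = 0.01          # chance a cell ignores neighbors
    threshold_start: float = 0.8
    threshold_decay: float = 0.9            # per stalled round
    transition_permissions: np.ndarray | None = None  # (n, n) bool, rows=from
    max_rounds: int = 200
    demand_tolerance_cells: int = 0
    seed: int = 0


def markov_demand(
    p: np.ndarray, areas: np.ndarray, steps: int = 1
) -> np.ndarray:
    """Project class areas ``steps`` transitions ahead: areas · Pᵗ."""
    p = np.asarray(p, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition matrix must be square")
    rows = p.sum(axis=1)
    occupied = areas > 0
    if not np.allclose(rows[occupied], 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    if (p < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    out = areas.copy()
    for _ in range(steps):
        out = out @ p
    return out


def _default_classifier(seed: int):
    from sklearn.ensemble import ExtraTreesClassifier

    return ExtraTreesClassifier(
        n_estimators=100,
        min_samples_leaf=5,
        class_weight="balanced",
        n_jobs=1,
        random_state=seed,
    )


def fit_expansion_model(
    lu_t1: LandUseRaster,
    lu_t2: LandUseRaster,
    drivers: list[ContinuousRaster],
    seed: int = 0,
    classifier_factory=None,
    max_samples_per_class: int = 10_000,
    negative_ratio: int = 3,
) -> SuitabilitySurfaces:
    """Learn per-class gain-probability surfaces from observed expansion.

    For each class the positives are cells that changed *into* the class
    between the two dates; negatives are sampled from the remaining
    *candidate* cells (cells not already of the class at the first date),
    ``negative_ratio`` negatives per positive.  A class that gained
    nothing falls back to a flat surface at its base occupancy rate, with
    a warning.
    """
    lu_t1.spec.require_same(lu_t2.spec)
    if lu_t1.legend != lu_t2.legend:
        raise ValueError("legends differ between dates")
    from .grid import aligned_stack

    cube, dmask = aligned_stack(drivers)
    lu_t1.spec.require_same(drivers[0].spec)
    valid = lu_t1.valid & lu_t2.valid & ~dmask
    x_all = cube[:, valid].T  # (n_valid, n_drivers)
    rng = np.random.default_rng(seed)
    classes = lu_t1.classes()
    surfaces = np.zeros((len(classes),) + lu_t1.spec.shape)
    for ci, code in enumerate(classes):
        candidate = (lu_t1.codes != code) & valid
        gained = (lu_t2.codes == code) & candidate
        pos_idx = np.flatnonzero(gained[valid])
        if pos_idx.size == 0:
            base = float(((lu_t2.codes == code) & valid).sum() / valid.sum())
            warnings.warn(
                f"class {code} gained no cells; using flat prior {base:.4f}"
            )
            surfaces[ci][valid] = base
            continue
        neg_pool = np.flatnonzero((candidate & ~gained)[valid])
        n_pos = min(pos_idx.size, max_samples_per_class)
        n_neg = min(neg_pool.size, negative_ratio * n_pos)
        pos_sample = rng.choice(pos_idx, size=n_pos, replace=False)
        neg_sample = rng.choice(neg_pool, size=n_neg, replace=False)
        idx = np.concatenate([pos_sample, neg_sample])
        y = np.zeros(idx.size, dtype=int)
        y[: n_pos] = 1
        factory = classifier_factory or _default_classifier
        clf = factory(int(rng.integers(2**31)))
        clf.fit(x_all[idx], y)
        proba = clf.predict_proba(x_all)
        col = list(clf.classes_).index(1)
        surfaces[ci][valid] = proba[:, col]
    return SuitabilitySurfaces(classes, surfaces)


def _neighborhood_fraction(codes: np.ndarray, code: int, radius: int) -> np.ndarray:
    """Fraction of same-class cells in the (2r+1)² Moore window (self excluded)."""
    size = 2 * radius + 1
    mask = (codes == code).astype(float)
    counts = ndimage.uniform_filter(mask, size=size, mode="constant") * size**2
    counts -= mask
    return counts / (size**2 - 1)


def ca_simulate(
    initial: LandUseRaster,
    suit: SuitabilitySurfaces,
    demand_km2: np.ndarray,
    cfg: CAConfig | None = None,
) -> LandUseRaster:
    """Allocate land-class change toward a demand vector.

    Only cells of classes above their demand may convert, and only into
    classes below theirs, so total area is conserved and allocation
    converges monotonically.  Returns a partially allocated map (with a
    warning) if the permission matrix makes the demand unreachable.
    """
    cfg = cfg or CAConfig()
    classes = initial.classes()
    if list(suit.classes) != classes:
        raise ValueError("suitability classes do not match raster legend")
    n = len(classes)
    cell_area = initial.spec.cell_area_km2
    demand_cells = np.rint(np.asarray(demand_km2, dtype=float) / cell_area).astype(int)
    total_valid = int(initial.valid.sum())
    # force exact conservation after rounding
    demand_cells[np.argmax(demand_cells)] += total_valid - demand_cells.sum()
    if (demand_cells < 0).any():
        raise ValueError("negative demand after rounding")

    perm = cfg.transition_permissions
    if perm is None:
        perm = np.ones((n, n), dtype=bool)
    perm = np.asarray(perm, dtype=bool)
    np.fill_diagonal(perm, True)

    rng = np.random.default_rng(cfg.seed)
    codes = initial.codes.copy()
    valid = initial.valid
    class_index = {c: i for i, c in enumerate(classes)}
    idx_map = np.full(codes.shape, -1, dtype=int)
    for c, i in class_index.items():
        idx_map[codes == c] = i

    counts = np.bincount(idx_map[valid], minlength=n)
    threshold = cfg.threshold_start
    weights = np.array(
        [cfg.neighborhood_weights.get(c, 1.0) for c in classes], dtype=float
    )

    flat_idx = idx_map.ravel()
    flat_codes = codes.ravel()
    for _ in range(cfg.max_rounds):
        deficit = demand_cells - counts
        growing = np.flatnonzero(deficit > cfg.demand_tolerance_cells)
        shrinking = np.flatnonzero(deficit < -cfg.demand_tolerance_cells)
        if growing.size == 0 or shrinking.size == 0:
            break
        donor_cells = np.flatnonzero(
            (valid & np.isin(idx_map, shrinking)).ravel()
        )
        if donor_cells.size == 0:
            break
        # per-growing-class score fields for this round
        suit_flat = suit.surfaces.reshape(n, -1)[:, donor_cells]
        scores = np.empty((growing.size, donor_cells.size))
        for gi, g in enumerate(growing):
            neigh = _neighborhood_fraction(
                codes, classes[g], cfg.neighborhood_radius
            ).ravel()[donor_cells]
            w = weights[g]
            base = suit_flat[g]
            scores[gi] = base * ((1.0 - min(w, 1.0)) + min(w, 1.0) * neigh)
        # stochastic seeds bypass the neighborhood damping entirely
        seeded = rng.random(donor_cells.size) < cfg.seed_probability
        if seeded.any():
            scores[:, seeded] = suit_flat[growing][:, seeded]
        # mask forbidden transitions
        src_all = flat_idx[donor_cells]
        permitted = perm[src_all][:, growing].T  # (n_growing, n_donor)
        scores = np.where(permitted, scores, 0.0)
        # roulette pick of a target class per donor cell
        totals = scores.sum(axis=0)
        ok = totals > 0
        u_pick = rng.random(donor_cells.size)
        cum = np.cumsum(scores, axis=0)
        pick = np.zeros(donor_cells.size, dtype=int)
        pick[ok] = (
            cum[:, ok] < (u_pick[ok] * totals[ok])[None, :]
        ).sum(axis=0)
        pick = np.minimum(pick, growing.size - 1)
        picked_score = scores[pick, np.arange(donor_cells.size)]
        # acceptance against the decaying threshold, then best-first order
        accept = ok & (picked_score >= threshold * rng.random(donor_cells.size))
        order = np.argsort(-picked_score[accept], kind="stable")
        cand_cells = donor_cells[accept][order]
        cand_src = src_all[accept][order]
        cand_tgt = growing[pick[accept][order]]
        remaining = deficit.copy()
        surplus = -deficit.copy()
        converted = 0
        for cell, src, tgt in zip(cand_cells, cand_src, cand_tgt):
            if surplus[src] <= 0 or remaining[tgt] <= 0:
                continue
            flat_idx[cell] = tgt
            flat_codes[cell] = classes[tgt]
            counts[src] -= 1
            counts[tgt] += 1
            remaining[tgt] -= 1
            surplus[src] -= 1
            converted += 1
        if converted == 0:
            threshold *= cfg.threshold_decay
            if threshold < 1e-6:
                break

    deficit = demand_cells - counts
    if np.abs(deficit).max() > max(cfg.demand_tolerance_cells, 0):
        unmet = {
            classes[i]: int(d) for i, d in enumerate(deficit) if d != 0
        }
        if any(abs(v) > 0 for v in unmet.values()):
            warnings.warn(f"demand not fully met (cells): {unmet}")
    return LandUseRaster(initial.spec, codes, dict(initial.legend))


def confusion_matrix(
    observed: LandUseRaster, simulated: LandUseRaster
) -> tuple[list[int], np.ndarray]:
    observed.spec.require_same(simulated.spec)
    if observed.legend != simulated.legend:
        raise ValueError("legends differ")
    classes = observed.classes()
    valid = observed.valid & simulated.valid
    n = len(classes)
    o = np.searchsorted(classes, observed.codes[valid])
    s = np.searchsorted(classes, simulated.codes[valid])
    m = np.bincount(o * n + s, minlength=n * n).reshape(n, n)
    return classes, m


def kappa(observed: LandUseRaster, simulated: LandUseRaster) -> float:
    """Cohen's kappa over the cellwise confusion matrix."""
    _, m = confusion_matrix(observed, simulated)
    total = m.sum()
    if total == 0:
        raise ValueError("no overlapping valid cells")
    if (m.sum(axis=1) > 0).sum() < 2:
        raise ValueError("kappa undefined with a single observed class")
    po = np.trace(m) / total
    pe = float((m.sum(axis=0) * m.sum(axis=1)).sum()) / total**2
    if pe == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return float((po - pe) / (1 - pe))


def figure_of_merit(
    initial: LandUseRaster,
    observed: LandUseRaster,
    simulated: LandUseRaster,
) -> float:
    """FoM = B / (A + B + C + D) on the three-map comparison.

    A: observed change predicted as persistence (miss);
    B: observed change predicted as the correct new class (hit);
    C: observed change predicted as change to the wrong class;
    D: observed persistence predicted as change (false alarm).
    """
    initial.spec.require_same(observed.spec)
    initial.spec.require_same(simulated.spec)
    valid = initial.valid & observed.valid & simulated.valid
    ini = initial.codes[valid]
    obs = observed.codes[valid]
    sim = simulated.codes[valid]
    obs_change = obs != ini
    sim_change = sim != ini
    if not obs_change.any():
        raise ValueError("FoM undefined: no observed change")
    a = int((obs_change & ~sim_change).sum())
    b = int((obs_change & sim_change & (sim == obs)).sum())
    c = int((obs_change & sim_change & (sim != obs)).sum())
    d = int((~obs_change & sim_change).sum())
    return b / (a + b + c + d)
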