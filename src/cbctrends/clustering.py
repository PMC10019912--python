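"""k-medoids clustering of standardized population trends.

Trends are standardized row-wise (mean 0, sd 1) so that only shape, not
level or amplitude, drives the grouping, then partitioned around k = 4
medoids. Exact PAM (the classic BUILD + SWAP algorithm on the full
Euclidean dissimilarity matrix) handles species-level matrices; the
circle-by-species matrix is far larger, so a CLARA-style scheme draws
random row subsamples, runs PAM on each, assigns every row to the nearest
candidate medoid set, and keeps the set with the lowest full-data cost.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import MedoidResult

log = logging.getLogger(__name__)


def standardize_trends(matrix: np.ndarray):
    """Row-standardize a trend-by-year matrix to mean 0, sd 1.

    Affine transforms of the same shape map to the same standardized row.
    Constant rows (sd = 0) cannot be standardized; they are excluded and
    their indices returned, with a log entry.

    Returns ``(standardized, kept_indices)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        log.warning("excluding %d constant trend row(s) from clustering",
                    int((~keep).sum()))
    out = (matrix[keep] - mean[keep]) / sd[keep]
    return out, np.flatnonzero(keep)


def align_trends(curves, n_points: int = 100) -> np.ndarray:
    """Resample trend curves of unequal year span onto a common grid.

    Each curve is linearly time-rescaled to ``n_points`` points over its
    own span, so trends observed over different windows become comparable
    shape vectors.
    """
    out = np.empty((len(curves), n_points))
    grid = np.linspace(0.0, 1.0, n_points)
    for r, values in enumerate(curves):
        values = np.asarray(values, dtype=float)
        x = np.linspace(0.0, 1.0, values.size)
        out[r] = np.interp(grid, x, values)
    return out


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    bad = ~np.isfinite(matrix).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite entries in trend rows {np.flatnonzero(bad).tolist()}")
    return matrix


def _build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy cost-reduction starting medoids (the classic BUILD phase)."""
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(D, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        m = int(np.argmin(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, D[m])
    return np.asarray(medoids)


def _swap_descend(D: np.ndarray, medoids: np.ndarray, k: int):
    """Steepest-descent SWAP phase; total cost is non-increasing."""
    n = D.shape[0]
    medoids = np.asarray(medoids).copy()
    while True:
        dist_to_meds = D[medoids]                      # (k, n)
        order = np.argsort(dist_to_meds, axis=0)
        nearest_idx = order[0]
        nearest = dist_to_meds[nearest_idx, np.arange(n)]
        second = dist_to_meds[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        current_cost = nearest.sum()

        best = (0.0, None, None)
        for mi in range(k):
            base = np.where(nearest_idx == mi, second, nearest)
            costs = np.minimum(D, base[None, :]).sum(axis=1)
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            delta = costs[h] - current_cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]

    dist_to_meds = D[medoids]
    assignments = np.argmin(dist_to_meds, axis=0)
    cost = float(dist_to_meds[assignments, np.arange(n)].sum())
    return medoids, assignments, cost


def _pam_core(D: np.ndarray, k: int, seed: int = 0, n_starts: int = 8):
    """Multi-start BUILD + SWAP; returns the cheapest local optimum.

    SWAP converges to a local optimum of the single-exchange neighborhood,
    which on small unstructured instances occasionally misses the global
    medoid set; restarting SWAP from seeded random medoid subsets and
    keeping the cheapest solution removes that failure mode while leaving
    each descent a textbook PAM run.
    """
    n = D.shape[0]
    best = _swap_descend(D, _build(D, k), k)
    if n > k:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            start = rng.choice(n, size=k, replace=False)
            cand = _swap_descend(D, start, k)
            if cand[2] < best[2] - 1e-12:
                best = cand
    return best


def pam(matrix: np.ndarray, k: int = 4, seed: int = 0) -> MedoidResult:
    """Partitioning around medoids with Euclidean dissimilarity.

    BUILD picks a greedy starting medoid set; SWAP repeatedly applies the
    best cost-reducing (medoid, non-medoid) exchange until none improves,
    so the total cost is non-increasing across iterations. Additional
    seeded random starts guard against SWAP's rare local optima. The
    procedure is deterministic given the seed and input row order (ties
    break toward lower indices).
    """
    matrix = _check_matrix(matrix)
    n = matrix.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    D = _euclidean_matrix(matrix)
    medoids, assignments, cost = _pam_core(D, k, seed=seed)
    return MedoidResult(
        k=k, medoid_indices=medoids, medoid_curves=matrix[medoids],
        assignments=assignments, total_cost=cost, method="pam",
    )


def _euclidean_matrix(matrix: np.ndarray) -> np.ndarray:
    sq = (matrix ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (matrix @ matrix.T)
    np.fill_diagonal(D2, 0.0)
    return np.sqrt(np.maximum(D2, 0.0))


def _cross_distances(rows: np.ndarray, medoid_curves: np.ndarray) -> np.ndarray:
    diff = rows[:, None, :] - medoid_curves[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def assign_to_medoids(trends: np.ndarray, medoid_curves: np.ndarray) -> np.ndarray:
    """Nearest-medoid labels under Euclidean dissimilarity.

    Rows must be standardized on the medoids' grid. Exact ties break
    toward the lowest medoid index (numpy argmin convention).
    """
    trends = np.asarray(trends, dtype=float)
    medoid_curves = np.asarray(medoid_curves, dtype=float)
    if trends.shape[1] != medoid_curves.shape[1]:
        raise ValueError(
            f"trend length {trends.shape[1]} does not match medoid length "
            f"{medoid_curves.shape[1]}"
        )
    return np.argmin(_cross_distances(trends, medoid_curves), axis=1)


def clara(matrix: np.ndarray, k: int = 4, subsample_size: int = 1000,
          n_subsamples: int = 5, seed: int = 0) -> MedoidResult:
    """Subsampled PAM for large trend matrices.

    Each of ``n_subsamples`` random subsamples (drawn without replacement
    within a subsample, independently across subsamples) is clustered with
    exact PAM; every candidate medoid set is then scored by the total
    dissimilarity over the *full* matrix and the cheapest set wins. When
    the matrix has at most ``subsample_size`` rows this reduces to exact
    PAM. The production-scale configuration used for very large
    circle-by-species matrices is ``subsample_size=1000, n_subsamples=1000``.
    """
    matrix = _check_matrix(matrix)
    n = matrix.shape[0]
    if subsample_size < k:
        raise ValueError(f"subsample_size must be >= k={k}")
    if n <= subsample_size:
        res = pam(matrix, k=k, seed=seed)
        return MedoidResult(
            k=k, medoid_indices=res.medoid_indices, medoid_curves=res.medoid_curves,
            assignments=res.assignments, total_cost=res.total_cost, method="clara",
        )
    rng = np.random.default_rng(seed)
    best: MedoidResult | None = None
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub = pam(matrix[idx], k=k)
        med_idx = idx[sub.medoid_indices]
        dists = _cross_distances(matrix, matrix[med_idx])
        labels = np.argmin(dists, axis=1)
        cost = float(dists[np.arange(n), labels].sum())
        if best is None or cost < best.total_cost:
            best = MedoidResult(
                k=k, medoid_indices=med_idx, medoid_curves=matrix[med_idx],
                assignments=labels, total_cost=cost, method="clara",
            )
    return best
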