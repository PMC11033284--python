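"""Residue-based rice quality grading.

The grading feature is the M index: the pair ``[d_current, d_predicted]`` of
a sample's measured residue and its forecast residue (both mg/kg), so a
grade reflects not just where a lot stands today but where it is heading.
Samples are clustered per pesticide with K-Means (Lloyd's iterations,
k-means++ seeding, multiple restarts), the number of clusters is chosen by
the mean silhouette over a candidate range, and clusters are ordered by
residue level into named grades with concentration-interval breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MIndexSample",
    "ClusterResult",
    "GradeModel",
    "build_m_index",
    "kmeans",
    "silhouette",
    "select_k",
    "grade_clusters",
]

GRADE_NAMES = {
    2: ("High", "Low"),
    3: ("High", "Medium", "Low"),
}


@dataclass(frozen=True)
class MIndexSample:
    """Quality-index pair for one sample of one pesticide."""

    d_current: float
    d_predicted: float
    pesticide: str = ""

    def __post_init__(self) -> None:
        if self.d_current < 0 or self.d_predicted < 0:
            raise ValueError("residue values must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.d_current, self.d_predicted])


@dataclass(frozen=True)
class ClusterResult:
    K: int
    labels: np.ndarray
    centers: np.ndarray  # (K, 2): mean (d_current, d_predicted) per cluster
    inertia: float
    silhouette: float | None = None


@dataclass(frozen=True)
class GradeModel:
    """Ordered grades with per-grade residue intervals (best -> worst).

    ``breakpoints`` are the K-1 increasing concentration cut points on the
    current-residue axis; grade ``g`` covers ``(0, b1)`` for the best grade,
    ``[b_i, b_{i+1}]`` for middle grades, and ``(b_{K-1}, +inf)`` for the
    worst.
    """

    K: int
    grade_names: tuple[str, ...]
    breakpoints: np.ndarray
    centers: np.ndarray          # ordered best -> worst
    counts: np.ndarray
    cluster_to_grade: np.ndarray  # cluster index -> grade rank

    def intervals(self) -> list[tuple[str, str]]:
        """Human-readable (grade, interval) rows in the bracket pattern
        (0, b1) / [b1, b2] / ... / (b_last, +inf)."""
        rows = []
        bp = list(self.breakpoints)
        for g, name in enumerate(self.grade_names):
            if g == 0:
                rows.append((name, f"(0, {bp[0]:g})"))
            elif g == self.K - 1:
                rows.append((name, f"({bp[-1]:g}, +inf)"))
            else:
                rows.append((name, f"[{bp[g - 1]:g}, {bp[g]:g}]"))
        return rows

    def grade_of_value(self, d_current: float) -> str:
        """Grade by interval membership.

        The best interval is open above, the worst open below, middle
        intervals closed on both ends — so a value landing exactly on a
        breakpoint belongs to the adjacent closed (middle) interval.
        """
        bp = self.breakpoints
        if d_current < bp[0]:
            return self.grade_names[0]
        if d_current > bp[-1]:
            return self.grade_names[-1]
        for g in range(1, self.K - 1):
            if d_current <= bp[g]:
                return self.grade_names[g]
        return self.grade_names[-1]


def build_m_index(current: float, predicted: float,
                  pesticide: str = "") -> MIndexSample:
    """Pair a measured residue with its forecast, unscaled."""
    return MIndexSample(float(current), float(predicted), pesticide)


def _kmeans_pp_init(points: np.ndarray, K: int, rng) -> np.ndarray:
    n = len(points)
    centers = np.empty((K, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[j] = points[rng.integers(n)]
        else:
            centers[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(points: np.ndarray, centers: np.ndarray,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    K = len(centers)
    labels = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        labels = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        new_centers = centers.copy()
        for j in range(K):
            members = points[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:  # re-seed an emptied cluster at the farthest point
                far = np.argmax(np.min(d2, axis=1))
                new_centers[j] = points[far]
        if np.allclose(new_centers, centers, rtol=0, atol=0):
            break
        centers = new_centers
    d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(np.sum(d2[np.arange(len(points)), labels]))
    return labels, centers, inertia


def kmeans(points: np.ndarray, K: int, seed: int = 0,
           restarts: int = 10) -> ClusterResult:
    """Lloyd's K-Means: assign to nearest centroid, recompute centroids as
    coordinate means, repeat to a fixed point (or 300 iterations).

    k-means++ seeding, best of ``restarts`` runs by inertia; nearest-centroid
    ties go to the lowest centroid index; an emptied cluster is re-seeded at
    the farthest point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of points n={n}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        init = _kmeans_pp_init(points, K, rng)
        labels, centers, inertia = _lloyd(points, init)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    return ClusterResult(K=K, labels=labels, centers=centers, inertia=inertia)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette ``(b - a) / max(a, b)`` over all samples.

    ``a(i)`` is the mean distance to the other members of i's cluster,
    ``b(i)`` the mean distance to the nearest other cluster.  Samples in
    singleton clusters contribute 0, as do exact 0/0 cases.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for fewer than 2 clusters")
    dist = np.sqrt(np.maximum(
        np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=2), 0.0))
    scores = np.zeros(len(points))
    for i in range(len(points)):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same <= 1:
            continue  # singleton contributes 0
        a = dist[i, same].sum() / (n_same - 1)
        b = min(dist[i, labels == other].mean()
                for other in uniq if other != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def select_k(points: np.ndarray, k_range=range(3, 8), seed: int = 0,
             restarts: int = 10) -> tuple[int, dict[int, float]]:
    """Choose K by maximum mean silhouette; ties break toward smaller K."""
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("empty K range")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if max(k_range) > len(points) - 1:
        raise ValueError("largest K must be at most n - 1")
    scores: dict[int, float] = {}
    for K in k_range:
        res = kmeans(points, K, seed=seed, restarts=restarts)
        scores[K] = silhouette(points, res.labels)
    best = max(k_range, key=lambda K: (scores[K], -K))
    return best, scores


def grade_clusters(result: ClusterResult, points: np.ndarray) -> GradeModel:
    """Order clusters by residue level into grades with interval breakpoints.

    Clusters are ranked by ascending center ``d_current`` (lower residue =
    better grade).  The breakpoint between adjacent grades is the midpoint of
    the better cluster's maximum ``d_current`` and the worse cluster's
    minimum.
    """
    if result.K < 2:
        raise ValueError("grading needs at least 2 clusters")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    order = np.argsort(result.centers[:, 0], kind="stable")
    names = GRADE_NAMES.get(
        result.K,
        tuple(f"Grade {i + 1}" for i in range(result.K)))
    breakpoints = []
    for better, worse in zip(order[:-1], order[1:]):
        hi = points[result.labels == better, 0].max()
        lo = points[result.labels == worse, 0].min()
        breakpoints.append(0.5 * (hi + lo))
    bp = np.array(breakpoints)
    if np.any(np.diff(bp) <= 0):
        bad = [(int(order[i]), int(order[i + 1]))
               for i in range(len(bp) - 1) if bp[i + 1] <= bp[i]]
        raise ValueError(
            f"clusters overlap: non-increasing breakpoints between cluster "
            f"pairs {bad}")
    cluster_to_grade = np.empty(result.K, dtype=int)
    cluster_to_grade[order] = np.arange(result.K)
    counts = np.array([(result.labels == c).sum() for c in order])
    return GradeModel(K=result.K, grade_names=names, breakpoints=bp,
                      centers=result.centers[order], counts=counts,
                      cluster_to_grade=cluster_to_grade)
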