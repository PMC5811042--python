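"""Shape-based clustering of per-animal trajectory profiles.

Profiles (deviations from the population fixed curve, all sampled on the same
age grid) are grouped with a k-medoids-style iteration under the discrete
Fréchet distance: animals are assigned to the nearest cluster curve, and each
cluster curve is updated to the pointwise median of its members whenever that
lowers the total within-cluster distance.  Initialization is k-means++-style
(distance-weighted seeding) and fully determined by the seed.

Because all profiles share the age grid, the Fréchet ground cost between
sample points is taken as |a_i - b_j| in trait units; monotone couplings still
allow index shifts, so the distance respects curve shape rather than pointwise
alignment alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Trajectory

__all__ = ["ClusterResult", "frechet_distance", "cluster_profiles"]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-profile cluster index, 0..k-1
    centers: np.ndarray  # (k, n_ages) cluster curves
    ages: np.ndarray
    proportions: np.ndarray
    within_distance: float
    within_distance_trace: list[float]
    seed: int
    animal_ids: list[str] | None = None

    def assignments(self) -> dict[str, int]:
        ids = self.animal_ids or [str(i) for i in range(len(self.labels))]
        return {a: int(c) for a, c in zip(ids, self.labels)}


def _values(curve) -> np.ndarray:
    if isinstance(curve, Trajectory):
        return np.asarray(curve.values, dtype=float)
    return np.asarray(curve, dtype=float)


def frechet_distance(curve_a, curve_b) -> float:
    """Discrete Fréchet distance between two sampled curves.

    Minimum over monotone couplings of the maximum pointwise gap; symmetric,
    zero iff the sampled curves are identical, and a metric on sampled curves.
    """
    a, b = _values(curve_a), _values(curve_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compute a Fréchet distance for an empty curve")
    return float(_frechet_many(a[None, :], b[None, :])[0])


def _frechet_many(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Discrete Fréchet distances between paired rows of A and B.

    A: (m, na), B: (m, nb).  Dynamic program vectorized across the m pairs.
    """
    m, na = A.shape
    nb = B.shape[1]
    # cost[i, j] per pair: |A[:, i] - B[:, j]|
    prev = np.empty((m, nb))
    cur = np.empty((m, nb))
    c0 = np.abs(A[:, 0][:, None] - B)  # (m, nb)
    prev[:, 0] = c0[:, 0]
    for j in range(1, nb):
        prev[:, j] = np.maximum(prev[:, j - 1], c0[:, j])
    for i in range(1, na):
        ci = np.abs(A[:, i][:, None] - B)
        cur[:, 0] = np.maximum(prev[:, 0], ci[:, 0])
        for j in range(1, nb):
            reach = np.minimum(
                prev[:, j], np.minimum(prev[:, j - 1], cur[:, j - 1])
            )
            cur[:, j] = np.maximum(reach, ci[:, j])
        prev, cur = cur, prev
    return prev[:, -1].copy()


def _dist_to_centers(P: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n_profiles, k) matrix of Fréchet distances."""
    n = P.shape[0]
    k = centers.shape[0]
    out = np.empty((n, k))
    for c in range(k):
        out[:, c] = _frechet_many(P, np.broadcast_to(centers[c], P.shape))
    return out


def cluster_profiles(
    profiles: list[Trajectory] | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 5,
    ages: np.ndarray | None = None,
    animal_ids: list[str] | None = None,
) -> ClusterResult:
    """Cluster trajectory profiles into ``k`` shape groups.

    Runs ``n_init`` seeded restarts and keeps the solution with the smallest
    total within-cluster distance.  Within each run the total within-cluster
    Fréchet distance is non-increasing across iterations: the assignment step
    moves each profile to its nearest center, and a center update (pointwise
    median of members) is only accepted when it does not increase the
    cluster's within-distance.
    """
    if k < 1:
        raise ValueError("number of clusters must be >= 1")
    if n_init > 1:
        sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_init)
        best = None
        for s in sub:
            res = cluster_profiles(
                profiles,
                k,
                seed=int(s),
                max_iter=max_iter,
                n_init=1,
                ages=ages,
                animal_ids=animal_ids,
            )
            if best is None or res.within_distance < best.within_distance:
                best = res
        best.seed = seed
        return best
    if isinstance(profiles, np.ndarray):
        P = np.asarray(profiles, dtype=float)
        if ages is None:
            ages = np.arange(P.shape[1], dtype=float)
    else:
        if not profiles:
            raise ValueError("no profiles to cluster")
        ages = profiles[0].ages
        for t in profiles:
            if not np.array_equal(t.ages, ages):
                raise ValueError("profiles must share a common age grid")
        P = np.vstack([t.values for t in profiles])
        if animal_ids is None:
            animal_ids = [t.animal_id or str(i) for i, t in enumerate(profiles)]
    n = P.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")

    rng = np.random.default_rng(seed)
    # k-means++-style seeding under the Fréchet distance
    first = int(rng.integers(n))
    center_idx = [first]
    d2 = _frechet_many(P, np.broadcast_to(P[first], P.shape)) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            # degenerate: all remaining profiles identical to a center
            choices = [i for i in range(n) if i not in center_idx]
            center_idx.append(choices[0] if choices else first)
        else:
            center_idx.append(int(rng.choice(n, p=d2 / total)))
        dn = _frechet_many(P, np.broadcast_to(P[center_idx[-1]], P.shape)) ** 2
        d2 = np.minimum(d2, dn)
    centers = P[center_idx].copy()

    labels = np.full(n, -1, dtype=int)
    trace: list[float] = []
    for _ in range(max_iter):
        D = _dist_to_centers(P, centers)
        new_labels = np.argmin(D, axis=1)
        # keep every cluster non-empty: reseed empties at the worst-fit profile
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(D[np.arange(n), new_labels]))
                new_labels[far] = c
                centers[c] = P[far]
                D = _dist_to_centers(P, centers)
        within = float(D[np.arange(n), new_labels].sum())
        trace.append(within)
        # center update: pointwise median, accepted only if it improves
        improved = False
        for c in range(k):
            members = P[new_labels == c]
            cand = np.median(members, axis=0)
            old_d = _frechet_many(members, np.broadcast_to(centers[c], members.shape)).sum()
            new_d = _frechet_many(members, np.broadcast_to(cand, members.shape)).sum()
            if new_d < old_d - 1e-15:
                centers[c] = cand
                improved = True
        if np.array_equal(new_labels, labels) and not improved:
            labels = new_labels
            break
        labels = new_labels

    D = _dist_to_centers(P, centers)
    within = float(D[np.arange(n), labels].sum())
    trace.append(within)
    proportions = np.bincount(labels, minlength=k) / n
    return ClusterResult(
        labels=labels,
        centers=centers,
        ages=np.asarray(ages, dtype=float),
        proportions=proportions,
        within_distance=within,
        within_distance_trace=trace,
        seed=seed,
        animal_ids=animal_ids,
    )
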