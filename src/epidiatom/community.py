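"""Community-level statistics on paired observation channels.

Bray-Curtis dissimilarity, non-metric multidimensional scaling (Kruskal
stress-1 with isotonic disparities), k-medoids (PAM) clustering on a
precomputed distance matrix, the Mantel permutation test, and a two-sample
comparison of two distance distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, DistanceMatrix, ValidationError, to_relative_abundance

__all__ = [
    "Ordination",
    "Partition",
    "MantelResult",
    "DistanceSetComparison",
    "bray_curtis",
    "nmds",
    "cluster_k_groups",
    "mantel",
    "compare_distance_sets",
]


# ---------------------------------------------------------------------------
# Bray-Curtis


def bray_curtis(t: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    Counts are converted to relative abundances first, so the result is
    invariant to rescaling any sample's counts by a positive constant.
    """
    rel = to_relative_abundance(t) if t.mode == "count" else t
    x = rel.values
    d = squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(t.sample_ids), d)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class Ordination:
    """NMDS result: centered coordinates plus the achieved Kruskal stress-1."""

    coordinates: np.ndarray  # n_samples x k, column means 0
    stress: float
    n_restarts_used: int
    converged: bool
    labels: list[str]
    degenerate: bool = False


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def _stress_parts(d_flat: np.ndarray, order: np.ndarray, x: np.ndarray):
    """Configuration distances, isotonic disparities and Kruskal stress-1."""
    e = pdist(x)
    # Kruskal primary tie handling: tied input distances are ordered by the
    # current configuration distance, so ties impose no extra constraint.
    tie_order = np.lexsort((e, d_flat)) if order is None else order
    dhat = np.empty_like(e)
    dhat[tie_order] = isotonic_regression(e[tie_order]).x
    denom = float(np.sum(e**2))
    if denom == 0:
        return e, dhat, np.inf
    stress = math.sqrt(float(np.sum((e - dhat) ** 2)) / denom)
    return e, dhat, stress


def _guttman(x: np.ndarray, e: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    e_sq = squareform(e)
    dhat_sq = squareform(dhat)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(e_sq > 0, dhat_sq / np.where(e_sq > 0, e_sq, 1.0), 0.0)
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return (b @ x) / n


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1 over ``n_restarts`` starts.

    Restart 0 uses classical metric scaling; the rest are seeded random
    configurations.  Each refinement step (Guttman transform against the
    isotonic disparities) is accepted only if stress does not increase.
    """
    n = d.n
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} samples for {k}-D NMDS")
    if d.has_undefined():
        raise ValidationError("NMDS requires fully defined distances")
    d_flat = squareform(d.data, checks=False)
    if np.ptp(d_flat) < 1e-12:
        # all pairwise distances equal: any configuration is equally (un)fit
        x = _classical_scaling(d.data, k)
        x = x - x.mean(axis=0)
        return Ordination(x, 0.0, 0, False, list(d.labels), degenerate=True)

    rng = np.random.default_rng(seed)
    scale = float(d_flat.mean())
    best: tuple[float, np.ndarray, bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_scaling(d.data, k)
        else:
            x = rng.normal(scale=scale, size=(n, k))
        x = x - x.mean(axis=0)
        e, dhat, stress = _stress_parts(d_flat, None, x)
        converged = False
        for _ in range(max_iter):
            x_new = _guttman(x, e, dhat)
            x_new = x_new - x_new.mean(axis=0)
            e_new, dhat_new, stress_new = _stress_parts(d_flat, None, x_new)
            if stress_new > stress + 1e-15:
                break
            improved = stress - stress_new
            x, e, dhat, stress = x_new, e_new, dhat_new, stress_new
            if improved < tol:
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, x, converged)
    stress, x, converged = best
    return Ordination(
        coordinates=x - x.mean(axis=0),
        stress=float(stress),
        n_restarts_used=max(1, n_restarts),
        converged=bool(converged),
        labels=list(d.labels),
    )


# ---------------------------------------------------------------------------
# k-medoids (PAM)


@dataclass
class Partition:
    assignment: dict[str, int]
    medoids: list[str]
    total_cost: float


def _assign_cost(d: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = d[:, medoids]
    nearest = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(d.shape[0]), nearest].sum())
    return nearest, cost


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(current - d[:, c], 0).sum() if c not in medoids else -1.0
                for c in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = d.shape[0]
    medoids = list(medoids)
    _, cost = _assign_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best_delta, best_swap = 0.0, None
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                _, trial_cost = _assign_cost(d, trial)
                delta = trial_cost - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            _, cost = _assign_cost(d, medoids)
            improved = True
    return medoids, cost


def cluster_k_groups(
    d: DistanceMatrix,
    k: int = 3,
    n_restarts: int = 10,
    seed: int | None = None,
) -> Partition:
    """PAM-style k-medoids on a precomputed distance matrix.

    Restart 0 uses the deterministic BUILD initialization; the remaining
    restarts draw random medoid sets.  Returns the best partition by total
    within-cluster distance to medoid.
    """
    n = d.n
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of points n={n}")
    if d.has_undefined():
        raise ValidationError("clustering requires fully defined distances")
    rng = np.random.default_rng(seed)
    best: tuple[float, list[int]] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            init = _pam_build(d.data, k)
        else:
            init = list(rng.choice(n, size=k, replace=False))
        medoids, cost = _pam_swap(d.data, init)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids)
    cost, medoids = best
    nearest, _ = _assign_cost(d.data, medoids)
    assignment = {lab: int(c) for lab, c in zip(d.labels, nearest)}
    return Partition(
        assignment=assignment,
        medoids=[d.labels[m] for m in medoids],
        total_cost=cost,
    )


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p: float
    n_permutations: int
    method: str


def _lower(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> MantelResult:
    """Two-sided Mantel test (Pearson r of lower triangles, joint row/column
    permutations of the second matrix).

    ``method="exhaustive"`` enumerates all n! permutations (automatic for
    n <= 7); ``"sampled"`` draws ``n_permutations`` random permutations and
    reports ``p = (1 + hits) / (1 + n_permutations)``.
    """
    if set(d1.labels) != set(d2.labels):
        raise ValidationError("Mantel requires identical label sets")
    if d1.n < 4:
        raise ValidationError("Mantel requires at least 4 samples")
    d2 = d2.reordered(d1.labels)
    x = _lower(d1.data)
    y = _lower(d2.data)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("Mantel requires fully defined distances")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in a distance triangle")
    if method == "auto":
        method = "exhaustive" if d1.n <= 7 else "sampled"
    if method not in ("exhaustive", "sampled"):
        raise ValidationError(f"unknown Mantel method {method!r}")

    xc = x - x.mean()
    yc = y - y.mean()
    xnorm = math.sqrt(float(xc @ xc))

    def corr_with(perm: np.ndarray) -> float:
        yp = _lower(d2.data[np.ix_(perm, perm)])
        ypc = yp - yp.mean()
        return float(xc @ ypc) / (xnorm * math.sqrt(float(ypc @ ypc)))

    r = float(np.corrcoef(x, y)[0, 1])
    n = d1.n
    if method == "exhaustive":
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(corr_with(np.array(perm))) >= abs(r) - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if abs(corr_with(perm)) >= abs(r) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        n_used = n_permutations
    return MantelResult(
        r=r, r_squared=r * r, p=float(p), n_permutations=n_used, method=method
    )


# ---------------------------------------------------------------------------
# comparing two sets of pairwise distances


@dataclass
class DistanceSetComparison:
    mean_a: float
    mean_b: float
    t_statistic: float
    p_parametric: float
    p_permutation: float
    n_a: int
    n_b: int


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as t_dist

    p = 2 * float(t_dist.sf(abs(t), df))
    return float(t), p


def compare_distance_sets(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> DistanceSetComparison:
    """Compare two distance distributions (lower triangles of d1 vs d2).

    Reports the classical pooled-variance two-sample t test and, because
    pairwise distances are not independent observations, a permutation p in
    which triangle entries are reshuffled between the two sets.
    """
    a = _lower(d1.data)
    b = _lower(d2.data)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each triangle needs at least 2 entries")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("undefined distances present")
    t, p_param = _pooled_t(a, b)
    obs = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        stat = abs(pool[: len(a)].mean() - pool[len(a) :].mean())
        if stat >= obs - 1e-15:
            hits += 1
    p_perm = (1 + hits) / (1 + n_permutations)
    return DistanceSetComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        p_parametric=p_param,
        p_permutation=float(p_perm),
        n_a=len(a),
        n_b=len(b),
    )
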