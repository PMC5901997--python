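"""Cryptic-diversity inference from genetic distance and host co-occurrence.

The chain: Spearman co-occurrence of OTU abundance profiles across hosts,
a linear fit of co-occurrence against pairwise genetic distance with
Mantel-style permutation significance, an explicit maximal-separation
estimator of the co-occurrence distance threshold, single-linkage grouping
below that threshold, and a within-vs-between permutation test of group
co-exclusion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .tables import AbundanceTable, DistanceMatrix, ValidationError

__all__ = [
    "CooccurrenceMatrix",
    "DistanceCooccurrenceFit",
    "ThresholdEstimate",
    "CrypticGroups",
    "CoexclusionResult",
    "spearman_cooccurrence",
    "fit_distance_cooccurrence",
    "estimate_threshold",
    "estimate_threshold_from_pairs",
    "cluster_below_threshold",
    "coexclusion_test",
]


@dataclass
class CooccurrenceMatrix:
    """Spearman rho between OTU abundance profiles, over samples."""

    labels: list[str]
    rho: np.ndarray
    zero_variance: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.rho[i, j]


def spearman_cooccurrence(t: AbundanceTable) -> CooccurrenceMatrix:
    """Pairwise Spearman correlation (average ranks for ties) between the
    abundance profiles of every pair of taxa, across samples.

    Taxa with zero variance across samples are flagged and their
    correlations are ``nan``.
    """
    if len(t.sample_ids) < 3:
        raise ValidationError("need at least 3 samples for co-occurrence")
    x = t.values  # samples x taxa
    ranks = np.apply_along_axis(rankdata, 0, x)
    sd = ranks.std(axis=0)
    zero_var = [t.taxon_ids[i] for i in np.nonzero(sd == 0)[0]]
    centered = ranks - ranks.mean(axis=0)
    cov = centered.T @ centered
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0, out=rho)
    return CooccurrenceMatrix(list(t.taxon_ids), rho, zero_var)


# ---------------------------------------------------------------------------
# distance vs co-occurrence fit


@dataclass
class DistanceCooccurrenceFit:
    slope: float
    intercept: float
    r: float
    p_permutation: float
    p_parametric: float
    n_pairs: int


def _paired_triangles(
    g: DistanceMatrix, c: CooccurrenceMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if set(g.labels) != set(c.labels):
        raise ValidationError("distance and co-occurrence label sets differ")
    order = [c.labels.index(l) for l in g.labels]
    rho = c.rho[np.ix_(order, order)]
    i, j = np.tril_indices(g.n, k=-1)
    gd, cc = g.data[i, j], rho[i, j]
    ok = np.isfinite(gd) & np.isfinite(cc)
    return gd[ok], cc[ok], ok


def fit_distance_cooccurrence(
    g: DistanceMatrix,
    c: CooccurrenceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> DistanceCooccurrenceFit:
    """OLS of co-occurrence on genetic distance over lower-triangle pairs.

    Significance is assessed Mantel-style (joint row/column permutation of
    the co-occurrence matrix, two-sided on \\|r\\|) because pairs sharing an
    OTU are not independent; a parametric p is reported alongside.
    """
    gd, cc, _ = _paired_triangles(g, c)
    if len(gd) < 3:
        raise ValidationError("need at least 3 defined pairs")
    if np.ptp(gd) == 0:
        raise ValidationError("degenerate: all genetic distances equal")
    slope, intercept = np.polyfit(gd, cc, 1)
    r = float(np.corrcoef(gd, cc)[0, 1])

    df = len(gd) - 2
    if abs(r) >= 1:
        p_param = 0.0
    else:
        tstat = r * math.sqrt(df / (1 - r * r))
        p_param = 2 * float(t_dist.sf(abs(tstat), df))

    n = g.n
    order = [c.labels.index(l) for l in g.labels]
    rho = c.rho[np.ix_(order, order)]
    i, j = np.tril_indices(n, k=-1)
    gd_full = g.data[i, j]

    def perm_r(perm: np.ndarray) -> float:
        cp = rho[np.ix_(perm, perm)][i, j]
        ok = np.isfinite(gd_full) & np.isfinite(cp)
        if ok.sum() < 3 or np.ptp(cp[ok]) == 0:
            return 0.0
        return float(np.corrcoef(gd_full[ok], cp[ok])[0, 1])

    if method == "auto":
        method = "exhaustive" if n <= 6 else "sampled"
    if method == "exhaustive":
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(perm_r(np.array(perm))) >= abs(r) - 1e-12:
                hits += 1
        p = hits / total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if abs(perm_r(rng.permutation(n))) >= abs(r) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    return DistanceCooccurrenceFit(
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        p_permutation=float(p),
        p_parametric=p_param,
        n_pairs=len(gd),
    )


# ---------------------------------------------------------------------------
# threshold estimation


@dataclass
class ThresholdEstimate:
    threshold: float
    t_statistic: float
    n_below: int
    n_above: int
    n_candidates: int


def _split_t(below: np.ndarray, above: np.ndarray) -> float:
    na, nb = len(below), len(above)
    df = na + nb - 2
    if df <= 0:
        return 0.0
    sp2 = (
        np.sum((below - below.mean()) ** 2) + np.sum((above - above.mean()) ** 2)
    ) / df
    diff = below.mean() - above.mean()
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(sp2 * (1 / na + 1 / nb)))


def estimate_threshold_from_pairs(
    distances: np.ndarray, correlations: np.ndarray
) -> ThresholdEstimate:
    """Maximal-separation scan over matched (distance, correlation) pairs.

    Candidate thresholds are midpoints between consecutive sorted unique
    distances; the returned candidate maximizes the pooled two-sample t
    statistic of (sub-threshold minus supra-threshold) correlations, ties
    broken toward the smallest candidate.
    """
    d = np.asarray(distances, dtype=float)
    c = np.asarray(correlations, dtype=float)
    ok = np.isfinite(d) & np.isfinite(c)
    d, c = d[ok], c[ok]
    if len(d) < 4:
        raise ValidationError("need at least 4 defined pairs")
    uniq = np.unique(d)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 distinct distances")
    order = np.argsort(d, kind="stable")
    d, c = d[order], c[order]
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_cand, best_split = -math.inf, None, None
    for cand in candidates:
        k = int(np.searchsorted(d, cand))
        below, above = c[:k], c[k:]
        t = _split_t(below, above)
        if t > best_t + 1e-12:
            best_t, best_cand, best_split = t, float(cand), (len(below), len(above))
    return ThresholdEstimate(
        threshold=best_cand,
        t_statistic=best_t,
        n_below=best_split[0],
        n_above=best_split[1],
        n_candidates=len(candidates),
    )


def estimate_threshold(g: DistanceMatrix, c: CooccurrenceMatrix) -> ThresholdEstimate:
    """Estimate the genetic distance below which OTU pairs co-occur."""
    gd, cc, _ = _paired_triangles(g, c)
    return estimate_threshold_from_pairs(gd, cc)


# ---------------------------------------------------------------------------
# grouping below threshold


@dataclass
class CrypticGroups:
    threshold: float
    assignment: dict[str, int]
    n_groups: int
    mean_within_correlation: float | None = None
    mean_between_correlation: float | None = None


def cluster_below_threshold(g: DistanceMatrix, threshold: float) -> CrypticGroups:
    """Single-linkage grouping: connected components of the graph whose edges
    are OTU pairs at distance strictly below ``threshold``.

    Group indices are ordered by descending size, ties by lexicographically
    smallest member.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    n = g.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            dij = g.data[i, j]
            if np.isfinite(dij) and dij < threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(g.labels[i])
    ordered = sorted(comps.values(), key=lambda mem: (-len(mem), min(mem)))
    assignment = {lab: gi for gi, mem in enumerate(ordered) for lab in mem}
    return CrypticGroups(
        threshold=float(threshold),
        assignment=assignment,
        n_groups=len(ordered),
    )


# ---------------------------------------------------------------------------
# co-exclusion test


@dataclass
class CoexclusionResult:
    mean_within: float
    mean_between: float
    difference: float
    p: float
    n_within: int
    n_between: int


def _within_between(
    labels: list[str], groups: np.ndarray, rho: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.tril_indices(len(labels), k=-1)
    same = groups[i] == groups[j]
    vals = rho[i, j]
    ok = np.isfinite(vals)
    return vals[same & ok], vals[~same & ok]


def coexclusion_test(
    groups: CrypticGroups,
    c: CooccurrenceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> CoexclusionResult:
    """Test whether within-group co-occurrence exceeds between-group
    co-occurrence, by random relabeling of group membership (sizes kept)."""
    if groups.n_groups < 2:
        raise ValidationError("need at least 2 groups")
    labels = c.labels
    try:
        gvec = np.array([groups.assignment[l] for l in labels])
    except KeyError as e:
        raise ValidationError(f"OTU {e.args[0]!r} missing from groups") from None
    within, between = _within_between(labels, gvec, c.rho)
    if len(within) == 0 or len(between) == 0:
        raise ValidationError("within or between pair set is empty")
    obs = within.mean() - between.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(gvec)
        w, b = _within_between(labels, perm, c.rho)
        if w.mean() - b.mean() >= obs - 1e-15:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return CoexclusionResult(
        mean_within=float(within.mean()),
        mean_between=float(between.mean()),
        difference=float(obs),
        p=float(p),
        n_within=len(within),
        n_between=len(between),
    )
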