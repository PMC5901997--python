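"""Sequence-level computation.

Pairwise p-distance with pairwise deletion, a composite-frequency TN93-form
substitutions/site distance, greedy centroid OTU clustering at an identity
threshold, nearest-reference taxonomic assignment with rank summaries, and
neighbor-joining tree export to Newick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import Align

from .tables import DistanceMatrix, SequenceCollection, ValidationError

__all__ = [
    "TaxAssignment",
    "p_distance",
    "pairwise_identity",
    "mcl_distance",
    "greedy_cluster",
    "assign_taxonomy",
    "rank_summary",
    "nj_tree",
    "RANK_THRESHOLDS",
]

_GOOD = frozenset("ACGT")

#: Default identity cutoffs granting each taxonomic rank.
RANK_THRESHOLDS = {
    "species": 0.97,
    "genus": 0.95,
    "family": 0.90,
    "class": 0.80,
}


def _effective_mask(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValidationError("aligned sequences must have equal length")
    xa = np.frombuffer(a.encode(), dtype="S1")
    xb = np.frombuffer(b.encode(), dtype="S1")
    good = np.frombuffer(b"ACGT", dtype="S1")
    mask = np.isin(xa, good) & np.isin(xb, good)
    return xa, xb, mask


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching sites, pairwise deletion of gaps/N.

    Returns ``nan`` when the pair shares no effective sites.
    """
    xa, xb, mask = _effective_mask(a, b)
    eff = int(mask.sum())
    if eff == 0:
        return math.nan
    return float((xa[mask] != xb[mask]).sum()) / eff


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical effective sites after (if needed) global alignment.

    Equal-length sequences are compared position-by-position; unequal lengths
    are globally aligned first.
    """
    if len(a) != len(b):
        aln = _aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
        a, b = str(aln[0]), str(aln[1])
    d = p_distance(a, b)
    return math.nan if math.isnan(d) else 1.0 - d


# ---------------------------------------------------------------------------
# composite-frequency TN93 distance


def _pooled_frequencies(seqs: list[str]) -> dict[str, float]:
    counts = {b: 0 for b in "ACGT"}
    for s in seqs:
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no unambiguous bases in collection")
    return {b: c / total for b, c in counts.items()}


def _tn93_pair(
    a: str, b: str, pi: dict[str, float]
) -> float:
    """TN93 distance for one pair given (possibly pooled) base frequencies."""
    xa, xb, mask = _effective_mask(a, b)
    eff = int(mask.sum())
    if eff == 0:
        return math.nan
    sa, sb = xa[mask], xb[mask]
    diff = sa != sb
    pair = set()
    p1 = p2 = q = 0
    for ca, cb in zip(sa[diff], sb[diff]):
        key = frozenset((ca, cb))
        if key == frozenset((b"A", b"G")):
            p1 += 1
        elif key == frozenset((b"C", b"T")):
            p2 += 1
        else:
            q += 1
    p1 /= eff
    p2 /= eff
    q /= eff

    pa, pc, pg, pt = pi["A"], pi["C"], pi["G"], pi["T"]
    pr, py = pa + pg, pc + pt
    if pr <= 0 or py <= 0:
        return math.nan
    k1 = 2 * pa * pg / pr
    k2 = 2 * pc * pt / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)

    terms = 0.0
    if k1 > 0:
        w1 = 1 - p1 / k1 - q / (2 * pr)
        if w1 <= 0:
            return math.nan
        terms += -k1 * math.log(w1)
    elif p1 > 0:
        return math.nan
    if k2 > 0:
        w2 = 1 - p2 / k2 - q / (2 * py)
        if w2 <= 0:
            return math.nan
        terms += -k2 * math.log(w2)
    elif p2 > 0:
        return math.nan
    w3 = 1 - q / (2 * pr * py)
    if w3 <= 0:
        return math.nan
    terms += -k3 * math.log(w3)
    return max(terms, 0.0)


def mcl_distance(
    seqs: SequenceCollection, per_pair_frequencies: bool = False
) -> DistanceMatrix:
    """Substitutions/site between all pairs of aligned sequences.

    The model is TN93; by default base frequencies are pooled over the whole
    collection (the composite element), with per-pair estimation behind a
    flag.  Saturated pairs (non-positive log argument) are marked ``nan``.
    """
    ids = seqs.ids()
    if len(ids) < 2:
        raise ValidationError("need at least 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError("sequences must be aligned to equal length")
    pooled = None if per_pair_frequencies else _pooled_frequencies(list(seqs.values()))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            pi = pooled if pooled is not None else _pooled_frequencies([a, b])
            dij = _tn93_pair(a, b, pi)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# greedy OTU clustering


def greedy_cluster(
    seqs: SequenceCollection,
    similarity: float = 0.95,
    abundances: Mapping[str, float] | None = None,
) -> dict[str, list[str]]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed in descending abundance (ties broken by
    lexicographic id); each joins the first existing centroid with identity
    >= ``similarity``, otherwise it founds a new OTU.  Returns centroid id ->
    member ids (centroid first), in centroid founding order.
    """
    if not seqs:
        raise ValidationError("empty sequence collection")
    if not 0 < similarity <= 1:
        raise ValidationError("similarity must be in (0, 1]")
    if abundances is None:
        order = sorted(seqs.ids())
    else:
        order = sorted(seqs.ids(), key=lambda sid: (-abundances.get(sid, 0.0), sid))
    clusters: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for centroid in clusters:
            ident = pairwise_identity(seqs[centroid], seqs[sid])
            if not math.isnan(ident) and ident >= similarity - 1e-12:
                clusters[centroid].append(sid)
                placed = True
                break
        if not placed:
            clusters[sid] = [sid]
    return clusters


# ---------------------------------------------------------------------------
# taxonomy assignment


@dataclass
class TaxAssignment:
    otu_id: str
    best_reference: str
    identity: float
    name: str
    rank: str  # species | genus | family | class | unassigned


def assign_taxonomy(
    otus: SequenceCollection,
    refs: SequenceCollection,
    ref_taxonomy: Mapping[str, Mapping[str, str]],
    thresholds: Mapping[str, float] | None = None,
) -> list[TaxAssignment]:
    """Assign each OTU to its best-identity reference, granting the deepest
    rank whose identity cutoff is met.

    ``ref_taxonomy`` maps reference id -> {"species": ..., "genus": ...,
    "family": ..., "class": ...}.
    """
    if not refs:
        raise ValidationError("empty reference set")
    thresholds = dict(RANK_THRESHOLDS if thresholds is None else thresholds)
    out = []
    for oid, oseq in otus.items():
        best_ref, best_ident = None, -1.0
        for rid, rseq in refs.items():
            ident = pairwise_identity(oseq, rseq)
            if not math.isnan(ident) and ident > best_ident:
                best_ref, best_ident = rid, ident
        rank = "unassigned"
        for r in ("species", "genus", "family", "class"):
            if best_ident >= thresholds[r] - 1e-12:
                rank = r
                break
        tax = ref_taxonomy.get(best_ref, {})
        name = tax.get(rank, best_ref) if rank != "unassigned" else ""
        out.append(
            TaxAssignment(
                otu_id=oid,
                best_reference=best_ref,
                identity=float(best_ident),
                name=name,
                rank=rank,
            )
        )
    return out


def rank_summary(assignments: list[TaxAssignment]) -> dict[str, float]:
    """Percent of OTUs assigned at each rank (the identification-level pie)."""
    total = len(assignments)
    if total == 0:
        raise ValidationError("no assignments")
    out = {}
    for rank in ("species", "genus", "family", "class", "unassigned"):
        out[rank] = 100.0 * sum(1 for a in assignments if a.rank == rank) / total
    return out


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, returned as Newick text.

    Negative branch lengths are clamped to zero with a warning.
    """
    if d.n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if d.has_undefined():
        raise ValidationError("undefined distances present")

    clamped = False

    def fmt(length: float) -> str:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        return f"{length:.10g}"

    dm = d.data.astype(float).copy()
    nodes = list(d.labels)
    active = list(range(len(nodes)))
    newick = {i: nodes[i] for i in active}
    dist = {(i, j): dm[i, j] for i in active for j in active if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = len(nodes)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best, pair = None, None
        for ai in range(n):
            for bi in range(ai + 1, n):
                i, j = active[ai], active[bi]
                q = (n - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best - 1e-15:
                    best, pair = q, (i, j)
        i, j = pair
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{fmt(li)},{newick[j]}:{fmt(lj)})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    dij, dik, djk = get(i, j), get(i, k), get(j, k)
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    tree = f"({newick[i]}:{fmt(li)},{newick[j]}:{fmt(lj)},{newick[k]}:{fmt(lk)});"
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0", stacklevel=2)
    return tree
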