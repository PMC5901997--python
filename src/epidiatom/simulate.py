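"""Synthetic paired microscopy/metabarcoding observations with ground truth.

Latent host-biofilm communities are built from morphospecies that each hide
several genetic lineages; lineages belong to habitat groups that control
which hosts carry them.  The two observation channels then apply the stated
bias mechanisms: microscopy counts a fixed number of valves and also sees a
dead-frustule pool; metabarcoding draws reads with probability proportional
to abundance times biovolume**beta (gene copy number scales with cell
biovolume).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SequenceCollection, ValidationError

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "expected_channel_bias",
    "collapse_to_morphospecies",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# genus names cycled over morphospecies so the guild stage has real genera
_GENERA = (
    "Labellicula",
    "Nitzschia",
    "Halamphora",
    "Navicula",
    "Entomoneis",
    "Amphora",
    "Olifantiella",
    "Tursicola",
    "Pseudo-nitzschia",
)


@dataclass
class SimulationParams:
    """Generator configuration; defaults match the desk-scale scenario of
    7 hosts and a 60-lineage focal morphospecies split into 4 groups."""

    n_hosts: int = 7
    n_morphospecies: int = 8
    focal_lineages: int = 60
    background_lineages: int = 2
    n_groups: int = 4
    seq_length: int = 312
    phi: float = 0.2  # dead-frustule carryover weight
    valve_count: int = 400
    read_depth: int = 30000
    beta: float = 1.0  # copy-number ~ biovolume**beta
    sigma: float = 0.1  # lognormal co-occurrence noise
    delta_within: float = 0.015  # target within-group divergence (subst/site)
    delta_between: float = 0.10  # target between-group divergence
    dirichlet_alpha: float | None = 1.0  # None = equal shares
    biovolume_range: tuple[float, float] = (15.0, 2000.0)
    biovolumes: tuple[float, ...] | None = None  # explicit override

    def validate(self) -> None:
        if self.n_hosts < 1 or self.n_morphospecies < 1:
            raise ValidationError("need at least one host and one morphospecies")
        if self.focal_lineages < 1 or self.background_lineages < 1:
            raise ValidationError("lineage counts must be >= 1")
        if not 0 <= self.phi < 1:
            raise ValidationError("phi must be in [0, 1)")
        if self.delta_within >= self.delta_between:
            raise ValidationError("delta_within must be < delta_between")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.biovolumes is not None and len(self.biovolumes) != self.n_morphospecies:
            raise ValidationError(
                "biovolumes length must equal n_morphospecies"
            )


@dataclass
class SyntheticTruth:
    params: SimulationParams
    seed: int
    morphospecies_ids: list[str]
    biovolumes: np.ndarray  # per morphospecies, um^3
    lineage_ids: list[str]
    lineage_morphospecies: np.ndarray  # index into morphospecies
    lineage_group: np.ndarray  # habitat-group index per lineage
    host_group_choice: np.ndarray  # n_hosts x n_morphospecies
    latent: np.ndarray  # n_hosts x n_lineages, rows sum to 1
    dead_pool: np.ndarray  # morphospecies composition of the dead pool
    focal_ids: list[str]

    def group_of(self) -> dict[str, int]:
        return {
            lid: int(g) for lid, g in zip(self.lineage_ids, self.lineage_group)
        }

    def to_json(self) -> str:
        payload = {
            "params": asdict(self.params),
            "seed": self.seed,
            "morphospecies_ids": self.morphospecies_ids,
            "biovolumes": self.biovolumes.tolist(),
            "lineage_ids": self.lineage_ids,
            "lineage_morphospecies": self.lineage_morphospecies.tolist(),
            "lineage_group": self.lineage_group.tolist(),
            "host_group_choice": self.host_group_choice.tolist(),
            "latent": self.latent.tolist(),
            "dead_pool": self.dead_pool.tolist(),
            "focal_ids": self.focal_ids,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    truth: SyntheticTruth
    microscopy: AbundanceTable  # counts over morphospecies
    metabarcoding: AbundanceTable  # read counts over lineages
    sequences: SequenceCollection


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate(params: SimulationParams | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate one paired dataset; identical (params, seed) -> identical output."""
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)
    p = params
    L = p.seq_length

    morpho_ids = [
        f"{_GENERA[m % len(_GENERA)]}_sp{m + 1:02d}" for m in range(p.n_morphospecies)
    ]
    if p.biovolumes is not None:
        biovol = np.asarray(p.biovolumes, dtype=float)
    else:
        lo, hi = p.biovolume_range
        biovol = np.exp(rng.uniform(math.log(lo), math.log(hi), p.n_morphospecies))

    lineage_ids: list[str] = []
    lin_morpho: list[int] = []
    lin_group: list[int] = []
    seqs = SequenceCollection()
    # Substitution counts are calibrated so *pairwise* corrected divergences
    # hit the targets: invert the correction (Jukes-Cantor form is adequate
    # at these scales) to a raw mismatch fraction, then split it between the
    # two endpoints of a pair.  Between-group pairs additionally carry the
    # two within-group mutation loads, which is subtracted out.
    def _p_raw(d: float) -> float:
        return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))

    n_w = max(1, round(_p_raw(p.delta_within) * L / 2))
    n_b = max(1, round((_p_raw(p.delta_between) * L - 2 * n_w) / 2))
    for m in range(p.n_morphospecies):
        n_lin = p.focal_lineages if m == 0 else p.background_lineages
        ancestral = rng.choice(_BASES, size=L)
        groups_here = sorted({l % p.n_groups for l in range(n_lin)})
        consensus = {g: _mutate(ancestral, n_b, rng) for g in groups_here}
        for l in range(n_lin):
            g = l % p.n_groups
            lid = f"{morpho_ids[m]}_lin{l + 1:03d}"
            seq = _mutate(consensus[g], n_w, rng)
            lineage_ids.append(lid)
            lin_morpho.append(m)
            lin_group.append(g)
            seqs.add(lid, seq.tobytes().decode())
    lin_morpho = np.array(lin_morpho)
    lin_group = np.array(lin_group)
    n_lin_total = len(lineage_ids)

    # which habitat group each host carries, per morphospecies (balanced)
    host_choice = np.zeros((p.n_hosts, p.n_morphospecies), dtype=int)
    for m in range(p.n_morphospecies):
        present = sorted(set(lin_group[lin_morpho == m]))
        pattern = np.array([present[h % len(present)] for h in range(p.n_hosts)])
        rng.shuffle(pattern)
        host_choice[:, m] = pattern

    latent = np.zeros((p.n_hosts, n_lin_total))
    for h in range(p.n_hosts):
        present = host_choice[h, lin_morpho] == lin_group
        k = int(present.sum())
        if p.dirichlet_alpha is None:
            w = np.ones(k)
        else:
            w = rng.dirichlet(np.full(k, p.dirichlet_alpha))
            w = np.maximum(w, 1e-12)
        if p.sigma > 0:
            w = w * rng.lognormal(0.0, p.sigma, size=k)
        latent[h, present] = w / w.sum()

    dead_pool = np.full(p.n_morphospecies, 1.0 / p.n_morphospecies)

    # microscopy channel: valves over morphospecies + dead-frustule mixture
    morpho_latent = np.zeros((p.n_hosts, p.n_morphospecies))
    for m in range(p.n_morphospecies):
        morpho_latent[:, m] = latent[:, lin_morpho == m].sum(axis=1)
    micro_counts = np.zeros((p.n_hosts, p.n_morphospecies), dtype=float)
    for h in range(p.n_hosts):
        probs = (1 - p.phi) * morpho_latent[h] + p.phi * dead_pool
        micro_counts[h] = rng.multinomial(p.valve_count, probs / probs.sum())

    # metabarcoding channel: reads over lineages, copy number ~ biovolume**beta
    meta_counts = np.zeros((p.n_hosts, n_lin_total), dtype=float)
    copy_factor = biovol[lin_morpho] ** p.beta
    for h in range(p.n_hosts):
        w = latent[h] * copy_factor
        meta_counts[h] = rng.multinomial(p.read_depth, w / w.sum())

    host_ids = [f"host{h + 1}" for h in range(p.n_hosts)]
    truth = SyntheticTruth(
        params=p,
        seed=seed,
        morphospecies_ids=morpho_ids,
        biovolumes=biovol,
        lineage_ids=lineage_ids,
        lineage_morphospecies=lin_morpho,
        lineage_group=lin_group,
        host_group_choice=host_choice,
        latent=latent,
        dead_pool=dead_pool,
        focal_ids=[lid for lid, m in zip(lineage_ids, lin_morpho) if m == 0],
    )
    return SyntheticDataset(
        truth=truth,
        microscopy=AbundanceTable(host_ids, morpho_ids, micro_counts, "count"),
        metabarcoding=AbundanceTable(host_ids, lineage_ids, meta_counts, "count"),
        sequences=seqs,
    )


def expected_channel_bias(truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form expected (microscopy %, metabarcoding %) per host and
    morphospecies, used as oracles for :func:`generate`."""
    p = truth.params
    n_m = p.n_morphospecies
    morpho_latent = np.zeros((p.n_hosts, n_m))
    meta_w = np.zeros((p.n_hosts, n_m))
    copy_factor = truth.biovolumes[truth.lineage_morphospecies] ** p.beta
    for m in range(n_m):
        sel = truth.lineage_morphospecies == m
        morpho_latent[:, m] = truth.latent[:, sel].sum(axis=1)
        meta_w[:, m] = (truth.latent[:, sel] * copy_factor[sel]).sum(axis=1)
    micro = (1 - p.phi) * morpho_latent + p.phi * truth.dead_pool
    micro = 100.0 * micro / micro.sum(axis=1, keepdims=True)
    meta = 100.0 * meta_w / meta_w.sum(axis=1, keepdims=True)
    hosts = [f"host{h + 1}" for h in range(p.n_hosts)]
    return (
        pd.DataFrame(micro, index=hosts, columns=truth.morphospecies_ids),
        pd.DataFrame(meta, index=hosts, columns=truth.morphospecies_ids),
    )


def collapse_to_morphospecies(ds: SyntheticDataset) -> AbundanceTable:
    """Sum the metabarcoding lineage counts up to morphospecies."""
    truth = ds.truth
    n_m = truth.params.n_morphospecies
    out = np.zeros((len(ds.metabarcoding.sample_ids), n_m))
    for m in range(n_m):
        sel = truth.lineage_morphospecies == m
        out[:, m] = ds.metabarcoding.values[:, sel].sum(axis=1)
    return AbundanceTable(
        list(ds.metabarcoding.sample_ids), list(truth.morphospecies_ids), out, "count"
    )
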