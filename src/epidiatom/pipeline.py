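"""End-to-end orchestration of the two-channel analysis.

Stages: normalize both channels, Bray-Curtis, NMDS and k-group clustering
per channel, Mantel across channels, comparison of the two distance
distributions, genetic distances on the focal OTU set, the cryptic-structure
chain, and guild profiles on the morphology channel.  A single global seed
is expanded into per-stage seeds with ``numpy.random.SeedSequence.spawn``
(stage order is fixed, so summaries are byte-identical across runs).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np

from . import community, cryptic, guilds, seqops, simulate
from .tables import (
    AbundanceTable,
    SequenceCollection,
    ValidationError,
    read_abundance_table,
    read_fasta,
    to_relative_abundance,
    write_abundance_table,
    write_fasta,
)

__all__ = ["RunConfig", "run_pipeline", "validate_summary"]

_KNOWN_KEYS = {
    "microscopy_table",
    "metabarcoding_table",
    "sequences_fasta",
    "focal_ids",
    "simulate",
    "simulate_params",
    "k",
    "nmds_dimensions",
    "nmds_restarts",
    "n_permutations",
    "otu_similarity",
    "seed",
}


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    microscopy_table: str | None = None
    metabarcoding_table: str | None = None
    sequences_fasta: str | None = None
    focal_ids: list[str] | None = None
    simulate: bool = False
    simulate_params: dict[str, Any] = field(default_factory=dict)
    k: int = 3
    nmds_dimensions: int = 2
    nmds_restarts: int = 20
    n_permutations: int = 999
    otu_similarity: float = 0.95
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Per-stage seeds: child i of SeedSequence(seed), as a 32-bit int."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


class _Log:
    def __init__(self) -> None:
        self.lines: list[str] = []
        self._t0 = time.perf_counter()

    def stage(self, name: str, **info: Any) -> None:
        elapsed = time.perf_counter() - self._t0
        details = " ".join(f"{k}={v}" for k, v in info.items())
        self.lines.append(f"[{elapsed:8.2f}s] {name}: {details}")


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute all stages and return the machine-readable summary.

    If ``outdir`` is given, stage outputs (tables, coordinates, newick,
    summary JSON, log) are written there.
    """
    seeds = _stage_seeds(cfg.seed)
    log = _Log()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, err: Exception) -> None:
        log.stage(stage, error=repr(err))
        if out is not None:
            (out / "run.log").write_text("\n".join(log.lines) + "\n")
        raise ValidationError(f"pipeline stage {stage!r} failed: {err}") from err

    # ---- stage 0: inputs
    try:
        if cfg.simulate:
            params = simulate.SimulationParams(**cfg.simulate_params)
            ds = simulate.generate(params, seed=seeds[0])
            micro, meta, seqs = ds.microscopy, ds.metabarcoding, ds.sequences
            focal = ds.truth.focal_ids
            truth = ds.truth
        else:
            if cfg.microscopy_table is None or cfg.metabarcoding_table is None:
                raise ValidationError(
                    "either set simulate=true or give both input tables"
                )
            micro = read_abundance_table(cfg.microscopy_table)
            meta = read_abundance_table(cfg.metabarcoding_table)
            seqs = (
                read_fasta(cfg.sequences_fasta) if cfg.sequences_fasta else None
            )
            focal = cfg.focal_ids or (list(seqs.ids()) if seqs else [])
            truth = None
        log.stage(
            "inputs",
            microscopy=micro.shape,
            metabarcoding=meta.shape,
            sequences=len(seqs) if seqs else 0,
        )
    except ValidationError as e:
        fail("inputs", e)

    summary: dict[str, Any] = {
        "seed": cfg.seed,
        "parameters": {
            "k": cfg.k,
            "nmds_dimensions": cfg.nmds_dimensions,
            "nmds_restarts": cfg.nmds_restarts,
            "n_permutations": cfg.n_permutations,
            "otu_similarity": cfg.otu_similarity,
        },
        "channels": {},
    }

    bc = {}
    for name, table, seed_ix in (("microscopy", micro, 1), ("metabarcoding", meta, 2)):
        ch: dict[str, Any] = {}
        try:
            rel = to_relative_abundance(table)
            d = community.bray_curtis(rel)
            bc[name] = d
            ord_ = community.nmds(
                d,
                k=cfg.nmds_dimensions,
                n_restarts=cfg.nmds_restarts,
                seed=seeds[seed_ix],
            )
            part = community.cluster_k_groups(d, k=cfg.k, seed=seeds[seed_ix + 2])
            ch["n_samples"], ch["n_taxa"] = table.shape
            ch["mean_bray_curtis"] = float(np.mean(d.condensed()))
            ch["nmds_stress"] = ord_.stress
            ch["nmds_converged"] = ord_.converged
            ch["partition"] = {k_: int(v) for k_, v in part.assignment.items()}
            ch["medoids"] = part.medoids
            ch["partition_cost"] = part.total_cost
            summary["channels"][name] = ch
            if out is not None:
                _write_ordination(ord_, out / f"nmds_{name}.tsv")
                _write_partition(part, out / f"partition_{name}.tsv")
                d.write_tsv(out / f"bray_curtis_{name}.tsv")
            log.stage(f"channel:{name}", shape=table.shape, stress=round(ord_.stress, 4))
        except ValidationError as e:
            fail(f"channel:{name}", e)

    try:
        mres = community.mantel(
            bc["microscopy"],
            bc["metabarcoding"],
            n_permutations=cfg.n_permutations,
            seed=seeds[5],
        )
        summary["mantel"] = {
            "r": mres.r,
            "r_squared": mres.r_squared,
            "p": mres.p,
            "n_permutations": mres.n_permutations,
            "method": mres.method,
        }
        log.stage("mantel", r=round(mres.r, 4), p=mres.p)
    except ValidationError as e:
        fail("mantel", e)

    try:
        comp = community.compare_distance_sets(
            bc["metabarcoding"],
            bc["microscopy"],
            n_permutations=cfg.n_permutations,
            seed=seeds[6],
        )
        summary["distance_comparison"] = {
            "mean_metabarcoding": comp.mean_a,
            "mean_microscopy": comp.mean_b,
            "t_statistic": comp.t_statistic,
            "p_parametric": comp.p_parametric,
            "p_permutation": comp.p_permutation,
        }
        log.stage("compare", meta=round(comp.mean_a, 3), micro=round(comp.mean_b, 3))
    except ValidationError as e:
        fail("compare", e)

    # ---- cryptic chain on the focal OTU subset of the metabarcoding channel
    if seqs is not None and focal and len(focal) >= 4:
        try:
            focal_seqs = SequenceCollection((i, seqs[i]) for i in focal)
            gdist = seqops.mcl_distance(focal_seqs)
            sub = meta.select_taxa(focal)
            cooc = cryptic.spearman_cooccurrence(sub)
            fit = cryptic.fit_distance_cooccurrence(
                gdist, cooc, n_permutations=cfg.n_permutations, seed=seeds[7],
                method="sampled",
            )
            thr = cryptic.estimate_threshold(gdist, cooc)
            groups = cryptic.cluster_below_threshold(gdist, thr.threshold)
            block: dict[str, Any] = {
                "threshold": thr.threshold,
                "threshold_t_statistic": thr.t_statistic,
                "n_groups": groups.n_groups,
                "groups": {k_: int(v) for k_, v in groups.assignment.items()},
                "fit": {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.r,
                    "p_permutation": fit.p_permutation,
                    "n_pairs": fit.n_pairs,
                },
            }
            if groups.n_groups >= 2:
                co = cryptic.coexclusion_test(
                    groups, cooc, n_permutations=cfg.n_permutations, seed=seeds[8]
                )
                block["coexclusion"] = {
                    "mean_within": co.mean_within,
                    "mean_between": co.mean_between,
                    "difference": co.difference,
                    "p": co.p,
                }
            summary["cryptic"] = block
            if out is not None:
                gdist.write_tsv(out / "genetic_distance.tsv")
                with open(out / "cryptic_groups.tsv", "w") as fh:
                    fh.write("otu\tgroup\n")
                    for otu, gi in groups.assignment.items():
                        fh.write(f"{otu}\t{gi}\n")
                if gdist.n >= 3 and not gdist.has_undefined():
                    (out / "focal_nj.nwk").write_text(seqops.nj_tree(gdist) + "\n")
            log.stage(
                "cryptic", threshold=round(thr.threshold, 4), n_groups=groups.n_groups
            )
        except ValidationError as e:
            fail("cryptic", e)

    # ---- guild profiles on the morphology channel
    try:
        lookup = guilds.default_lookup()
        assignments = {
            taxon: guilds.assign_guild(taxon, None, lookup)
            for taxon in micro.taxon_ids
        }
        prof = guilds.guild_profile(micro, assignments)
        summary["guilds"] = {
            sid: {g: float(v) for g, v in row.items()}
            for sid, row in prof.table.iterrows()
        }
        if out is not None:
            prof.table.to_csv(out / "guild_profile.tsv", sep="\t")
        log.stage("guilds", samples=len(prof.sample_ids))
    except ValidationError as e:
        fail("guilds", e)

    if truth is not None:
        summary["simulation"] = {
            "seed_used": seeds[0],
            "n_lineages": len(truth.lineage_ids),
            "n_focal": len(truth.focal_ids),
            "true_groups": {
                lid: int(g)
                for lid, g in zip(truth.lineage_ids, truth.lineage_group)
                if lid in set(truth.focal_ids)
            },
        }

    if out is not None:
        write_abundance_table(micro, out / "microscopy.tsv")
        write_abundance_table(meta, out / "metabarcoding.tsv")
        if seqs is not None:
            write_fasta(seqs, out / "sequences.fasta")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        (out / "run.log").write_text("\n".join(log.lines) + "\n")
    return summary


def _write_ordination(ord_, path: Path) -> None:
    k = ord_.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# stress={ord_.stress!r} converged={ord_.converged}\n")
        fh.write("sample\t" + "\t".join(f"dim{i + 1}" for i in range(k)) + "\n")
        for lab, row in zip(ord_.labels, ord_.coordinates):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _write_partition(part, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcluster\n")
        for lab, c in part.assignment.items():
            fh.write(f"{lab}\t{c}\n")


# ---------------------------------------------------------------------------
# minimal JSON-schema validation (subset: type / required / properties)


def _check(instance: Any, schema: dict[str, Any], path: str = "$") -> list[str]:
    errors = []
    stype = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }
    if stype and not isinstance(instance, type_map[stype]):
        return [f"{path}: expected {stype}, got {type(instance).__name__}"]
    if stype == "object":
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    return errors


def validate_summary(summary: dict[str, Any]) -> None:
    """Validate a pipeline summary against the shipped schema."""
    schema = json.loads(
        (resources.files("epidiatom.schema") / "summary.schema.json").read_text()
    )
    errors = _check(summary, schema)
    if errors:
        raise ValidationError("summary schema violations: " + "; ".join(errors))
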