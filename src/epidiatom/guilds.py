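"""Ecological guild assignment and per-sample guild profiles.

Benthic diatom taxa are mapped to one of four guilds (high profile, low
profile, motile, planktonic) from a genus-level lookup with optional size
bounds; profiles report the percent of counted units per guild per sample,
with an explicit fifth "unclassified" column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ValidationError

__all__ = [
    "GUILDS",
    "GuildRule",
    "GuildLookup",
    "GuildProfile",
    "default_lookup",
    "genus_of",
    "assign_guild",
    "guild_profile",
    "guild_extremes",
]

GUILDS = ("high_profile", "low_profile", "motile", "planktonic")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GuildRule:
    genus: str
    max_size_um: float | None  # rule applies when size <= bound; None = any size
    guild: str


class GuildLookup:
    """Validated collection of (genus, optional size bound) -> guild rules.

    Size-specific rules take precedence over genus-general rules; at most one
    rule may exist per (genus, bound) pair.
    """

    def __init__(self, rules: list[GuildRule]):
        seen: set[tuple[str, float | None]] = set()
        for r in rules:
            if r.guild not in GUILDS:
                raise ValidationError(
                    f"unknown guild {r.guild!r} for genus {r.genus!r}"
                )
            key = (r.genus.lower(), r.max_size_um)
            if key in seen:
                raise ValidationError(
                    f"conflicting duplicate rule for genus {r.genus!r}"
                    f" (max_size_um={r.max_size_um})"
                )
            seen.add(key)
        self.rules = list(rules)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GuildLookup":
        rules = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"genus", "guild"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValidationError(
                    "guild lookup CSV needs columns: genus, max_size_um, guild"
                )
            for row in reader:
                size = row.get("max_size_um", "")
                size_val = float(size) if size not in ("", None) else None
                rules.append(GuildRule(row["genus"].strip(), size_val, row["guild"].strip()))
        return cls(rules)


def default_lookup() -> GuildLookup:
    """The shipped genus -> guild table (editable config, not ground truth)."""
    with resources.as_file(
        resources.files("epidiatom.data") / "default_guilds.csv"
    ) as p:
        return GuildLookup.from_csv(p)


def genus_of(taxon: str) -> str:
    """First token of a taxon name (hyphens kept, e.g. 'Pseudo-nitzschia')."""
    return taxon.replace("_", " ").strip().split()[0] if taxon.strip() else ""


def assign_guild(
    taxon: str, size_um: float | None, lookup: GuildLookup
) -> str:
    """Guild for a taxon, or 'unclassified' when no rule matches.

    Among the rules for the taxon's genus, size-bounded rules (requiring
    ``size_um <= bound``) are tried from tightest bound up, then the
    genus-general rule.
    """
    genus = genus_of(taxon).lower()
    sized = sorted(
        (r for r in lookup.rules
         if r.genus.lower() == genus and r.max_size_um is not None),
        key=lambda r: r.max_size_um,
    )
    if size_um is not None:
        for r in sized:
            if size_um <= r.max_size_um:
                return r.guild
    for r in lookup.rules:
        if r.genus.lower() == genus and r.max_size_um is None:
            return r.guild
    return UNCLASSIFIED


@dataclass
class GuildProfile:
    """Percent of counted units per guild per sample (+ unclassified)."""

    table: pd.DataFrame  # index: sample ids; columns: GUILDS + unclassified

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def guild_profile(
    t: AbundanceTable, assignments: Mapping[str, str]
) -> GuildProfile:
    """Aggregate an abundance table into guild percentages per sample.

    Percent-mode input values are summed as-is (published rounded tables are
    echoed exactly); count-mode input is converted to percent of row total.
    """
    missing = [x for x in t.taxon_ids if x not in assignments]
    if missing:
        raise ValidationError(f"taxa without guild assignment: {missing[:5]}")
    cols = list(GUILDS) + [UNCLASSIFIED]
    out = np.zeros((len(t.sample_ids), len(cols)))
    col_idx = {g: i for i, g in enumerate(cols)}
    for j, taxon in enumerate(t.taxon_ids):
        guild = assignments[taxon]
        if guild not in col_idx:
            raise ValidationError(f"unknown guild {guild!r} for taxon {taxon!r}")
        out[:, col_idx[guild]] += t.values[:, j]
    if t.mode == "count":
        sums = t.values.sum(axis=1)
        if (sums <= 0).any():
            i = int(np.argmax(sums <= 0))
            raise ValidationError(f"sample {t.sample_ids[i]!r} has zero total")
        out = 100.0 * out / sums[:, None]
    return GuildProfile(pd.DataFrame(out, index=t.sample_ids, columns=cols))


def guild_extremes(
    p: GuildProfile, guild: str
) -> tuple[tuple[str, float], tuple[str, float]]:
    """((sample with minimum, value), (sample with maximum, value)) for a
    guild column; ties broken by first sample in input order."""
    if guild not in p.table.columns:
        raise ValidationError(f"unknown guild {guild!r}")
    col = p.table[guild].to_numpy()
    if len(col) == 0:
        raise ValidationError("empty profile")
    imin = int(np.argmin(col))
    imax = int(np.argmax(col))
    sids = p.sample_ids
    return (sids[imin], float(col[imin])), (sids[imax], float(col[imax]))
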