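"""Abundance tables, sequence collections and labeled distance matrices.

The three container types here are shared by every downstream analysis:
:class:`AbundanceTable` holds a sample x taxon matrix in either raw-count or
percent mode, :class:`SequenceCollection` holds nucleotide sequences keyed by
id, and :class:`DistanceMatrix` is a labeled symmetric matrix reused for both
community (Bray-Curtis) and genetic (substitutions/site) distances.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "SequenceCollection",
    "DistanceMatrix",
    "RichnessSummary",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative_abundance",
    "mean_per_sample",
    "richness_summary",
    "read_fasta",
    "write_fasta",
]

#: Accepted nucleotide characters (stored uppercase).
SEQ_ALPHABET = frozenset("ACGTN-")

#: Row sums accepted as "percent" when inferring table mode, and the window
#: within which percent-mode rows must fall.  The window is wide enough to
#: admit published tables whose rounded entries sum to e.g. 100.1.
PERCENT_SUM_WINDOW = (99.9, 100.1)


class ValidationError(ValueError):
    """Raised when an input file or constructed object violates a contract."""


@dataclass
class AbundanceTable:
    """Sample x taxon abundance matrix.

    Parameters
    ----------
    sample_ids, taxon_ids :
        Unique, ordered row and column labels.
    values :
        Non-negative matrix of shape ``(len(sample_ids), len(taxon_ids))``.
    mode :
        ``"count"`` for raw tallies or ``"percent"`` for relative abundances
        (each row summing to 100 within :data:`PERCENT_SUM_WINDOW`).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("count", "percent"):
            raise ValidationError(f"unknown table mode {self.mode!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.taxon_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.taxon_ids, "taxon id")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r} (ragged or empty cell)"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}"
            )
        if self.mode == "percent":
            sums = self.values.sum(axis=1)
            lo, hi = PERCENT_SUM_WINDOW
            bad = (sums < lo - 1e-6) | (sums > hi + 1e-6)
            if bad.any():
                i = int(np.argmax(bad))
                raise ValidationError(
                    f"percent-mode row {self.sample_ids[i]!r} sums to "
                    f"{sums[i]:.6g}, outside [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.taxon_ids
        )

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        """Return a sub-table restricted to ``taxa`` (kept in given order)."""
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise ValidationError(f"unknown taxa: {missing[:5]}")
        cols = [idx[t] for t in taxa]
        # a sub-table of a percent table no longer sums to 100, so drop to count
        return AbundanceTable(
            list(self.sample_ids), list(taxa), self.values[:, cols].copy(), "count"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and self.mode == other.mode
            and np.array_equal(self.values, other.values)
        )


class SequenceCollection(dict):
    """Ordered mapping of sequence id -> uppercase nucleotide string."""

    def __init__(self, items: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        super().__init__()
        items = items.items() if isinstance(items, Mapping) else items
        for sid, seq in items:
            self.add(sid, seq)

    def add(self, sid: str, seq: str) -> None:
        sid = str(sid)
        if sid in self:
            raise ValidationError(f"duplicate sequence id {sid!r}")
        seq = str(seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for id {sid!r}")
        bad = set(seq) - SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"illegal character(s) {sorted(bad)} in sequence {sid!r}"
            )
        self[sid] = seq

    def ids(self) -> list[str]:
        return list(self.keys())


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix; ``nan`` marks undefined pairs."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        _check_unique(self.labels, "label")
        if self.data.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.data.shape} != ({n}, {n})"
            )
        finite = np.isfinite(self.data)
        both = finite & finite.T
        if not np.allclose(
            self.data[both.nonzero()],
            self.data.T[both.nonzero()],
            atol=1e-9,
            rtol=0,
        ):
            raise ValidationError("distance matrix is not symmetric within 1e-9")
        diag = np.diag(self.data)
        if not np.allclose(diag[np.isfinite(diag)], 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.data[finite] < 0).any():
            raise ValidationError("negative distances present")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.data[i, j]

    def has_undefined(self) -> bool:
        i, j = np.tril_indices(self.n, k=-1)
        return bool(np.isnan(self.data[i, j]).any())

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = {l: i for i, l in enumerate(self.labels)}
        try:
            order = [idx[l] for l in labels]
        except KeyError as e:
            raise ValidationError(f"label {e.args[0]!r} not in matrix") from None
        sub = self.data[np.ix_(order, order)]
        return DistanceMatrix(list(labels), sub)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.data):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# abundance table I/O


def read_abundance_table(
    path: str | Path | io.StringIO,
    mode: str = "infer",
    sep: str = "\t",
) -> AbundanceTable:
    """Read a sample x taxon table (header = taxon ids, first column = sample ids).

    ``mode`` is ``"count"``, ``"percent"`` or ``"infer"``; infer assigns
    percent when every row sum lies in :data:`PERCENT_SUM_WINDOW`.
    """
    if mode not in ("count", "percent", "infer"):
        raise ValidationError(f"unknown read mode {mode!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate taxon id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValidationError(f"non-numeric cell in table: {e}") from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"ragged or empty cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if mode == "infer":
        sums = values.sum(axis=1)
        lo, hi = PERCENT_SUM_WINDOW
        ok = (sums >= lo - 1e-6) & (sums <= hi + 1e-6)
        mode = "percent" if len(sums) and ok.all() else "count"
    return AbundanceTable(
        list(df.index.astype(str)), list(df.columns.astype(str)), values, mode
    )


def write_abundance_table(t: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    """Write a table as TSV; floats use shortest round-trip representation."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["sample"] + t.taxon_ids) + "\n")
        for sid, row in zip(t.sample_ids, t.values):
            fh.write(sep.join([sid] + [repr(float(v)) for v in row]) + "\n")


def to_relative_abundance(t: AbundanceTable) -> AbundanceTable:
    """Convert a count table to percent mode (idempotent on percent tables)."""
    if t.mode == "percent":
        sums = t.values.sum(axis=1)
        return AbundanceTable(
            list(t.sample_ids), list(t.taxon_ids), 100.0 * t.values / sums[:, None],
            "percent",
        )
    sums = t.values.sum(axis=1)
    if (sums <= 0).any():
        i = int(np.argmax(sums <= 0))
        raise ValidationError(
            f"sample {t.sample_ids[i]!r} has zero total abundance"
        )
    return AbundanceTable(
        list(t.sample_ids), list(t.taxon_ids), 100.0 * t.values / sums[:, None],
        "percent",
    )


def mean_per_sample(total: int, n_samples: int) -> int:
    """Average units per sample, rounded half away from zero.

    E.g. a run of 510922 reads over 7 samples averages 72989 reads/sample.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if total < 0:
        raise ValidationError("total must be non-negative")
    q = total / n_samples
    return int(math.floor(q + 0.5)) if q >= 0 else int(math.ceil(q - 0.5))


@dataclass
class RichnessSummary:
    counts: dict[str, int]
    min: int
    max: int
    mean: float  # reported to 1 decimal


def richness_summary(t: AbundanceTable) -> RichnessSummary:
    """Per-sample count of taxa with positive abundance, plus min/max/mean."""
    counts = {
        sid: int((row > 0).sum()) for sid, row in zip(t.sample_ids, t.values)
    }
    vals = list(counts.values())
    return RichnessSummary(
        counts=counts,
        min=min(vals),
        max=max(vals),
        mean=round(sum(vals) / len(vals), 1),
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path | io.StringIO) -> SequenceCollection:
    """Read a (wrapped or single-line) FASTA file into a SequenceCollection."""
    coll = SequenceCollection()
    for rec in SeqIO.parse(path, "fasta"):
        coll.add(rec.id, str(rec.seq))
    if not coll:
        raise ValidationError("FASTA file contains no sequences")
    return coll


def write_fasta(seqs: SequenceCollection, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
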