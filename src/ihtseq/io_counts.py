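"""Readers and writers for every on-disk artifact the pipeline touches.

Count matrices and design tables are plain delimited text (delimiter inferred
from the extension: ``.csv`` → comma, anything else → tab, overridable); gene
sets use the standard GMT format; result tables are written with pandas'
default float repr, which round-trips IEEE doubles exactly.

Gene identifiers are treated as opaque strings throughout — no symbol or
Ensembl mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "DEG_TABLE_COLUMNS",
    "ENRICHMENT_TABLE_COLUMNS",
    "write_deg_table",
    "read_deg_table",
    "write_enrichment_table",
    "read_enrichment_table",
]


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class CountMatrix:
    """A genes × samples matrix of nonnegative (possibly fractional) counts.

    Fractional values are legitimate: upstream quantifiers emit estimated
    counts, and all downstream filters compare on the real line.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.counts)):
            g, s = np.argwhere(~np.isfinite(self.counts))[0]
            raise ValueError(
                f"non-numeric count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = [self.gene_ids[i] for i in keep]
        return CountMatrix(genes, list(self.sample_ids), self.counts[keep, :])


@dataclass
class SampleDesign:
    """Sample → group assignment with one designated control group.

    Every group must hold at least two samples: the per-gene tests need
    within-group variance.
    """

    assignments: dict[str, str]
    control_group: str

    def __post_init__(self) -> None:
        if self.control_group not in set(self.assignments.values()):
            raise ValueError(
                f"control group {self.control_group!r} has no samples in the design"
            )
        for grp, n in self.replicate_counts().items():
            if n < 2:
                raise ValueError(
                    f"group {grp!r} has {n} sample(s); at least 2 replicates required"
                )

    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        out: list[str] = []
        for g in self.assignments.values():
            if g not in out:
                out.append(g)
        return out

    def treatments(self) -> list[str]:
        return [g for g in self.groups() if g != self.control_group]

    def replicate_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.assignments.values():
            out[g] = out.get(g, 0) + 1
        return out

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.assignments.values()):
            raise ValueError(f"group {group!r} absent from design")
        return [s for s, g in self.assignments.items() if g == group]

    def validate_against(self, counts: CountMatrix) -> None:
        missing = [s for s in counts.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples present in counts but absent from design: {missing}")


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT-backed)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            dup = _first_duplicate(members)
            if dup is not None:
                raise ValueError(f"gene set {name!r} lists member {dup!r} twice")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> list[str]:
        return list(self.sets)


def read_counts(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a gene × sample count matrix (gene IDs in the first column)."""
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str}, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            gene = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric count at gene {gene!r}, sample {col!r} in {path}"
            )
        if coerced.isna().any():
            gene = frame.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(f"missing count at gene {gene!r}, sample {col!r} in {path}")
        frame[col] = coerced
    return CountMatrix.from_frame(frame)


def write_counts(matrix: CountMatrix, path: str | Path, delimiter: str | None = None) -> None:
    matrix.to_frame().to_csv(path, sep=_infer_delimiter(path, delimiter))


def read_design(
    path: str | Path,
    control_group: str,
    delimiter: str | None = None,
) -> SampleDesign:
    """Read a two-column (sample, group) design table.

    The control group is declared by the caller rather than in the file; row
    order is irrelevant.
    """
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"design table {path} needs two columns (sample, group)")
    samples = frame.iloc[:, 0].astype(str)
    groups = frame.iloc[:, 1].astype(str)
    dup = _first_duplicate(samples)
    if dup is not None:
        raise ValueError(f"duplicate sample ID in design: {dup!r}")
    return SampleDesign(dict(zip(samples, groups)), control_group)


def write_design(design: SampleDesign, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    frame = pd.DataFrame(
        {"sample_id": list(design.assignments), "group": list(design.assignments.values())}
    )
    frame.to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, tab-separated name, description, members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    logger.warning(
                        "%s:%d: duplicate member %r in set %r dropped", path, lineno, m, name
                    )
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# Fixed, documented column orders for the result tables.
DEG_TABLE_COLUMNS = [
    "gene_id", "log2fc", "t_stat", "p_t", "median_diff", "p_m",
    "z_combined", "p_combined", "q_fdr", "is_deg", "direction",
]
ENRICHMENT_TABLE_COLUMNS = [
    "set_id", "description", "k", "K", "n", "N",
    "p_fisher", "q_fdr", "neg_log10_q", "significant",
]


def write_deg_table(table: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    """Write a per-gene test table in input gene order, full float precision."""
    sep = _infer_delimiter(path, delimiter)
    out = table.loc[:, DEG_TABLE_COLUMNS]
    out.to_csv(path, sep=sep, index=False)


def read_deg_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    sep = _infer_delimiter(path, delimiter)
    table = pd.read_csv(
        path, sep=sep, dtype={"gene_id": str, "direction": str},
        float_precision="round_trip",
    )
    table["is_deg"] = table["is_deg"].astype(bool)
    return table.loc[:, DEG_TABLE_COLUMNS]


def write_enrichment_table(
    result: pd.DataFrame, path: str | Path, delimiter: str | None = None
) -> None:
    """Write an enrichment table sorted by ascending q then set_id."""
    sep = _infer_delimiter(path, delimiter)
    out = result.loc[:, ENRICHMENT_TABLE_COLUMNS]
    out = out.sort_values(["q_fdr", "set_id"], kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep=sep, index=False)


def read_enrichment_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    sep = _infer_delimiter(path, delimiter)
    table = pd.read_csv(
        path, sep=sep, dtype={"set_id": str, "description": str},
        float_precision="round_trip",
    )
    table["significant"] = table["significant"].astype(bool)
    return table.loc[:, ENRICHMENT_TABLE_COLUMNS]
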