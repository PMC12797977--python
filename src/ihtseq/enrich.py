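"""Gene-set over-representation and radar-chart value export.

For each gene set the overlap with a query list (typically the up-regulated
genes of one comparison) is scored with the one-sided Fisher exact /
hypergeometric upper-tail probability against a stated universe (by default,
all genes surviving the expression filter), and the p-values are
Benjamini–Hochberg adjusted across the tested sets. Significance is q < 0.05
(strict). For cross-comparison displays, −log10(q) values are clipped into a
caller-chosen [cap_min, cap_max] band and exported as a comparisons ×
pathways matrix that any plotting layer can consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .integrated_test import bh_adjust
from .io_counts import ENRICHMENT_TABLE_COLUMNS, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["RadarSpec", "fisher_enrichment", "radar_values", "write_radar", "read_radar"]


@dataclass
class RadarSpec:
    """Capped −log10(q) values, comparisons in rows, pathways in columns."""

    values: pd.DataFrame
    cap_min: float
    cap_max: float

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if v.size and (v.min() < self.cap_min - 1e-12 or v.max() > self.cap_max + 1e-12):
            raise ValueError("radar values fall outside [cap_min, cap_max]")


def fisher_enrichment(
    query: list[str] | set[str],
    universe: list[str] | set[str],
    sets: GeneSetCollection,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation of each gene set in the query.

    With universe size N, set size K (after intersecting the set with the
    universe), query size n and overlap k, p = P(Hypergeom(N, K, n) >= k).
    Sets that do not intersect the universe are skipped. q-values are BH
    across the tested sets; ``significant`` means q < fdr_cut (strict).
    """
    universe_set = set(universe)
    query_set = set(query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query genes absent from the universe: {offenders}")
    n = len(query_set)
    N = len(universe_set)

    rows = []
    for set_id in sets.names():
        members = set(sets.members(set_id)) & universe_set
        if not members:
            continue
        K = len(members)
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, sets.description(set_id), k, K, n, N, min(max(p, 0.0), 1.0)))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_TABLE_COLUMNS)

    table = pd.DataFrame(
        rows, columns=["set_id", "description", "k", "K", "n", "N", "p_fisher"]
    )
    table["p_fisher"] = table["p_fisher"].clip(lower=float(np.finfo(float).tiny))
    table["q_fdr"] = bh_adjust(table["p_fisher"].to_numpy())
    table["neg_log10_q"] = -np.log10(table["q_fdr"])
    table["significant"] = table["q_fdr"] < fdr_cut
    return table[ENRICHMENT_TABLE_COLUMNS]


def radar_values(
    tables: dict[str, pd.DataFrame],
    pathways: list[str],
    cap_max: float,
    cap_min: float = 0.0,
) -> RadarSpec:
    """Clip −log10(q) of the requested pathways into [cap_min, cap_max].

    ``tables`` maps comparison labels to enrichment tables. A pathway missing
    from a table contributes cap_min (logged) — it was not tested, so it
    carries no enrichment signal.
    """
    if cap_min >= cap_max:
        raise ValueError(f"cap_min ({cap_min}) must be below cap_max ({cap_max})")
    mat = np.full((len(tables), len(pathways)), float(cap_min))
    for i, (label, table) in enumerate(tables.items()):
        lookup = dict(zip(table["set_id"], table["neg_log10_q"]))
        for j, pw in enumerate(pathways):
            if pw in lookup:
                mat[i, j] = float(np.clip(lookup[pw], cap_min, cap_max))
            else:
                logger.warning(
                    "pathway %r absent from comparison %r; radar value set to cap_min",
                    pw, label,
                )
    values = pd.DataFrame(mat, index=list(tables), columns=pathways)
    values.index.name = "comparison"
    return RadarSpec(values=values, cap_min=float(cap_min), cap_max=float(cap_max))


def write_radar(spec: RadarSpec, path: str | Path, delimiter: str | None = None) -> None:
    sep = "," if str(path).lower().endswith(".csv") and delimiter is None else (delimiter or "\t")
    spec.values.to_csv(path, sep=sep)


def read_radar(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") and delimiter is None else (delimiter or "\t")
    return pd.read_csv(path, sep=sep, index_col=0)
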