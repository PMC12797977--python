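"""Integrated hypothesis testing for differential expression.

Each treatment-vs-control comparison runs two per-gene tests on the
log2-normalized expression matrix:

* a two-sided two-sample t-test (Student pooled-variance by default, Welch
  by flag), and
* a median-difference test whose significance comes from a permutation null:
  group labels are reassigned over all C(n1+n2, n1) splits (70 for a 4-vs-4
  design) when that enumeration is small, otherwise over seeded random
  splits, and the absolute median differences are pooled across genes into
  one empirical null. Pooling is used because per-gene 4-vs-4 enumeration
  yields only 70 distinct values — far too coarse for FDR work.

The two two-sided p-values are converted to signed z-scores (sign of the
corresponding effect), combined by Stouffer's method z = (z_t + z_m)/sqrt(2),
converted back to a two-sided combined p, and Benjamini–Hochberg adjusted
across genes. A gene is called differentially expressed when q <= fdr_cut
and |log2FC| >= lfc_cut (both inclusive); log2FC is the difference of group
means of log expression (treatment minus control).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_counts import DEG_TABLE_COLUMNS, CountMatrix, SampleDesign
from .normalize import NormalizationResult, filter_low_counts, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonConfig",
    "ttest_per_gene",
    "median_null",
    "median_diff_p",
    "stouffer_combine",
    "bh_adjust",
    "call_degs",
    "run_comparison",
    "deg_summary",
]

_TINY = float(np.finfo(float).tiny)


@dataclass
class ComparisonConfig:
    """Thresholds and permutation settings for one comparison.

    ``permutation_mode`` may be ``"exact"`` (enumerate every label split,
    refused when there are more than ``max_exact``), ``"sampled"`` (``n_perm``
    seeded random splits) or ``"auto"`` (exact when feasible).
    """

    fdr_cut: float = 0.05
    lfc_cut: float = 0.58
    permutation_mode: str = "auto"
    n_perm: int = 10_000
    seed: int = 0
    pooled_null: bool = True
    welch: bool = False
    max_exact: int = 10_000
    filter_threshold: float = 10.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fdr_cut <= 0 or self.lfc_cut <= 0:
            raise ValueError("fdr_cut and lfc_cut must be positive")
        if self.permutation_mode not in {"exact", "sampled", "auto"}:
            raise ValueError(f"unknown permutation mode {self.permutation_mode!r}")
        if self.permutation_mode == "sampled" and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 in sampled mode")


def _group_matrices(
    log_expr: pd.DataFrame, design: SampleDesign, treatment: str, control: str
) -> tuple[np.ndarray, np.ndarray]:
    cols_t = design.samples_in(treatment)
    cols_c = design.samples_in(control)
    missing = [s for s in cols_t + cols_c if s not in log_expr.columns]
    if missing:
        raise ValueError(f"samples in design but not in expression matrix: {missing}")
    return log_expr[cols_t].to_numpy(float), log_expr[cols_c].to_numpy(float)


def ttest_per_gene(
    log_expr: pd.DataFrame,
    design: SampleDesign,
    treatment: str,
    control: str,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per gene row.

    Genes with zero variance in both groups get t = 0, p = 1 (no evidence
    rather than NaN).
    """
    a, b = _group_matrices(log_expr, design, treatment, control)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    # means differing with zero pooled variance -> infinite t, p under machine tiny
    p = np.clip(np.nan_to_num(p, nan=1.0), _TINY, 1.0)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return t, p


def _label_splits(n1: int, n2: int, cfg: ComparisonConfig) -> np.ndarray:
    """Index array (n_splits, n1) of pseudo-treatment members among n1+n2 slots."""
    total = n1 + n2
    n_exact = comb(total, n1)
    mode = cfg.permutation_mode
    if mode == "auto":
        mode = "exact" if n_exact <= cfg.max_exact else "sampled"
    if mode == "exact":
        if n_exact > cfg.max_exact:
            raise ValueError(
                f"exact enumeration of {n_exact} splits exceeds max_exact={cfg.max_exact}"
            )
        return np.array(list(itertools.combinations(range(total), n1)), dtype=int)
    rng = np.random.default_rng(cfg.seed)
    picks = np.empty((cfg.n_perm, n1), dtype=int)
    for i in range(cfg.n_perm):
        picks[i] = rng.choice(total, size=n1, replace=False)
    return picks


def median_null(
    log_expr: pd.DataFrame,
    design: SampleDesign,
    treatment: str,
    control: str,
    cfg: ComparisonConfig | None = None,
) -> np.ndarray:
    """Permutation null of |median(groupA*) − median(groupB*)|.

    Returns a sorted 1-D pooled null (all splits × all genes) when
    ``cfg.pooled_null`` is true, else a (genes × splits) matrix.
    """
    cfg = cfg or ComparisonConfig()
    a, b = _group_matrices(log_expr, design, treatment, control)
    data = np.concatenate([a, b], axis=1)  # genes x (n1+n2)
    n1 = a.shape[1]
    total = data.shape[1]
    splits = _label_splits(n1, total - n1, cfg)

    mask = np.zeros((splits.shape[0], total), dtype=bool)
    mask[np.arange(splits.shape[0])[:, None], splits] = True
    null = np.empty((data.shape[0], splits.shape[0]))
    for j in range(splits.shape[0]):
        med_a = np.median(data[:, mask[j]], axis=1)
        med_b = np.median(data[:, ~mask[j]], axis=1)
        null[:, j] = np.abs(med_a - med_b)
    if cfg.pooled_null:
        return np.sort(null, axis=None)
    return null


def median_diff_p(
    log_expr: pd.DataFrame,
    design: SampleDesign,
    treatment: str,
    control: str,
    null: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed median differences and their permutation p-values.

    p = (1 + #{null >= |observed|}) / (1 + null size): add-one smoothing keeps
    p strictly positive; ties count against the observation (conservative).
    """
    if null.size == 0:
        raise ValueError("permutation null is empty")
    a, b = _group_matrices(log_expr, design, treatment, control)
    observed = np.median(a, axis=1) - np.median(b, axis=1)
    abs_obs = np.abs(observed)
    if null.ndim == 1:  # pooled, pre-sorted
        n = null.size
        count_ge = n - np.searchsorted(null, abs_obs, side="left")
        p = (1.0 + count_ge) / (1.0 + n)
    else:  # per-gene null rows
        n = null.shape[1]
        count_ge = (null >= abs_obs[:, None]).sum(axis=1)
        p = (1.0 + count_ge) / (1.0 + n)
    return observed, p


def stouffer_combine(
    p_t: np.ndarray,
    p_m: np.ndarray,
    sign_t: np.ndarray,
    sign_m: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine two two-sided p-values into one via signed z-scores.

    Each p maps to z = Phi^{-1}(1 − p/2) × sign(effect) (sign 0 → z 0), so
    discordant directions cancel instead of reinforcing; the combined
    z = (z_t + z_m)/sqrt(2) is returned with its two-sided p, clipped into
    (0, 1].
    """
    p_t = np.asarray(p_t, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    for name, p in (("p_t", p_t), ("p_m", p_m)):
        if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError(f"{name} values must lie in (0, 1]")
    z_t = stats.norm.isf(p_t / 2.0) * np.sign(sign_t)
    z_m = stats.norm.isf(p_m / 2.0) * np.sign(sign_m)
    z = (z_t + z_m) / np.sqrt(2.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _TINY, 1.0)
    return z, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, cfg: ComparisonConfig) -> pd.DataFrame:
    """Flag genes with q <= fdr_cut and |log2FC| >= lfc_cut (both inclusive)."""
    out = table.copy()
    is_deg = (out["q_fdr"] <= cfg.fdr_cut) & (out["log2fc"].abs() >= cfg.lfc_cut)
    out["is_deg"] = is_deg
    out["direction"] = np.where(
        is_deg & (out["log2fc"] > 0), "up", np.where(is_deg, "down", "none")
    )
    return out


def run_comparison(
    counts: CountMatrix,
    design: SampleDesign,
    treatment: str,
    control: str | None = None,
    cfg: ComparisonConfig | None = None,
    norm: NormalizationResult | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene table for one treatment-vs-control comparison.

    Filters and normalizes the raw counts unless a precomputed
    ``NormalizationResult`` (spanning the same samples) is supplied — sharing
    one normalization across comparisons matches a multi-group design where
    factors are computed on all samples at once. Deterministic given
    ``cfg.seed``. Returns the table plus a tally summary
    (n_genes, n_deg, n_up, n_down).
    """
    cfg = cfg or ComparisonConfig()
    control = control if control is not None else design.control_group
    design.validate_against(counts)
    for grp in (treatment, control):
        if grp not in design.groups():
            raise ValueError(f"group {grp!r} absent from design")

    if norm is None:
        counts = filter_low_counts(counts, threshold=cfg.filter_threshold)
        norm = normalize(counts, pseudocount=cfg.pseudocount)
    log_expr = pd.DataFrame(norm.log_expr, index=counts.gene_ids, columns=norm.sample_ids)

    t_stat, p_t = ttest_per_gene(log_expr, design, treatment, control, welch=cfg.welch)
    null = median_null(log_expr, design, treatment, control, cfg)
    med_diff, p_m = median_diff_p(log_expr, design, treatment, control, null)

    a, b = _group_matrices(log_expr, design, treatment, control)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    z, p_comb = stouffer_combine(p_t, p_m, sign_t=log2fc, sign_m=med_diff)
    q = bh_adjust(p_comb)

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_t": p_t,
            "median_diff": med_diff,
            "p_m": p_m,
            "z_combined": z,
            "p_combined": p_comb,
            "q_fdr": q,
        }
    )
    table = call_degs(table, cfg)[DEG_TABLE_COLUMNS]
    summary = deg_summary(table)
    logger.info(
        "%s vs %s: %d DEGs (%d up-regulated and %d down-regulated) of %d genes",
        treatment, control, summary["n_deg"], summary["n_up"], summary["n_down"],
        summary["n_genes"],
    )
    return table, summary


def deg_summary(table: pd.DataFrame) -> dict:
    """Tallies in the shape results are reported: total, up, down."""
    return {
        "n_genes": int(len(table)),
        "n_deg": int(table["is_deg"].sum()),
        "n_up": int((table["direction"] == "up").sum()),
        "n_down": int((table["direction"] == "down").sum()),
    }
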