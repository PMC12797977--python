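"""Expression filtering, TMM scale factors, and log2 CPM.

The preprocessing chain is: keep genes whose count strictly exceeds a
threshold in every sample, compute trimmed-mean-of-M-values (TMM) scale
factors between samples, then log2-transform counts-per-million computed
against the effective (factor-adjusted) library sizes.

TMM estimates, for each sample against a reference column, the trimmed,
precision-weighted mean of per-gene log2 expression ratios (M values), after
discarding the extreme tails of both the M distribution and the average
log-abundance (A) distribution. Genes with a zero in either column are
excluded from that pair — M is undefined at zero (moot after the strict
count filter). Factors are rescaled to geometric mean 1 so that they only
encode composition differences, not sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_counts import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormalizationResult", "filter_low_counts", "tmm_factors", "log_cpm", "normalize"]


@dataclass
class NormalizationResult:
    """Per-sample scale factors and the log2-normalized expression matrix."""

    sample_ids: list[str]
    tmm_factors: np.ndarray
    library_sizes: np.ndarray
    log_expr: np.ndarray  # genes x samples
    pseudocount: float

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def __post_init__(self) -> None:
        if np.any(self.tmm_factors <= 0):
            raise ValueError("TMM factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.tmm_factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")
        if not np.all(np.isfinite(self.log_expr)):
            raise ValueError("log expression matrix contains non-finite values")


def filter_low_counts(
    counts: CountMatrix, threshold: float = 10.0, require_all_samples: bool = True
) -> CountMatrix:
    """Keep genes with count strictly greater than ``threshold``.

    With ``require_all_samples`` (the default) a gene must exceed the
    threshold in every sample; otherwise one sample suffices. A count exactly
    equal to the threshold fails the test. Gene order is preserved and the
    operation is idempotent.
    """
    above = counts.counts > threshold
    keep = above.all(axis=1) if require_all_samples else above.any(axis=1)
    if not keep.any():
        raise ValueError(
            f"no gene exceeds {threshold} in "
            f"{'all' if require_all_samples else 'any'} samples; review the threshold"
        )
    return counts.subset_genes(keep)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """Unscaled TMM factor of one column against the reference column."""
    positive = (obs > 0) & (ref > 0)
    obs, ref = obs[positive], ref[positive]
    if obs.size == 0:
        raise ValueError("no gene has positive counts in both the sample and the reference")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse binomial delta-method variances of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        logger.warning(
            "only %d genes survive TMM trimming; falling back to the untrimmed "
            "weighted mean", int(keep.sum()),
        )
        keep = np.ones(n, dtype=bool)
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> np.ndarray:
    """Per-sample TMM normalization factors, geometric mean exactly 1.

    The reference column defaults to the sample whose 75th-percentile
    library-size-scaled count is closest to the mean of those percentiles.
    """
    x = counts.counts
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if reference is None:
        q75 = np.quantile(x / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if reference not in counts.sample_ids:
            raise ValueError(f"reference sample {reference!r} not in count matrix")
        ref_idx = counts.sample_ids.index(reference)

    factors = np.array(
        [
            1.0 if s == ref_idx else _tmm_pair(
                x[:, s], x[:, ref_idx], lib[s], lib[ref_idx], trim_m, trim_a
            )
            for s in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    counts: CountMatrix, effective_sizes: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2(count / effective library size × 1e6 + pseudocount), elementwise."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    effective_sizes = np.asarray(effective_sizes, dtype=float)
    return np.log2(counts.counts / effective_sizes[np.newaxis, :] * 1e6 + pseudocount)


def normalize(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
    pseudocount: float = 1.0,
) -> NormalizationResult:
    """TMM factors plus the log2 CPM matrix, bundled."""
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a, reference=reference)
    lib = counts.counts.sum(axis=0)
    expr = log_cpm(counts, lib * factors, pseudocount=pseudocount)
    return NormalizationResult(
        sample_ids=list(counts.sample_ids),
        tmm_factors=factors,
        library_sizes=lib,
        log_expr=expr,
        pseudocount=pseudocount,
    )
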