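"""Negative-binomial count simulation with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-group bulk RNA-seq experiment (default: one control plus
seven treatments, four replicates each — 32 samples), gene-wise baseline
means drawn log-normally, negative-binomial counts with gene-wise dispersion
(variance = mu + phi * mu^2), per-sample library scale factors, and for each
treatment a chosen fraction of genes shifted by a true log2 fold-change whose
magnitude never falls below a floor. Ground truth (DE flags, true log2FC,
size factors, baselines, dispersions) is emitted alongside the counts so
every pipeline stage can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_counts import CountMatrix, SampleDesign

__all__ = ["SimConfig", "SyntheticTruth", "simulate_counts", "simulate_null"]


def _default_groups() -> dict[str, int]:
    # control + 7 treatment groups x 4 replicates = 32 samples
    return {
        "control": 4, "MO": 4, "EO": 4, "KSO": 4,
        "DO": 4, "PFF": 4, "sPFF": 4, "Fib": 4,
    }


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    baseline means ~ LogNormal(baseline_meanlog, baseline_sdlog) counts;
    dispersion phi is the quadratic NB overdispersion (variance mu + phi mu^2),
    either a scalar or per-gene array; size factors, when not given, are drawn
    LogNormal(0, size_factor_sdlog). True log2FC magnitudes are
    lfc_floor + Exponential(lfc_scale) with random sign.
    """

    n_genes: int = 12_000
    groups: dict[str, int] = field(default_factory=_default_groups)
    control_group: str = "control"
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 1.3
    dispersion: float | np.ndarray = 0.1
    size_factors: np.ndarray | None = None
    size_factor_sdlog: float = 0.15
    de_fraction: float = 0.1
    lfc_floor: float = 0.58
    lfc_scale: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.control_group not in self.groups:
            raise ValueError(f"control group {self.control_group!r} not in groups")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs >= 2 replicates")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp < 0):
            raise ValueError("dispersion must be nonnegative")
        if self.lfc_floor < 0 or self.lfc_scale <= 0:
            raise ValueError("lfc_floor must be >= 0 and lfc_scale positive")

    @property
    def n_samples(self) -> int:
        return sum(self.groups.values())


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a simulated dataset.

    ``is_de`` and ``true_lfc`` are genes × treatments frames (non-DE genes
    carry true_lfc = 0); ``size_factors`` is per sample; ``baseline_mean``
    and ``dispersion`` are per gene.
    """

    is_de: pd.DataFrame
    true_lfc: pd.DataFrame
    size_factors: pd.Series
    baseline_mean: pd.Series
    dispersion: pd.Series

    def __post_init__(self) -> None:
        if ((~self.is_de.to_numpy()) & (self.true_lfc.to_numpy() != 0)).any():
            raise ValueError("non-DE genes must carry true_lfc = 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi mu^2; phi == 0 degenerates to Poisson."""
    out = np.empty_like(mean)
    poisson = phi <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        size = 1.0 / phi[~poisson]
        p = size / (size + mean[~poisson])
        out[~poisson] = rng.negative_binomial(size, p)
    return out


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SampleDesign, SyntheticTruth]:
    """Draw one dataset: counts, design, and ground truth.

    count(g, s) ~ NB(mean = baseline_g * 2^lfc(g, group(s)) * sizefactor_s,
    dispersion phi_g), independently; fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes, n_samples = cfg.n_genes, cfg.n_samples
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]

    sample_ids: list[str] = []
    sample_group: list[str] = []
    for grp, n_rep in cfg.groups.items():
        for r in range(n_rep):
            sample_ids.append(f"{grp}_{r + 1}")
            sample_group.append(grp)
    treatments = [g for g in cfg.groups if g != cfg.control_group]

    baseline = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n_genes)
    phi = np.broadcast_to(np.asarray(cfg.dispersion, dtype=float), (n_genes,)).copy()
    if cfg.size_factors is not None:
        sf = np.asarray(cfg.size_factors, dtype=float)
        if sf.shape != (n_samples,):
            raise ValueError(f"size_factors must have length {n_samples}")
        if np.any(sf <= 0):
            raise ValueError("size_factors must be positive")
    else:
        sf = rng.lognormal(0.0, cfg.size_factor_sdlog, size=n_samples)

    lfc = np.zeros((n_genes, len(treatments)))
    is_de = np.zeros((n_genes, len(treatments)), dtype=bool)
    n_de = int(round(cfg.de_fraction * n_genes))
    for j in range(len(treatments)):
        if n_de == 0:
            continue
        chosen = rng.choice(n_genes, size=n_de, replace=False)
        magnitude = cfg.lfc_floor + rng.exponential(cfg.lfc_scale, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        lfc[chosen, j] = sign * magnitude
        is_de[chosen, j] = True

    group_lfc = {cfg.control_group: np.zeros(n_genes)}
    for j, trt in enumerate(treatments):
        group_lfc[trt] = lfc[:, j]

    counts = np.empty((n_genes, n_samples))
    for s in range(n_samples):
        mean_s = baseline * (2.0 ** group_lfc[sample_group[s]]) * sf[s]
        counts[:, s] = _nb_draw(rng, mean_s, phi)

    matrix = CountMatrix(gene_ids, sample_ids, counts)
    design = SampleDesign(dict(zip(sample_ids, sample_group)), cfg.control_group)
    truth = SyntheticTruth(
        is_de=pd.DataFrame(is_de, index=gene_ids, columns=treatments),
        true_lfc=pd.DataFrame(lfc, index=gene_ids, columns=treatments),
        size_factors=pd.Series(sf, index=sample_ids, name="size_factor"),
        baseline_mean=pd.Series(baseline, index=gene_ids, name="baseline_mean"),
        dispersion=pd.Series(phi, index=gene_ids, name="dispersion"),
    )
    return matrix, design, truth


def simulate_null(cfg: SimConfig) -> tuple[CountMatrix, SampleDesign, SyntheticTruth]:
    """As :func:`simulate_counts` with the DE fraction forced to zero."""
    from dataclasses import replace

    return simulate_counts(replace(cfg, de_fraction=0.0))
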