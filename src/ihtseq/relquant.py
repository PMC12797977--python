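"""Relative expression by the comparative-Ct (delta-delta-Ct) rule.

Per sample, the target gene's Ct is referenced to a housekeeping gene
(dCt = Ct_target − Ct_reference) and then to the mean dCt of a calibrator
group; fold change = 2^(−ddCt), i.e. amplification efficiency is fixed at 2
and one cycle is one doubling. Technical replicates (repeated wells of the
same sample × gene) are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ddct_fold"]

_REQUIRED = ["sample_id", "group", "gene", "ct"]


def ddct_fold(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Per-sample fold change of ``target_gene`` relative to ``reference_gene``.

    ``ct`` is long-format with columns sample_id, group, gene, ct. Returns a
    frame with per-sample delta_ct, ddct, and fold = 2^(−ddct); calibrator
    folds have geometric mean 1 by construction.
    """
    missing_cols = [c for c in _REQUIRED if c not in ct.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks columns: {missing_cols}")

    # technical replicates collapse to one Ct per sample x gene
    mean_ct = (
        ct.groupby(["sample_id", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample_id", "group"], columns="gene", values="ct")

    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_ref = wide.index[wide[reference_gene].isna()].get_level_values("sample_id")
    if len(missing_ref):
        raise ValueError(
            f"reference gene {reference_gene!r} Ct missing for sample(s): "
            f"{sorted(missing_ref)}"
        )
    missing_tgt = wide.index[wide[target_gene].isna()].get_level_values("sample_id")
    if len(missing_tgt):
        raise ValueError(
            f"target gene {target_gene!r} Ct missing for sample(s): {sorted(missing_tgt)}"
        )

    out = wide.reset_index()[["sample_id", "group"]].copy()
    out["delta_ct"] = (wide[target_gene] - wide[reference_gene]).to_numpy()
    calibrator = out["group"] == calibrator_group
    if not calibrator.any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    out["ddct"] = out["delta_ct"] - out.loc[calibrator, "delta_ct"].mean()
    out["fold"] = 2.0 ** (-out["ddct"])
    return out
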