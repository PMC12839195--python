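"""Druggability-weighted therapeutic target prioritization.

Priority = w_hub * hub_indicator + w_mldpp * propagated score
         + w_drug * druggability, with weights summing to 1 (default
20/30/50%).  Genes without a druggability assessment are excluded from the
ranking (scoring them zero would silently demote genes never assessed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mldpp import MLDPPMetrics
from .stats import mann_whitney
from .topology import HubClassification

logger = logging.getLogger(__name__)

__all__ = ["priority_scores", "rank_targets"]


def priority_scores(
    hubs: HubClassification,
    mldpp_metrics: MLDPPMetrics | pd.DataFrame,
    gene_table: pd.DataFrame,
    weights: tuple[float, float, float] = (0.2, 0.3, 0.5),
) -> pd.DataFrame:
    """Weighted linear priority per gene with a stable descending ranking.

    Ties break by propagated score, then by symbol.  The returned frame
    records the excluded-for-missing-druggability count in
    ``df.attrs['n_excluded']``.
    """
    w_hub, w_mldpp, w_drug = weights
    if min(weights) < 0:
        raise ValueError("weights must be nonnegative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if isinstance(mldpp_metrics, MLDPPMetrics):
        final = mldpp_metrics.final
    else:
        final = mldpp_metrics["mldpp_final"]
    genes = final.index
    hub_ind = hubs.is_hub.reindex(genes, fill_value=False).astype(float)
    drug = gene_table["druggability"].reindex(genes)
    missing = drug.isna()
    if missing.any():
        logger.info(
            "%d genes excluded from prioritization (missing druggability)",
            int(missing.sum()),
        )
    df = pd.DataFrame(
        {
            "hub_indicator": hub_ind.astype(int),
            "mldpp_final": final,
            "druggability": drug,
        }
    )
    df = df.loc[~missing.to_numpy()].copy()
    df["priority"] = (
        w_hub * df["hub_indicator"]
        + w_mldpp * df["mldpp_final"]
        + w_drug * df["druggability"]
    )
    # stable sort after ordering the index, so ties break by propagated
    # score and then alphabetically by symbol
    df = df.sort_index().sort_values(
        by=["priority", "mldpp_final"], ascending=False, kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["n_excluded"] = int(missing.sum())
    df.attrs["weights"] = tuple(weights)
    return df


def rank_targets(table: pd.DataFrame, top_n: int = 10) -> dict:
    """Top-n targets plus a rank-sum comparison of top-n vs the rest.

    The comparison is an unpaired two-sample rank test on priority scores
    with its normal-approximation effect size.
    """
    if top_n >= len(table):
        raise ValueError("top_n must be below the table size")
    ordered = table.sort_values(
        by=["priority", "mldpp_final"], ascending=False, kind="mergesort"
    )
    top = ordered.head(top_n)
    rest = ordered.iloc[top_n:]
    u, p, r = mann_whitney(
        top["priority"].to_numpy(), rest["priority"].to_numpy()
    )
    return {
        "top": top,
        "rest_n": len(rest),
        "U": u,
        "p": p,
        "effect_r": r,
    }
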