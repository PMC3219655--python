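"""Pathway-membership enrichment of loop-involved genes.

Compares the fraction of a foreground gene set (e.g. disease genes caught in
feedback loops) that belongs to a pathway against the same fraction in the
background (the full disease gene list), with an exact one-sided
hypergeometric (Fisher) tail probability: the chance of drawing at least
``k`` pathway members in ``n`` draws from a background of ``N`` genes of
which ``K`` are in the pathway.  No multiple-testing correction is applied
for a single pathway; Benjamini-Hochberg is available when several pathways
are tested at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .errors import DataError

__all__ = ["EnrichmentResult", "pathway_enrichment", "enrich_pathways"]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # foreground genes in the pathway
    n: int  # foreground size
    K: int  # background genes in the pathway
    N: int  # background size
    foreground_fraction: float
    background_fraction: float
    p_value: float


def pathway_enrichment(
    foreground, background, pathway_members, pathway_id: str = "pathway"
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment of one pathway.

    ``foreground`` must be a subset of ``background``; pathway members
    outside the background are ignored.
    """
    fg, bg, pw = set(foreground), set(background), set(pathway_members)
    if not fg <= bg:
        raise DataError(
            f"foreground is not a subset of background; e.g. {sorted(fg - bg)[:3]}"
        )
    pw &= bg
    k, n, big_k, big_n = len(fg & pw), len(fg), len(pw), len(bg)
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    return EnrichmentResult(
        pathway_id=pathway_id,
        k=k,
        n=n,
        K=big_k,
        N=big_n,
        foreground_fraction=k / n if n else 0.0,
        background_fraction=big_k / big_n if big_n else 0.0,
        p_value=min(p, 1.0),
    )


def enrich_pathways(
    foreground, background, pathway_table: pd.DataFrame, bh_correct: bool = False
) -> pd.DataFrame:
    """Enrichment of every pathway in a (pathway_id, gene_id) table.

    With ``bh_correct`` a ``p_adjusted`` column (Benjamini-Hochberg) is
    appended.  Rows come back sorted by p-value.
    """
    results = [
        pathway_enrichment(foreground, background, grp["gene_id"], pathway_id=pid)
        for pid, grp in pathway_table.groupby("pathway_id", sort=True)
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
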