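"""Differential expression (mild vs severe) and over-representation analysis.

Per cell type, each gene is tested for a severe-vs-mild shift in normalized
expression with the two-sided Wilcoxon rank-sum test (exact for small
tie-free groups, tie-corrected normal approximation otherwise); fold change
is computed on the de-logged normalized means with a small pseudocount.  A
gene is called differentially expressed when BH-adjusted p < 0.05 and
|log2FC| > 0.25.

Over-representation of a query gene list against GMT gene sets uses the
hypergeometric upper tail within a user-supplied universe; the enrichment
ratio is overlap / query size (the convention behind reported values such
as 0.167 = 1/6).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_deg", "ora_enrichment", "read_gmt"]

FC_EPS = 1e-9


def wilcoxon_deg(
    adata,
    cell_type: str,
    fc_threshold: float = 0.25,
    alpha: float = 0.05,
    group_col: str = "group",
) -> pd.DataFrame:
    """Severe-vs-mild Wilcoxon rank-sum DEG table for one cell type.

    Columns: gene_id, cell_type, log2fc (severe over mild), p, p_adj, is_deg.
    log2fc = log2((mean expm1 severe + eps) / (mean expm1 mild + eps)) on the
    de-logged normalized scale.  Requires >= 3 cells per group.
    """
    mask = (adata.obs["cell_type"] == cell_type).to_numpy()
    groups = adata.obs[group_col].to_numpy()
    sev = mask & (groups == "severe")
    mil = mask & (groups == "mild")
    for name, m in (("severe", sev), ("mild", mil)):
        if m.sum() < 3:
            raise ValueError(f"group {name!r} has fewer than 3 cells of type {cell_type!r}")
    x = adata.layers["lognorm"]
    xs, xm = x[sev], x[mil]

    mean_sev = np.expm1(xs).mean(axis=0)
    mean_mil = np.expm1(xm).mean(axis=0)
    log2fc = np.log2((mean_sev + FC_EPS) / (mean_mil + FC_EPS))

    n1, n2 = xs.shape[0], xm.shape[0]
    if n1 < 8 and n2 < 8:
        # small groups: per-gene exact test when tie-free, asymptotic otherwise
        pvals = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            pvals[j] = stats.mannwhitneyu(
                xs[:, j], xm[:, j], alternative="two-sided", method="auto"
            ).pvalue
    else:
        pvals = stats.mannwhitneyu(
            xs, xm, alternative="two-sided", method="asymptotic", axis=0
        ).pvalue
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "cell_type": cell_type,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "is_deg": (p_adj < alpha) & (np.abs(log2fc) > fc_threshold),
        }
    ).reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (name -> member genes) via gseapy."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def ora_enrichment(
    query: list[str],
    genesets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Every term is intersected with the universe first; p is the upper tail
    P(overlap >= observed) of Hypergeom(universe, term, query); BH across
    terms; zero-overlap terms are dropped.  enrichment_ratio = overlap /
    query_size.
    """
    if not query:
        raise ValueError("empty query gene list")
    uni = set(universe)
    q = set(query) & uni
    if q != set(query):
        logger.warning("%d query genes outside the universe; dropped", len(set(query) - uni))
    if not q:
        raise ValueError("no query genes inside the universe")
    rows = []
    M, N = len(uni), len(q)
    for term_id, members in genesets.items():
        term = set(members) & uni
        n = len(term)
        overlap = len(term & q)
        if overlap == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
        rows.append(
            {
                "term_id": term_id,
                "overlap": overlap,
                "query_size": N,
                "term_size": n,
                "universe_size": M,
                "enrichment_ratio": overlap / N,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "overlap", "query_size", "term_size",
                "universe_size", "enrichment_ratio", "p", "fdr",
            ]
        )
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    _, out["fdr"], _, _ = multipletests(out["p"], method="fdr_bh")
    return out
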