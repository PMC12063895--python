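"""Per-cell disease-relevance scoring with matched Monte-Carlo controls.

Given a weighted disease gene set G (weights omega_g from the gene-level
association stage) and a normalized single-cell expression matrix X_cg, each
cell receives a raw disease score

    S_c = sum_{g in G} omega_g sigma_tech_g^{-1} X_cg
          / sum_{g in G} omega_g sigma_tech_g^{-1},

a technical-noise-weighted average of disease-gene expression.  B
Monte-Carlo control gene sets, matched to G on mean-expression and variance
bins, yield raw control scores; both sides are normalized per cell by the
mean/sd of that cell's control scores and the empirical cell-level p-value
pools all n_cell * B normalized control values:

    P_c = (1 + sum_{c'} sum_b 1[S_c <= S^ctrl_{c'b}]) / (1 + n_cell * B).

Cell-type associations summarize, per type, the fraction of significant
cells (BH-adjusted P_c < 0.05) with a one-sided binomial test of the
nominally significant count against the 5% expectation.

Cell and gene QC, subtype exclusion/merging, and log1p-CP10K normalization
are housed here too, operating on AnnData objects (cells x genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .geneassoc import DiseaseGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "TechNoiseModel",
    "ControlScores",
    "ScoreResult",
    "qc_cells",
    "exclude_subtypes",
    "merge_subtypes",
    "normalize_expression",
    "estimate_tech_noise",
    "raw_disease_score",
    "sample_control_scores",
    "cell_pvalues",
    "celltype_association",
    "score_cells",
]

SIGMA2_FLOOR = 1e-4


@dataclass
class TechNoiseModel:
    """Per-gene technical-noise scale sigma_tech_g (> 0), from mean-bin medians."""

    sigma: pd.Series  # indexed by gene
    n_bins: int


@dataclass
class ControlScores:
    s_ctrl: np.ndarray  # n_cell x B raw control scores
    B: int
    n_mean_bins: int
    n_var_bins: int


@dataclass
class ScoreResult:
    scores: pd.DataFrame  # index cell_id; columns raw_score, norm_score, pval, p_adj, significant


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# QC and label surgery
# ---------------------------------------------------------------------------


def qc_cells(
    adata,
    min_genes: int = 200,
    max_umi: int = 20_000,
    max_mito_frac: float = 0.15,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
):
    """Cell then gene QC, rule order fixed.

    Removes cells expressing fewer than ``min_genes`` genes, cells with total
    UMI >= ``max_umi``, cells whose mitochondrial fraction (genes named with
    ``mito_prefix``) is >= ``max_mito_frac``; then genes detected in fewer
    than ``min_cells_per_gene`` cells.  Returns (filtered AnnData, report).
    """
    x = _dense(adata.X)
    report: dict[str, int] = {}

    n_genes = (x > 0).sum(axis=1)
    keep = n_genes >= min_genes
    report["few_genes"] = int((~keep).sum())
    x, adata = x[keep], adata[keep].copy()

    total = x.sum(axis=1)
    keep = total < max_umi
    report["high_umi"] = int((~keep).sum())
    x, adata = x[keep], adata[keep].copy()

    mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    if mito.any():
        frac = x[:, mito].sum(axis=1) / np.maximum(x.sum(axis=1), 1)
    else:
        frac = np.zeros(x.shape[0])
    keep = frac < max_mito_frac
    report["high_mito"] = int((~keep).sum())
    x, adata = x[keep], adata[keep].copy()

    detected = (x > 0).sum(axis=0)
    gkeep = detected >= min_cells_per_gene
    report["rare_genes"] = int((~gkeep).sum())
    adata = adata[:, gkeep].copy()

    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("QC removed every cell or every gene")
    return adata, report


def exclude_subtypes(adata, drop: set[str]):
    """Drop entire cell types (e.g. platelets and red blood cells)."""
    observed = set(adata.obs["cell_type"].unique())
    unknown = set(drop) - observed
    if unknown:
        raise ValueError(
            f"unknown cell type(s) {sorted(unknown)}; valid: {sorted(observed)}"
        )
    keep = ~adata.obs["cell_type"].isin(drop)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("excluding these subtypes removes every cell")
    logger.info("excluded %d cells from subtypes %s", n_removed, sorted(drop))
    return adata[keep].copy(), n_removed


def merge_subtypes(adata, mapping: dict[str, str]):
    """Reclassify fine subtypes into coarser target labels.

    Every observed label must be mapped; per-target counts equal the sums of
    their source counts.  The original label is kept in ``cell_type_fine``.
    """
    observed = set(adata.obs["cell_type"].unique())
    unmapped = observed - set(mapping)
    if unmapped:
        raise ValueError(f"unmapped cell type(s): {sorted(unmapped)}")
    out = adata.copy()
    out.obs["cell_type_fine"] = out.obs["cell_type"].astype(str)
    out.obs["cell_type"] = out.obs["cell_type_fine"].map(mapping)
    return out


# ---------------------------------------------------------------------------
# normalization and technical noise
# ---------------------------------------------------------------------------


def normalize_expression(adata, target_sum: float = 1e4):
    """log1p counts-per-10k: X_cg = log(1 + target_sum * count / cell_total).

    Stores the normalized view in ``layers['lognorm']`` and returns the
    AnnData.  Zero-total cells are an error (QC should have removed them).
    """
    x = _dense(adata.X).astype(float)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total cell encountered; run qc_cells first")
    adata.layers["lognorm"] = np.log1p(target_sum * x / totals[:, None])
    return adata


def estimate_tech_noise(adata, n_bins: int = 20) -> TechNoiseModel:
    """Bin genes by mean normalized expression; sigma_g = sqrt(bin-median var).

    Genes are ranked by mean and split into ``n_bins`` equal-size bins; every
    gene in a bin shares sigma = sqrt(max(median variance in bin, 1e-4)).
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to estimate variances")
    x = adata.layers["lognorm"]
    means = x.mean(axis=0)
    variances = x.var(axis=0)
    order = np.argsort(means, kind="mergesort")
    sigma = np.empty(adata.n_vars)
    for chunk in np.array_split(order, min(n_bins, adata.n_vars)):
        med = np.median(variances[chunk])
        sigma[chunk] = np.sqrt(max(med, SIGMA2_FLOOR))
    return TechNoiseModel(sigma=pd.Series(sigma, index=adata.var_names), n_bins=n_bins)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _prepare_weights(
    adata, gs: DiseaseGeneSet, noise: TechNoiseModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve gene indices, clipped omega weights, and sigma for the set."""
    var_index = pd.Index(adata.var_names)
    idx = var_index.get_indexer(gs.genes["gene_id"])
    present = idx >= 0
    if not present.all():
        logger.warning(
            "%d disease genes absent from the expression matrix; dropped",
            int((~present).sum()),
        )
    idx = idx[present]
    if len(idx) == 0:
        raise ValueError("no disease genes present in the expression matrix")
    omega = gs.genes["weight"].to_numpy(dtype=float)[present]
    if (omega < 0).any():
        logger.info("clipping %d negative gene weights at 0", int((omega < 0).sum()))
        omega = np.clip(omega, 0.0, None)
    sigma = noise.sigma.to_numpy()[idx]
    return idx, omega, sigma


def raw_disease_score(adata, gs: DiseaseGeneSet, noise: TechNoiseModel) -> np.ndarray:
    """Weighted average of disease-gene expression, weights omega_g / sigma_g."""
    idx, omega, sigma = _prepare_weights(adata, gs, noise)
    w = omega / sigma
    denom = w.sum()
    if denom == 0:
        raise ValueError("disease-gene weights cancel; score undefined")
    return (adata.layers["lognorm"][:, idx] @ w) / denom


def _matching_bins(
    adata, n_mean_bins: int, n_var_bins: int, candidates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Assign candidate genes to (mean-bin, var-bin) cells by expression rank."""
    x = adata.layers["lognorm"][:, candidates]
    means = x.mean(axis=0)
    variances = x.var(axis=0)
    mean_bin = np.empty(len(candidates), dtype=int)
    var_bin = np.empty(len(candidates), dtype=int)
    order = np.argsort(means, kind="mergesort")
    for b, chunk in enumerate(np.array_split(order, min(n_mean_bins, len(candidates)))):
        mean_bin[chunk] = b
        vorder = chunk[np.argsort(variances[chunk], kind="mergesort")]
        for vb, vchunk in enumerate(np.array_split(vorder, min(n_var_bins, len(chunk)) or 1)):
            var_bin[vchunk] = vb
    cells: dict[tuple[int, int], np.ndarray] = {}
    for b in np.unique(mean_bin):
        for vb in np.unique(var_bin[mean_bin == b]):
            cells[(b, vb)] = candidates[(mean_bin == b) & (var_bin == vb)]
    return mean_bin, var_bin, cells


def sample_control_scores(
    adata,
    gs: DiseaseGeneSet,
    noise: TechNoiseModel,
    B: int = 1000,
    n_mean_bins: int = 20,
    n_var_bins: int = 5,
    seed: int = 0,
    candidate_genes: list[str] | None = None,
) -> ControlScores:
    """B matched control gene sets and their raw scores.

    Each disease gene is replaced, per MC draw, by a uniform draw from its
    (mean-expression bin x variance bin) cell among the candidate pool
    (default: all genes), carrying the disease gene's omega weight; the raw
    score formula is then applied with the control genes' own sigma.  An
    empty matching cell falls back to the nearest nonempty mean bin.
    """
    rng = np.random.default_rng(seed)
    var_index = pd.Index(adata.var_names)
    if candidate_genes is None:
        candidates = np.arange(adata.n_vars)
    else:
        candidates = var_index.get_indexer(candidate_genes)
        if (candidates < 0).any():
            raise ValueError("candidate pool contains unknown genes")
    idx, omega, _ = _prepare_weights(adata, gs, noise)

    mean_bin, var_bin, bin_cells = _matching_bins(adata, n_mean_bins, n_var_bins, candidates)
    cand_pos = {g: i for i, g in enumerate(candidates)}
    gene_bins = []
    for g in idx:
        if g in cand_pos:
            i = cand_pos[g]
            gene_bins.append((mean_bin[i], var_bin[i]))
        else:
            # disease gene outside the candidate pool: match on its rank among candidates
            x = adata.layers["lognorm"]
            gmean = x[:, g].mean()
            cmeans = x[:, candidates].mean(axis=0)
            i = int(np.argmin(np.abs(cmeans - gmean)))
            gene_bins.append((mean_bin[i], var_bin[i]))

    def pool_for(b: int, vb: int) -> np.ndarray:
        if (b, vb) in bin_cells and len(bin_cells[(b, vb)]):
            return bin_cells[(b, vb)]
        logger.warning("empty matching bin (%d, %d); falling back to mean bin", b, vb)
        for delta in range(0, n_mean_bins):
            for bb in (b - delta, b + delta):
                merged = np.concatenate(
                    [v for (mb, _), v in bin_cells.items() if mb == bb] or [np.array([], int)]
                )
                if len(merged):
                    return merged
        raise ValueError("no candidate genes available for matching")

    x = adata.layers["lognorm"]
    sigma_all = noise.sigma.to_numpy()
    pools = [pool_for(b, vb) for (b, vb) in gene_bins]
    # one control gene per disease gene per draw, sampled within its bin
    ctrl_idx = np.stack(
        [pool[rng.integers(len(pool), size=B)] for pool in pools]
    )  # n_set x B
    s_ctrl = np.empty((adata.n_obs, B))
    for b_draw in range(B):
        w = omega / sigma_all[ctrl_idx[:, b_draw]]
        denom = w.sum()
        if denom == 0:
            raise ValueError("control weights cancel; score undefined")
        s_ctrl[:, b_draw] = (x[:, ctrl_idx[:, b_draw]] @ w) / denom
    return ControlScores(s_ctrl=s_ctrl, B=B, n_mean_bins=n_mean_bins, n_var_bins=n_var_bins)


def cell_pvalues(
    s_raw: np.ndarray, ctrl: ControlScores, cell_ids=None, alpha: float = 0.05
) -> ScoreResult:
    """Pooled empirical p per cell on per-cell-normalized scores, plus BH.

    Each cell's raw score and its B control scores are centered and scaled
    by the mean/sd of that cell's own control scores; the empirical p pools
    all n_cell * B normalized control values.
    """
    s_raw = np.asarray(s_raw, dtype=float)
    n_cell, B = ctrl.s_ctrl.shape
    if len(s_raw) != n_cell:
        raise ValueError("raw scores and control scores cover different cells")
    mu = ctrl.s_ctrl.mean(axis=1)
    sd = np.maximum(ctrl.s_ctrl.std(axis=1), 1e-12)
    norm = (s_raw - mu) / sd
    ctrl_norm = (ctrl.s_ctrl - mu[:, None]) / sd[:, None]

    pooled = np.sort(ctrl_norm.ravel())
    # count of pooled values >= norm_c  <=>  1[S_c <= S_ctrl]
    ge = len(pooled) - np.searchsorted(pooled, norm, side="left")
    pvals = (1.0 + ge) / (1.0 + n_cell * B)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    df = pd.DataFrame(
        {
            "raw_score": s_raw,
            "norm_score": norm,
            "pval": pvals,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=cell_ids if cell_ids is not None else pd.RangeIndex(n_cell),
    )
    return ScoreResult(scores=df)


def celltype_association(
    sr: ScoreResult, cell_types: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-type fraction of significant cells plus a one-sided binomial test.

    ``assoc_p`` tests the count of cells with nominal P_c < alpha against a
    binomial(n_type, alpha) expectation (alternative: greater); BH adjusts
    across the reported types.
    """
    df = sr.scores.copy()
    df["cell_type"] = np.asarray(cell_types)
    rows = []
    for ct, grp in df.groupby("cell_type", sort=True):
        n = len(grp)
        k_nominal = int((grp["pval"] < alpha).sum())
        rows.append(
            {
                "cell_type": ct,
                "n_cells": n,
                "prop_sig": float(grp["significant"].mean()),
                "n_nominal": k_nominal,
                "assoc_p": stats.binomtest(
                    k_nominal, n, alpha, alternative="greater"
                ).pvalue,
            }
        )
    out = pd.DataFrame(rows)
    _, out["assoc_p_adj"], _, _ = multipletests(out["assoc_p"], method="fdr_bh")
    return out


def score_cells(
    adata,
    gs: DiseaseGeneSet,
    B: int = 1000,
    seed: int = 0,
    n_mean_bins: int = 20,
    n_var_bins: int = 5,
    alpha: float = 0.05,
) -> tuple[ScoreResult, pd.DataFrame]:
    """Convenience wrapper: noise model, raw + control scores, p-values, per-type table."""
    if "lognorm" not in adata.layers:
        normalize_expression(adata)
    noise = estimate_tech_noise(adata)
    s_raw = raw_disease_score(adata, gs, noise)
    ctrl = sample_control_scores(
        adata, gs, noise, B=B, n_mean_bins=n_mean_bins, n_var_bins=n_var_bins, seed=seed
    )
    sr = cell_pvalues(s_raw, ctrl, cell_ids=adata.obs_names, alpha=alpha)
    assoc = celltype_association(sr, adata.obs["cell_type"], alpha=alpha)
    return sr, assoc
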