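"""Cis-eQTL weight training and summary-based TWAS.

Per (gene, cell type): extract cis SNPs around the gene, estimate cis
heritability of pseudo-bulk expression by Haseman-Elston regression on the
cis genetic-relatedness matrix (permutation p-value), and — for genes
passing the cis-h2 gate — train four predictive eQTL weight models (top1,
ridge_blup, lasso, enet) under 5-fold cross-validation, keeping the method
with the best out-of-fold r2 and refitting it on all samples.  The trained
weights w are combined with GWAS z-scores and reference-panel LD R as

    z_TWAS = w' z / sqrt(w' R w),

a two-sided test of association between genetically predicted expression
and the trait; BH adjusts across the full (gene x cell type x trait) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .sumstats import SummaryStats
from .synth import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "CisModel",
    "TwasResult",
    "genotype_qc_eqtl",
    "extract_cis_snps",
    "estimate_cis_h2",
    "fit_weights",
    "twas_assoc",
    "adjust_results",
    "aggregate_pseudobulk",
    "inverse_normal_transform",
]

METHOD_ORDER = ["top1", "ridge_blup", "lasso", "enet"]
DENOM_FLOOR = 1e-8


@dataclass
class CisModel:
    gene_id: str
    cell_type: str
    snp_ids: list[str]
    a1: list[str]
    a2: list[str]
    weights: dict[str, np.ndarray]
    cv_r2: dict[str, float]
    best_method: str
    cis_h2: float
    cis_h2_p: float

    @property
    def best_weights(self) -> np.ndarray:
        return self.weights[self.best_method]


@dataclass
class TwasResult:
    gene_id: str
    cell_type: str
    trait_id: str
    z_twas: float
    p: float
    p_adj: float = np.nan
    nominal_sig: bool = False
    study_sig: bool = False


# ---------------------------------------------------------------------------
# genotype QC and cis extraction
# ---------------------------------------------------------------------------


def genotype_qc_eqtl(
    panel: GenotypePanel, min_info: float = 0.7, min_maf: float = 0.01
) -> tuple[GenotypePanel, dict[str, int]]:
    """Drop SNPs with imputation fill score < min_info or empirical MAF < min_maf."""
    frq = panel.genotypes.astype(float).mean(axis=0) / 2.0
    maf = np.minimum(frq, 1 - frq)
    info = panel.variants["info"].to_numpy(dtype=float)
    low_info = info < min_info
    low_maf = maf < min_maf
    keep = ~(low_info | low_maf)
    report = {"low_info": int(low_info.sum()), "low_maf": int((low_maf & ~low_info).sum())}
    return panel.subset_snps(keep), report


def extract_cis_snps(
    panel: GenotypePanel, gene: pd.Series, cis_kb: float = 500.0
) -> GenotypePanel:
    """SNPs on the gene's chromosome with pos in the closed cis window."""
    flank = int(cis_kb * 1000)
    chrom = int(str(gene["chr"]).removeprefix("chr"))
    mask = (
        (panel.variants["chr"].to_numpy() == chrom)
        & (panel.variants["pos"].to_numpy() >= int(gene["start"]) - flank)
        & (panel.variants["pos"].to_numpy() <= int(gene["end"]) + flank)
    )
    if not mask.any():
        raise ValueError(f"gene {gene.get('gene_id', '?')} has no cis SNPs in the panel")
    return panel.subset_snps(mask)


# ---------------------------------------------------------------------------
# cis heritability (Haseman-Elston + permutation p)
# ---------------------------------------------------------------------------


def estimate_cis_h2(
    sub: GenotypePanel,
    expr: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """HE regression of off-diagonal y_i y_j products on cis-GRM entries.

    GRM = X X' / m on standardized dosages; the slope of the with-intercept
    regression over pairs i < j estimates cis-h2 (clipped to [0, 1]); the
    p-value permutes the expression vector.
    """
    y = np.asarray(expr, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant expression; cis-h2 undefined")
    y = (y - y.mean()) / y.std()
    xs = sub.standardized()
    n, m = xs.shape
    A = (xs @ xs.T) / m

    a_diag = np.diag(A)
    # pair sums over i<j, computed from full-matrix quadratic forms
    sum_a = (A.sum() - a_diag.sum()) / 2.0
    sum_a2 = ((A**2).sum() - (a_diag**2).sum()) / 2.0
    n_pairs = n * (n - 1) / 2.0
    sxx = sum_a2 - sum_a**2 / n_pairs
    if sxx <= 0:
        raise ValueError("degenerate cis-GRM; cannot run HE regression")

    def he_slope(yv: np.ndarray) -> float:
        qf = yv @ A @ yv
        sum_xy = (qf - a_diag @ (yv**2)) / 2.0
        s = (yv.sum() ** 2 - (yv**2).sum()) / 2.0  # sum of y_i y_j over i<j
        return (sum_xy - sum_a * s / n_pairs) / sxx

    slope = he_slope(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if he_slope(rng.permutation(y)) >= slope:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(np.clip(slope, 0.0, 1.0)), float(p)


# ---------------------------------------------------------------------------
# weight training
# ---------------------------------------------------------------------------


def _fit_method(method: str, x: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Return a weight vector on standardized dosages for one learner."""
    if method == "top1":
        r = x.T @ (y - y.mean()) / len(y)
        j = int(np.argmax(np.abs(r)))
        w = np.zeros(x.shape[1])
        w[j] = r[j]  # marginal OLS beta on standardized x
        return w
    if method == "ridge_blup":
        model = RidgeCV(alphas=np.logspace(-2, 4, 20))
    elif method == "lasso":
        model = LassoCV(alphas=30, cv=3, random_state=seed, max_iter=5000)
    elif method == "enet":
        model = ElasticNetCV(l1_ratio=0.5, alphas=30, cv=3, random_state=seed, max_iter=5000)
    else:
        raise ValueError(f"unknown method {method!r}")
    model.fit(x, y)
    return model.coef_.astype(float)


def fit_weights(
    sub: GenotypePanel,
    expr: np.ndarray,
    gene_id: str = "gene",
    cell_type: str = "all",
    folds: int = 5,
    seed: int = 0,
    cis_h2: float | None = None,
    cis_h2_p: float | None = None,
    h2_gate_p: float = 0.05,
) -> CisModel | None:
    """Cross-validate the four eQTL learners and refit the winner on all samples.

    cv_r2 is the squared Pearson correlation between pooled out-of-fold
    predictions and expression.  Returns None (gene skipped) when the cis-h2
    permutation gate fails or no method achieves cv_r2 > 0.
    """
    y = np.asarray(expr, dtype=float)
    if cis_h2 is None or cis_h2_p is None:
        cis_h2, cis_h2_p = estimate_cis_h2(sub, y, seed=seed)
    if cis_h2_p >= h2_gate_p:
        logger.info("gene %s: cis-h2 gate failed (p=%.3f); skipped", gene_id, cis_h2_p)
        return None

    xs = sub.standardized()
    y = (y - y.mean()) / (y.std() or 1.0)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = {m: np.zeros(len(y)) for m in METHOD_ORDER}
    for train, test in kf.split(xs):
        for m in METHOD_ORDER:
            w = _fit_method(m, xs[train], y[train], seed)
            preds[m][test] = xs[test] @ w

    cv_r2: dict[str, float] = {}
    for m in METHOD_ORDER:
        if np.std(preds[m]) == 0:
            cv_r2[m] = 0.0
        else:
            cv_r2[m] = float(np.corrcoef(preds[m], y)[0, 1] ** 2)

    if max(cv_r2.values()) <= 0:
        logger.info("gene %s: no learner achieved cv_r2 > 0; rejected", gene_id)
        return None

    best = max(METHOD_ORDER, key=lambda m: (cv_r2[m], METHOD_ORDER.index(m)))
    weights = {m: _fit_method(m, xs, y, seed) for m in METHOD_ORDER}
    return CisModel(
        gene_id=gene_id,
        cell_type=cell_type,
        snp_ids=sub.variants["snp_id"].tolist(),
        a1=sub.variants["a1"].tolist(),
        a2=sub.variants["a2"].tolist(),
        weights=weights,
        cv_r2=cv_r2,
        best_method=best,
        cis_h2=float(cis_h2),
        cis_h2_p=float(cis_h2_p),
    )


# ---------------------------------------------------------------------------
# TWAS
# ---------------------------------------------------------------------------


def twas_assoc(
    model: CisModel,
    ss: SummaryStats,
    ref_panel: GenotypePanel,
    trait_id: str | None = None,
) -> TwasResult:
    """z_TWAS = w'z / sqrt(w'Rw) with reference-panel LD R.

    Model SNPs are matched to the summary statistics by id; swapped a1/a2
    flips the GWAS z sign, other allele mismatches drop the SNP (warned).
    """
    rec = ss.records.set_index("SNP")
    ref_idx = pd.Index(ref_panel.variants["snp_id"])
    w_full = model.best_weights
    keep, z, signs = [], [], []
    for i, snp in enumerate(model.snp_ids):
        if snp not in rec.index or snp not in ref_idx:
            continue
        row = rec.loc[snp]
        if (row["A1"], row["A2"]) == (model.a1[i], model.a2[i]):
            sign = 1.0
        elif (row["A1"], row["A2"]) == (model.a2[i], model.a1[i]):
            sign = -1.0
        else:
            logger.warning("SNP %s: allele mismatch beyond a swap; dropped", snp)
            continue
        keep.append(i)
        signs.append(sign)
        z.append(float(row["Z"]))
    if not keep:
        raise ValueError(f"no model SNPs for gene {model.gene_id} found in summary stats")
    keep = np.asarray(keep)
    z = np.asarray(z) * np.asarray(signs)
    w = w_full[keep]

    cols = ref_idx.get_indexer([model.snp_ids[i] for i in keep])
    if (cols < 0).any():
        raise ValueError("model SNPs missing from the reference panel")
    g = ref_panel.genotypes[:, cols].astype(float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    g /= sd
    R = (g.T @ g) / ref_panel.n_ind

    denom = float(w @ R @ w)
    if denom < DENOM_FLOOR:
        logger.warning("gene %s: near-singular TWAS denominator; floored", model.gene_id)
        denom = DENOM_FLOOR
    z_twas = float(w @ z / np.sqrt(denom))
    p = float(2.0 * stats.norm.sf(abs(z_twas)))
    return TwasResult(
        gene_id=model.gene_id,
        cell_type=model.cell_type,
        trait_id=trait_id or ss.trait_id,
        z_twas=z_twas,
        p=p,
    )


def adjust_results(results: list[TwasResult], alpha: float = 0.05) -> list[TwasResult]:
    """BH over the full (gene x cell type x trait) table; set both flags."""
    if not results:
        return results
    p = np.array([r.p for r in results])
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
        r.nominal_sig = bool(r.p < alpha)
        r.study_sig = bool(pa < alpha)
    return results


# ---------------------------------------------------------------------------
# pseudo-bulk helpers
# ---------------------------------------------------------------------------


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 3/8)."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def aggregate_pseudobulk(adata, gene: str, cell_type: str) -> pd.Series:
    """Mean normalized expression per individual for one gene and cell type.

    Requires obs columns ``individual`` and ``cell_type`` and the lognorm
    layer; the per-individual means are inverse-normal transformed, the
    convention used before cis-eQTL model fitting.
    """
    mask = (adata.obs["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    j = adata.var_names.get_loc(gene)
    vals = pd.Series(
        adata.layers["lognorm"][mask, j], index=adata.obs["individual"][mask].to_numpy()
    )
    means = vals.groupby(level=0).mean()
    return pd.Series(inverse_normal_transform(means.to_numpy()), index=means.index)
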