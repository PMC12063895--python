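"""GWAS summary-statistic QC, LD scores, and heritability gating.

The pipeline's first stage: read per-SNP marginal association records for a
microbial-abundance trait, apply the six-rule QC filter, compute
bias-corrected LD scores from a reference genotype panel, estimate SNP
heritability by LD-score regression (chi2 regressed on N*l/M), and keep only
traits whose h2 estimate clears a strict threshold (default 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "HeritabilityEstimate",
    "read_sumstats",
    "qc_filter",
    "compute_ld_scores",
    "estimate_h2_ldsc",
    "heritability_gate",
]

REQUIRED_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "N", "FRQ"]
VALID_ALLELES = frozenset("ACGT")

QC_RULES = [
    "non_autosomal",
    "low_sample_n",
    "invalid_allele",
    "bad_variance",
    "bad_se",
    "low_maf",
]


@dataclass
class SummaryStats:
    """Per-SNP marginal association records for one trait."""

    records: pd.DataFrame
    trait_id: str = "trait"

    @property
    def n_max(self) -> int:
        return int(self.records["N"].max())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HeritabilityEstimate:
    h2: float
    intercept: float
    se_h2: float
    M: int
    passed_gate: bool = False


def read_sumstats(path: str | Path, trait_id: str | None = None) -> SummaryStats:
    """Read the summary-stat TSV dialect (header: SNP CHR BP A1 A2 BETA SE N FRQ)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat file {path} lacks mandatory column(s): {missing}")
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    return SummaryStats(records=df, trait_id=trait_id or Path(path).stem)


def _normalize_chr(chrom: pd.Series) -> pd.Series:
    s = chrom.astype(str).str.removeprefix("chr")
    return pd.to_numeric(s, errors="coerce")


def qc_filter(
    ss: SummaryStats,
    min_sample_frac: float = 0.7,
    min_maf: float = 0.001,
) -> tuple[SummaryStats, dict[str, int]]:
    """Apply the six QC rules in their fixed order; report removals per rule.

    (i) autosomes 1-22 only; (ii) N >= min_sample_frac * max(N);
    (iii) alleles within {A,C,G,T}; (iv) finite beta and se^2 > 0 (the
    per-record operationalization of "variance of the summary statistic
    <= 0"); (v) se > 0; (vi) minor-allele frequency >= min_maf.
    """
    df = ss.records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats lack mandatory column(s): {missing}")
    report: dict[str, int] = {}

    chr_num = _normalize_chr(df["CHR"])
    keep = chr_num.between(1, 22)
    report["non_autosomal"] = int((~keep).sum())
    df = df[keep].assign(CHR=chr_num[keep].astype(int))

    n_max = ss.records["N"].max()
    keep = df["N"] >= min_sample_frac * n_max
    report["low_sample_n"] = int((~keep).sum())
    df = df[keep]

    ok_alleles = df["A1"].astype(str).isin(VALID_ALLELES) & df["A2"].astype(str).isin(
        VALID_ALLELES
    )
    report["invalid_allele"] = int((~ok_alleles).sum())
    df = df[ok_alleles]

    var = df["SE"].astype(float) ** 2
    keep = np.isfinite(df["BETA"].astype(float)) & np.isfinite(var) & (var > 0)
    report["bad_variance"] = int((~keep).sum())
    df = df[keep]

    keep = df["SE"].astype(float) > 0
    report["bad_se"] = int((~keep).sum())
    df = df[keep]

    frq = df["FRQ"].astype(float)
    keep = np.minimum(frq, 1 - frq) >= min_maf
    report["low_maf"] = int((~keep).sum())
    df = df[keep].reset_index(drop=True)

    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    return SummaryStats(records=df, trait_id=ss.trait_id), report


def compute_ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Bias-corrected LD scores: l_j = sum over the window of r2_adj(j, k).

    r2_adj = r2 - (1 - r2)/(n - 2) removes the finite-sample expectation of
    r2 between independent SNPs; the self term contributes exactly 1.
    Returns a table (SNP, L2).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if panel.n_ind < 3:
        raise ValueError("need at least 3 individuals for the bias correction")
    xs = panel.standardized()
    n = panel.n_ind
    chroms = panel.variants["chr"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    l2 = np.empty(panel.m_snps)
    for c in np.unique(chroms):
        cmask = np.flatnonzero(chroms == c)
        cpos = pos[cmask]
        xc = xs[:, cmask]
        for jj, j in enumerate(cmask):
            lo = np.searchsorted(cpos, cpos[jj] - window_bp, side="left")
            hi = np.searchsorted(cpos, cpos[jj] + window_bp, side="right")
            r = (xc[:, jj] @ xc[:, lo:hi]) / n
            r2 = r**2
            l2[j] = np.sum(r2 - (1.0 - r2) / (n - 2))
    return pd.DataFrame({"SNP": panel.variants["snp_id"].to_numpy(), "L2": l2})


def estimate_h2_ldsc(
    ss: SummaryStats,
    ld: pd.DataFrame,
    M: int | None = None,
    n_jackknife_blocks: int = 20,
    fixed_intercept: float | None = None,
) -> HeritabilityEstimate:
    """LD-score regression: chi2_j ~ intercept + h2 * (N_j * l_j / M).

    Weighted least squares with weights 1/max(l_j, 1); the slope is the h2
    estimate and the intercept captures confounding (1 under a clean
    polygenic architecture).  The slope SE comes from a delete-one block
    jackknife over contiguous SNP blocks.  ``fixed_intercept`` constrains
    the intercept (e.g. to 1 when no confounding is assumed), which keeps
    the slope identifiable when LD scores have little spread.
    """
    merged = ss.records.merge(ld, on="SNP", how="inner")
    if len(merged) < 50:
        raise ValueError(
            f"only {len(merged)} SNPs overlap the LD scores; need >= 50 for a stable fit"
        )
    if M is None:
        M = len(ld)
    chi2 = (merged["Z"].to_numpy(dtype=float)) ** 2
    n_vec = merged["N"].to_numpy(dtype=float)
    # truncate extreme chi2 (leverage control, the standard tool default)
    cap = max(80.0, 0.001 * n_vec.max())
    keep = chi2 <= cap
    merged, chi2, n_vec = merged[keep], chi2[keep], n_vec[keep]
    pred = n_vec * merged["L2"].to_numpy(dtype=float) / M
    w = 1.0 / np.maximum(merged["L2"].to_numpy(dtype=float), 1.0)

    def _wls(x, y, w):
        if fixed_intercept is not None:
            sxx = (w * x**2).sum()
            if sxx < 1e-12:
                return 0.0, fixed_intercept
            return (w * x * (y - fixed_intercept)).sum() / sxx, fixed_intercept
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx < 1e-12:
            return 0.0, ym
        slope = (w * (x - xm) * (y - ym)).sum() / sxx
        return slope, ym - slope * xm

    slope, intercept = _wls(pred, chi2, w)
    # one reweighting pass with variance weights 1/(intercept + slope*pred)^2,
    # the heteroskedasticity model of LD-score regression
    var_w = 1.0 / np.maximum(intercept + max(slope, 0.0) * pred, 0.1) ** 2
    w = w * var_w
    slope, intercept = _wls(pred, chi2, w)

    # delete-one-block jackknife for the slope SE
    nb = min(n_jackknife_blocks, len(merged))
    bounds = np.linspace(0, len(merged), nb + 1).astype(int)
    deleted = []
    for b in range(nb):
        mask = np.ones(len(merged), dtype=bool)
        mask[bounds[b] : bounds[b + 1]] = False
        deleted.append(_wls(pred[mask], chi2[mask], w[mask])[0])
    deleted = np.asarray(deleted)
    pseudo = nb * slope - (nb - 1) * deleted
    se = float(np.sqrt(np.var(pseudo, ddof=1) / nb))

    return HeritabilityEstimate(
        h2=float(slope), intercept=float(intercept), se_h2=se, M=int(M)
    )


def heritability_gate(est: HeritabilityEstimate, threshold: float = 0.1) -> bool:
    """Keep the trait iff h2 estimate is strictly greater than the threshold."""
    est.passed_gate = bool(est.h2 > threshold)
    return est.passed_gate
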