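"""Synthetic-data generators for every pipeline input, with known ground truth.

The real study runs on restricted cohorts (oral-microbiome GWAS summary
statistics, severe-ILI PBMC scRNA-seq, population-scale genotypes).  This
module emulates their statistical structure at desk scale:

* LD-blocked diploid genotype panels (Gaussian copula with equicorrelated
  latent liability inside fixed-size blocks, independence between blocks);
* heritable Gaussian quantitative traits with a controlled genetic variance
  share, standing in for transformed microbial-abundance phenotypes;
* marginal per-SNP GWAS summary statistics (simple-regression beta/SE/z);
* negative-binomial single-cell counts with cell-type labels, a mild/severe
  group label, and an optional upregulated disease gene set in designated
  target cell types;
* per-individual pseudo-bulk expression driven by known cis-eQTL weights.

Every generator is a pure function of (parameters, seed) and emits its
ground truth alongside the data so downstream parameter-recovery tests never
re-derive truth from outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "TraitSpec",
    "CellPopSpec",
    "simulate_genotypes",
    "simulate_trait",
    "compute_summary_stats",
    "simulate_cells",
    "simulate_pseudobulk_expression",
    "split_seed",
    "write_plink",
    "read_plink",
    "write_sumstats_tsv",
    "write_cell_matrix",
]


def split_seed(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Diploid allele-dosage panel: individuals x SNPs in {0,1,2}.

    ``variants`` columns: snp_id, chr (1..22), pos (1-based bp, strictly
    increasing within a chromosome), a1, a2, maf (the *target* minor-allele
    frequency used in simulation), info (imputation fill score, 1.0 for
    simulated data).
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    individuals: list[str]

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m_snps(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, sd 1 per SNP)."""
        g = self.genotypes.astype(float)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return (g - mu) / sd

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            genotypes=self.genotypes[:, mask],
            variants=self.variants.loc[mask].reset_index(drop=True),
            individuals=list(self.individuals),
        )


@dataclass
class TraitSpec:
    """A heritable quantitative trait: h2_true in [0,1] plus causal effects."""

    h2_true: float
    n_causal: int
    causal_effects: pd.DataFrame | None = None  # columns: snp_id, beta_true

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must lie in [0, 1], got {self.h2_true}")
        if self.h2_true > 0 and self.n_causal == 0:
            raise ValueError("h2_true > 0 requires n_causal >= 1")


@dataclass
class CellPopSpec:
    """Negative-binomial single-cell population with labelled cell types.

    Counts are NB with var = mu + mu^2/size (``dispersion`` is the NB size
    parameter; larger = closer to Poisson).  ``disease_genes`` get their mean
    multiplied by 2**effect_log2 in ``target_cell_types``;
    ``group_effect_log2`` additionally shifts disease genes in *severe* cells
    of the target types, giving the mild/severe contrast a known truth.
    """

    cell_types: list[str]
    n_cells_per_type: dict[str, int]
    genes: list[str]
    base_means: np.ndarray
    dispersion: float = 10.0
    disease_genes: list[str] = field(default_factory=list)
    effect_log2: float = 0.0
    target_cell_types: list[str] = field(default_factory=list)
    severe_frac: float = 0.5
    group_effect_log2: float = 0.0

    def __post_init__(self) -> None:
        self.base_means = np.asarray(self.base_means, dtype=float)
        if np.any(self.base_means <= 0):
            raise ValueError("all NB base means must be > 0")
        unknown = set(self.disease_genes) - set(self.genes)
        if unknown:
            raise ValueError(f"disease genes not in gene universe: {sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_ind: int,
    m_snps: int,
    block_size: int = 10,
    rho: float = 0.5,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: int = 1,
    pos_step: int = 20_000,
) -> GenotypePanel:
    """Simulate an LD-blocked dosage panel via a Gaussian copula.

    SNPs are organised into consecutive blocks of ``block_size`` with
    equicorrelation ``rho`` on the latent liability inside a block and
    independence between blocks.  Each haplotype is an independent draw, so
    the allele frequency is controlled exactly in expectation.  Positions are
    ``pos_step`` apart on chromosome ``chrom``.
    """
    if n_ind < 2 or m_snps < 1:
        raise ValueError("need n_ind >= 2 and m_snps >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5], got {maf_range}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if not 1 <= chrom <= 22:
        raise ValueError("chrom must be an autosome 1..22")
    rng = np.random.default_rng(seed)

    mafs = rng.uniform(lo, hi, size=m_snps)
    thresholds = stats.norm.ppf(mafs)  # latent < threshold => minor allele

    geno = np.empty((n_ind, m_snps), dtype=np.int8)
    sr = np.sqrt(rho)
    sc = np.sqrt(1.0 - rho)
    for start in range(0, m_snps, block_size):
        stop = min(start + block_size, m_snps)
        width = stop - start
        block = np.zeros((n_ind, width), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n_ind, 1))
            z = sr * shared + sc * rng.standard_normal((n_ind, width))
            block += (z < thresholds[start:stop]).astype(np.int8)
        geno[:, start:stop] = block

    # guarantee polymorphism: give individual 0 a heterozygote at any
    # monomorphic SNP (rare at realistic n, but the invariant is MAF > 0)
    mono = geno.min(axis=0) == geno.max(axis=0)
    if mono.any():
        geno[0, mono] = np.where(geno[0, mono] == 1, 0, 1)

    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{chrom}_{i + 1}" for i in range(m_snps)],
            "chr": chrom,
            "pos": np.arange(1, m_snps + 1, dtype=np.int64) * pos_step,
            "a1": "A",
            "a2": "G",
            "maf": mafs,
            "info": 1.0,
        }
    )
    individuals = [f"ind{i + 1}" for i in range(n_ind)]
    return GenotypePanel(genotypes=geno, variants=variants, individuals=individuals)


# ---------------------------------------------------------------------------
# trait + GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_trait(
    panel: GenotypePanel, spec: TraitSpec, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Simulate ``y = X beta + e`` with genetic variance share ``h2_true``.

    Causal effects are drawn N(0,1) on standardized dosages (or taken from
    ``spec.causal_effects``) and rescaled so the realized genetic component
    has variance h2_true against unit-variance noise scaled to 1 - h2_true.
    Returns the trait vector and a truth record including the realized
    genetic variance share.
    """
    rng = np.random.default_rng(seed)
    xs = panel.standardized()
    snp_ids = panel.variants["snp_id"].to_numpy()

    if spec.causal_effects is not None:
        idx = pd.Index(snp_ids).get_indexer(spec.causal_effects["snp_id"])
        if (idx < 0).any():
            raise ValueError("causal SNPs missing from panel")
        beta = np.zeros(panel.m_snps)
        beta[idx] = spec.causal_effects["beta_true"].to_numpy()
    else:
        beta = np.zeros(panel.m_snps)
        if spec.n_causal > 0:
            causal = rng.choice(panel.m_snps, size=spec.n_causal, replace=False)
            beta[causal] = rng.standard_normal(spec.n_causal)

    g = xs @ beta
    if spec.h2_true > 0:
        sd_g = g.std()
        if sd_g == 0:
            raise ValueError("causal effects produce a constant genetic value")
        g = g * (np.sqrt(spec.h2_true) / sd_g)
        beta = beta * (np.sqrt(spec.h2_true) / sd_g)
    else:
        g = np.zeros(panel.n_ind)
        beta = np.zeros(panel.m_snps)

    if spec.h2_true < 1.0:
        e = rng.standard_normal(panel.n_ind)
        e = e / e.std() * np.sqrt(1.0 - spec.h2_true)
    else:
        e = np.zeros(panel.n_ind)
    y = g + e

    var_y = y.var()
    realized = float(g.var() / var_y) if var_y > 0 else 0.0
    truth = {
        "h2_true": spec.h2_true,
        "realized_h2": realized,
        "causal_snps": [str(snp_ids[i]) for i in np.flatnonzero(beta != 0)],
    }
    return y, truth


def compute_summary_stats(
    panel: GenotypePanel, y: np.ndarray, trait_id: str = "trait"
) -> pd.DataFrame:
    """Per-SNP marginal simple-regression summary statistics.

    Returns a table with columns SNP CHR BP A1 A2 BETA SE Z N FRQ; z equals
    the marginal-fit t statistic.  Monomorphic SNPs get SE = NaN and are left
    for QC to remove.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_ind
    if len(y) != n:
        raise ValueError("trait length does not match panel individuals")
    g = panel.genotypes.astype(float)
    gm = g.mean(axis=0)
    yc = y - y.mean()
    sxx = ((g - gm) ** 2).sum(axis=0)
    sxy = (g - gm).T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        resid_ss = (yc**2).sum() - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
        sigma2 = resid_ss / (n - 2)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.nan))
        z = beta / se
    frq = g.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "SNP": panel.variants["snp_id"].to_numpy(),
            "CHR": panel.variants["chr"].to_numpy(),
            "BP": panel.variants["pos"].to_numpy(),
            "A1": panel.variants["a1"].to_numpy(),
            "A2": panel.variants["a2"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "Z": z,
            "N": n,
            "FRQ": frq,
        }
    )


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------


def simulate_cells(spec: CellPopSpec, seed: int = 0):
    """Draw NB counts per the population spec; returns an AnnData.

    obs carries cell_id (index), cell_type and group (mild/severe); the truth
    dict records the per-(cell_type, group) expected disease-gene fold
    change.  Cell types with zero requested cells are absent from the output.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    genes = list(spec.genes)
    n_genes = len(genes)
    if spec.base_means.shape != (n_genes,):
        raise ValueError("base_means must align with the gene list")
    dis_idx = pd.Index(genes).get_indexer(spec.disease_genes)

    blocks, ct_labels, grp_labels = [], [], []
    for ct in spec.cell_types:
        n_cells = int(spec.n_cells_per_type.get(ct, 0))
        if n_cells == 0:
            continue
        n_sev = int(round(n_cells * spec.severe_frac))
        groups = np.array(["mild"] * (n_cells - n_sev) + ["severe"] * n_sev)
        mu = np.tile(spec.base_means, (n_cells, 1))
        if ct in spec.target_cell_types and len(dis_idx):
            mu[:, dis_idx] *= 2.0**spec.effect_log2
            if spec.group_effect_log2 != 0.0:
                sev = groups == "severe"
                mu[np.ix_(sev, dis_idx)] *= 2.0**spec.group_effect_log2
        size = spec.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
        blocks.append(counts)
        ct_labels.extend([ct] * n_cells)
        grp_labels.extend(groups.tolist())

    if not blocks:
        raise ValueError("spec produced zero cells")
    x = np.vstack(blocks)
    obs = pd.DataFrame(
        {"cell_type": ct_labels, "group": grp_labels},
        index=[f"cell{i + 1}" for i in range(x.shape[0])],
    )
    adata = ad.AnnData(X=x.astype(np.int64), obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["truth"] = {
        "disease_genes": list(spec.disease_genes),
        "effect_log2": spec.effect_log2,
        "target_cell_types": list(spec.target_cell_types),
        "group_effect_log2": spec.group_effect_log2,
    }
    return adata


# ---------------------------------------------------------------------------
# pseudo-bulk expression with known cis effects
# ---------------------------------------------------------------------------


def simulate_pseudobulk_expression(
    panel: GenotypePanel,
    causal_weights: pd.DataFrame,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Per-individual expression: sum of w_true * standardized dosage + noise.

    ``causal_weights`` columns: snp_id, w_true.  Returns the expression
    vector and a truth record with the realized cis variance share.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index(panel.variants["snp_id"]).get_indexer(causal_weights["snp_id"])
    if (idx < 0).any():
        raise ValueError("causal cis SNPs missing from panel")
    xs = panel.standardized()
    g = xs[:, idx] @ causal_weights["w_true"].to_numpy(dtype=float)
    e = rng.standard_normal(panel.n_ind) * noise_sd
    expr = g + e
    var = expr.var()
    truth = {"realized_cis_share": float(g.var() / var) if var > 0 else 0.0}
    return expr, truth


# ---------------------------------------------------------------------------
# writers: PLINK bed/bim/fam, summary-stat TSV, MTX trio, truth JSON
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# PLINK 2-bit codes (counting a1 alleles): 00=2, 10=1, 11=0, 01=missing
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 2, 0b10: 1, 0b11: 0}


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK 1 bed/bim/fam (SNP-major, no missing calls)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = panel.n_ind
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        nbytes = (n + 3) // 4
        for j in range(panel.m_snps):
            col = panel.genotypes[:, j]
            buf = bytearray(nbytes)
            for i in range(n):
                buf[i // 4] |= _CODE_FOR_DOSAGE[int(col[i])] << (2 * (i % 4))
            fh.write(bytes(buf))
    bim = panel.variants.assign(cm=0)[["chr", "snp_id", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.individuals,
            "iid": panel.individuals,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 bed/bim/fam trio back into a GenotypePanel."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chr", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep="\t", header=None)
    individuals = fam[1].astype(str).tolist()
    n, m = len(individuals), len(bim)
    nbytes = (n + 3) // 4
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    geno = np.empty((n, m), dtype=np.int8)
    body = raw[3:]
    for j in range(m):
        chunk = body[j * nbytes : (j + 1) * nbytes]
        for i in range(n):
            code = (chunk[i // 4] >> (2 * (i % 4))) & 0b11
            if code == 0b01:
                raise ValueError("missing genotype calls are not supported")
            geno[i, j] = _DOSAGE_FOR_CODE[code]
    variants = bim[["snp_id", "chr", "pos", "a1", "a2"]].copy()
    g = geno.astype(float)
    frq = g.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(frq, 1 - frq)
    variants["info"] = 1.0
    return GenotypePanel(genotypes=geno, variants=variants, individuals=individuals)


def write_sumstats_tsv(ss: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "N", "FRQ"]
    ss[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cell_matrix(adata, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + genes.tsv + cells.tsv."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", csr_matrix(adata.X))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    cells = adata.obs.reset_index(names="cell_id")
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if "truth" in adata.uns:
        (outdir / "truth.json").write_text(json.dumps(adata.uns["truth"], indent=1))


def read_cell_matrix(indir: str | Path):
    """Read an MTX + genes.tsv + cells.tsv trio into an AnnData."""
    import anndata as ad
    from scipy.io import mmread

    indir = Path(indir)
    x = np.asarray(mmread(indir / "matrix.mtx").todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    return ad.AnnData(X=x, obs=cells, var=pd.DataFrame(index=genes))
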