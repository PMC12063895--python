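"""End-to-end orchestration: config, staged run, report tables.

Stage order: summary-stat QC + heritability gate -> gene-level association
-> per-cell disease-relevance scoring -> cis-eQTL/TWAS -> differential
expression -> over-representation analysis.  A run is a pure function of
(config, master seed): per-stage seeds are split from the master seed and
every output table is written deterministically (sorted, fixed float
format, no timestamps in the log).

`make_demo_dataset` builds a complete synthetic study — an LD-blocked
genotype panel, one signal-bearing and one null microbial-abundance trait,
a gene table, labelled single-cell counts with an upregulated disease gene
set in one target cell type, pseudo-bulk expression with known cis effects,
and a small GMT — so the whole chain can be exercised with known truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import degenrich, eqtl_twas, geneassoc, scdrs_core, sumstats as sumstats_mod, synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "tabulate_phyla", "phylum_shares", "make_demo_dataset"]

FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    """All paths, thresholds and toggles for one pipeline run."""

    panel_prefix: str
    traits_file: str  # TSV: trait_id, path, site, taxonomy
    gene_table: str
    cells_dir: str
    expression_file: str | None = None  # long TSV: gene_id, cell_type, individual, value
    gmt_file: str | None = None
    outdir: str = "run_out"
    seed: int = 0
    h2_gate: float = 0.1
    top_k: int = 1000
    B: int = 1000
    fc_threshold: float = 0.25
    alpha: float = 0.05
    cis_kb: float = 500.0
    window_kb: float = 10.0
    ld_window_bp: int = 1_000_000
    min_maf_sumstats: float = 0.001
    min_sample_frac: float = 0.7
    ldsc_fixed_intercept: float | None = None
    max_twas_genes: int = 10
    min_genes_per_cell: int = 200
    max_umi: int = 20_000
    max_mito_frac: float = 0.15
    min_cells_per_gene: int = 3
    exclude_cell_types: list[str] = field(default_factory=list)
    merge_map: dict[str, str] = field(default_factory=dict)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "sumstats": True, "geneassoc": True, "scdrs": True,
            "twas": True, "deg": True, "enrich": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute enabled stages in order; returns the output directory.

    Every stage logs its input/output row counts; identical (config, seed)
    produces byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("florascore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = synth.split_seed(config.seed, 8)
    try:
        return _run_stages(config, outdir, seeds)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, outdir: Path, seeds: list[int]) -> Path:
    echoed = {k: v for k, v in config.__dict__.items() if k != "outdir"}
    logger.info("run config: %s", json.dumps(echoed, default=str, sort_keys=True))
    panel = synth.read_plink(config.panel_prefix)
    traits = pd.read_csv(config.traits_file, sep="\t")
    base = Path(config.traits_file).parent

    gated: dict[str, sumstats_mod.SummaryStats] = {}
    if config.stages.get("sumstats", True):
        ld = sumstats_mod.compute_ld_scores(panel, window_bp=config.ld_window_bp)
        qc_rows, h2_rows = [], []
        for _, trow in traits.iterrows():
            ss = sumstats_mod.read_sumstats(base / trow["path"], trait_id=trow["trait_id"])
            n_in = len(ss)
            ss_qc, report = sumstats_mod.qc_filter(
                ss, min_sample_frac=config.min_sample_frac, min_maf=config.min_maf_sumstats
            )
            logger.info("sumstats %s: %d -> %d records", trow["trait_id"], n_in, len(ss_qc))
            qc_rows.append({"trait_id": trow["trait_id"], "n_in": n_in, "n_out": len(ss_qc), **report})
            est = sumstats_mod.estimate_h2_ldsc(
                ss_qc, ld, M=len(ld), fixed_intercept=config.ldsc_fixed_intercept
            )
            passed = sumstats_mod.heritability_gate(est, threshold=config.h2_gate)
            h2_rows.append(
                {
                    "trait_id": trow["trait_id"], "h2": est.h2, "intercept": est.intercept,
                    "se_h2": est.se_h2, "M": est.M, "passed_gate": passed,
                }
            )
            if passed:
                gated[str(trow["trait_id"])] = ss_qc
        _write(pd.DataFrame(qc_rows), outdir / "qc_report.tsv")
        _write(pd.DataFrame(h2_rows), outdir / "h2.tsv")
        logger.info("heritability gate: %d of %d traits retained", len(gated), len(traits))

    gene_sets: dict[str, geneassoc.DiseaseGeneSet] = {}
    gene_tab = geneassoc.read_gene_table(config.gene_table)
    if config.stages.get("geneassoc", True) and gated:
        rows = []
        for trait_id, ss in gated.items():
            results = geneassoc.gene_results(ss, panel, gene_tab, window_kb=config.window_kb)
            if not results:
                continue
            gene_sets[trait_id] = geneassoc.build_disease_gene_set(results, top_k=config.top_k)
            for r in results:
                rows.append(
                    {
                        "trait_id": trait_id, "gene_id": r.gene_id, "chr": r.chrom,
                        "n_snps": r.n_snps, "n_sample": r.n_sample, "stat": r.stat,
                        "p": r.p, "z_gene": r.z_gene,
                    }
                )
        _write(pd.DataFrame(rows), outdir / "gene_results.tsv")
        gs_rows = [
            {"trait_id": t, "gene_id": g, "weight": w}
            for t, gs in gene_sets.items()
            for g, w in zip(gs.genes["gene_id"], gs.genes["weight"])
        ]
        _write(pd.DataFrame(gs_rows), outdir / "geneset.tsv")

    assoc_all = pd.DataFrame()
    adata = None
    if config.stages.get("scdrs", True) and gene_sets:
        adata = synth.read_cell_matrix(config.cells_dir)
        adata, cell_report = scdrs_core.qc_cells(
            adata,
            min_genes=config.min_genes_per_cell,
            max_umi=config.max_umi,
            max_mito_frac=config.max_mito_frac,
            min_cells_per_gene=config.min_cells_per_gene,
        )
        logger.info("cell QC removals: %s", cell_report)
        if config.exclude_cell_types:
            adata, _ = scdrs_core.exclude_subtypes(adata, set(config.exclude_cell_types))
        if config.merge_map:
            adata = scdrs_core.merge_subtypes(adata, config.merge_map)
        scdrs_core.normalize_expression(adata)
        score_rows, assoc_rows = [], []
        for i, (trait_id, gs) in enumerate(sorted(gene_sets.items())):
            sr, assoc = scdrs_core.score_cells(
                adata, gs, B=config.B, seed=synth.split_seed(seeds[2], len(gene_sets) + 1)[i],
                alpha=config.alpha,
            )
            sdf = sr.scores.reset_index(names="cell_id")
            sdf.insert(0, "trait_id", trait_id)
            score_rows.append(sdf)
            assoc.insert(0, "trait_id", trait_id)
            assoc_rows.append(assoc)
        _write(pd.concat(score_rows, ignore_index=True), outdir / "scdrs_scores.tsv")
        assoc_all = pd.concat(assoc_rows, ignore_index=True)
        # BH across the pooled (cell type x trait) family
        _, assoc_all["assoc_p_adj"], _, _ = multipletests(assoc_all["assoc_p"], method="fdr_bh")
        _write(assoc_all, outdir / "celltype_assoc.tsv")

    twas_results: list[eqtl_twas.TwasResult] = []
    if (
        config.stages.get("twas", True)
        and gene_sets
        and config.expression_file
        and len(assoc_all)
    ):
        expr = pd.read_csv(config.expression_file, sep="\t")
        panel_qc, _ = eqtl_twas.genotype_qc_eqtl(panel)
        gmeta = gene_tab.set_index("gene_id")
        sig_types = assoc_all.loc[assoc_all["assoc_p_adj"] < config.alpha, ["trait_id", "cell_type"]]
        model_cache: dict[tuple[str, str], eqtl_twas.CisModel | None] = {}
        for _, row in sig_types.iterrows():
            trait_id, cell_type = str(row["trait_id"]), str(row["cell_type"])
            top_genes = gene_sets[trait_id].genes["gene_id"].head(config.max_twas_genes)
            for gene_id in top_genes:
                if gene_id not in gmeta.index:
                    continue
                sub_expr = expr[(expr["gene_id"] == gene_id) & (expr["cell_type"] == cell_type)]
                if sub_expr.empty:
                    continue
                key = (gene_id, cell_type)
                if key not in model_cache:
                    try:
                        cis = eqtl_twas.extract_cis_snps(
                            panel_qc, gmeta.loc[gene_id].rename(gene_id), cis_kb=config.cis_kb
                        )
                    except ValueError:
                        model_cache[key] = None
                        continue
                    model_cache[key] = eqtl_twas.fit_weights(
                        cis,
                        sub_expr.set_index("individual")
                        .loc[panel_qc.individuals, "value"]
                        .to_numpy(),
                        gene_id=gene_id,
                        cell_type=cell_type,
                        seed=seeds[3],
                    )
                model = model_cache[key]
                if model is None:
                    continue
                try:
                    twas_results.append(
                        eqtl_twas.twas_assoc(model, gated[trait_id], panel_qc, trait_id=trait_id)
                    )
                except ValueError as exc:
                    logger.warning("TWAS skipped for %s/%s: %s", gene_id, cell_type, exc)
        eqtl_twas.adjust_results(twas_results, alpha=config.alpha)
        _write(
            pd.DataFrame([r.__dict__ for r in twas_results]).sort_values(
                ["trait_id", "cell_type", "gene_id"]
            )
            if twas_results
            else pd.DataFrame(
                columns=["gene_id", "cell_type", "trait_id", "z_twas", "p", "p_adj",
                         "nominal_sig", "study_sig"]
            ),
            outdir / "twas.tsv",
        )

    deg_all = pd.DataFrame()
    if config.stages.get("deg", True) and adata is not None:
        frames = []
        for ct in sorted(adata.obs["cell_type"].unique()):
            try:
                frames.append(
                    degenrich.wilcoxon_deg(
                        adata, ct, fc_threshold=config.fc_threshold, alpha=config.alpha
                    )
                )
            except ValueError as exc:
                logger.info("DEG skipped for %s: %s", ct, exc)
        if frames:
            deg_all = pd.concat(frames, ignore_index=True)
            _write(deg_all, outdir / "deg.tsv")

    if (
        config.stages.get("enrich", True)
        and config.gmt_file
        and len(deg_all)
        and adata is not None
    ):
        genesets = degenrich.read_gmt(config.gmt_file)
        frames = []
        for ct, grp in deg_all.groupby("cell_type", sort=True):
            query = grp.loc[grp["is_deg"], "gene_id"].tolist()
            if not query:
                continue
            res = degenrich.ora_enrichment(query, genesets, universe=list(adata.var_names))
            if len(res):
                res.insert(0, "cell_type", ct)
                frames.append(res)
        if frames:
            _write(pd.concat(frames, ignore_index=True), outdir / "enrich.tsv")

    if len(assoc_all):
        sig_traits = set(
            assoc_all.loc[assoc_all["assoc_p_adj"] < config.alpha, "trait_id"].astype(str)
        )
        meta = traits.assign(
            significant=traits["trait_id"].astype(str).isin(sig_traits)
        )
        tab = tabulate_phyla(meta)
        _write(tab, outdir / "phylum_table.tsv")

    logger.info("pipeline complete")
    return outdir


# ---------------------------------------------------------------------------
# phylum tabulation (report arithmetic)
# ---------------------------------------------------------------------------


def _parse_phylum(taxonomy: str) -> str | None:
    try:
        for fld in str(taxonomy).split(";"):
            fld = fld.strip()
            if fld.startswith("p__") and len(fld) > 3:
                return fld[3:]
    except Exception:  # noqa: BLE001 - any malformed string counts as unparseable
        pass
    return None


def tabulate_phyla(
    traits: pd.DataFrame, sig_col: str = "significant", top_n: int = 5
) -> pd.DataFrame:
    """Per-phylum counts split by sampling site, with a significance tally.

    ``traits`` needs columns taxonomy (k__;p__;... strings), site
    (saliva/tongue) and a boolean ``sig_col``.  The ``top_n`` phyla by total
    count keep their names; the rest (and unparseable taxonomies, warned)
    are pooled as "Others".  Percentages are never stored — derive them with
    :func:`phylum_shares`.
    """
    phyla = traits["taxonomy"].map(_parse_phylum)
    bad = phyla.isna()
    if bad.any():
        logger.warning("%d unparseable taxonomy strings counted under Others", int(bad.sum()))
    phyla = phyla.fillna("Others")
    counts = phyla.value_counts()
    keep = set(counts.drop("Others", errors="ignore").head(top_n).index)
    label = phyla.where(phyla.isin(keep), "Others")
    df = traits.assign(_phylum=label)
    rows = []
    for ph, grp in df.groupby("_phylum"):
        rows.append(
            {
                "phylum": ph,
                "total": len(grp),
                "saliva": int((grp["site"] == "saliva").sum()),
                "tongue": int((grp["site"] == "tongue").sum()),
                "n_significant": int(grp[sig_col].sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values("total", ascending=False, kind="mergesort")
    others = out["phylum"] == "Others"
    return pd.concat([out[~others], out[others]]).reset_index(drop=True)


def phylum_shares(tab: pd.DataFrame) -> pd.DataFrame:
    """Row-wise percentage columns recomputed from the stored counts.

    saliva_pct and tongue_pct are shares of the phylum's total; total_pct is
    the phylum's share of the grand total; sig_pct is n_significant over the
    phylum total.  All rounded to 2 decimals.
    """
    out = tab.copy()
    grand = out["total"].sum()
    out["total_pct"] = (100.0 * out["total"] / grand).round(2)
    out["saliva_pct"] = (100.0 * out["saliva"] / out["total"]).round(2)
    out["tongue_pct"] = (100.0 * out["tongue"] / out["total"]).round(2)
    out["sig_pct"] = (100.0 * out["n_significant"] / out["total"]).round(2)
    return out


# ---------------------------------------------------------------------------
# packaged synthetic study
# ---------------------------------------------------------------------------

DEMO_TARGET_CELL_TYPE = "CD16_Mono"
DEMO_CELL_TYPES = ["CD14_Mono", "CD16_Mono", "CD4_T", "NK", "B"]


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_ind: int = 1500,
    m_snps: int = 600,
    snps_per_gene: int = 6,
    n_cells_per_type: int = 240,
    n_disease_genes: int = 3,
    h2_signal: float = 0.5,
    disease_boost: float = 6.0,
    effect_log2: float = 1.0,
    group_effect_log2: float = 0.5,
    cis_share: float = 0.4,
    B: int = 100,
    top_k: int = 30,
    n_bg_genes: int = 900,
) -> RunConfig:
    """Write a two-trait synthetic study with known truth; returns its RunConfig.

    Trait ``tongue_pheno.1`` carries h2 = ``h2_signal`` spread over all SNPs
    (a polygenic background, the architecture LD-score regression models)
    with per-SNP effects amplified ``disease_boost``-fold inside
    ``n_disease_genes`` disease genes, whose SNPs also drive pseudo-bulk
    expression (cis share ``cis_share``) and whose transcripts are
    upregulated 2**effect_log2-fold in the target cell type;
    ``saliva_pheno.1`` is a pure-noise null trait.  LD blocks coincide with
    genes (``snps_per_gene`` SNPs at latent correlation 0.8).  Truth is
    written to truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = synth.split_seed(seed, 10)
    pos_step = 5000

    panel = synth.simulate_genotypes(
        n_ind, m_snps, block_size=snps_per_gene, rho=0.8, maf_range=(0.1, 0.5),
        seed=seeds[0], pos_step=pos_step,
    )
    synth.write_plink(panel, outdir / "panel")

    n_genes = m_snps // snps_per_gene
    gene_tab = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:04d}" for i in range(n_genes)],
            "chr": 1,
            "start": [pos_step * (snps_per_gene * i + 1) for i in range(n_genes)],
            "end": [pos_step * (snps_per_gene * (i + 1)) for i in range(n_genes)],
        }
    )
    gene_tab.to_csv(outdir / "genes_table.tsv", sep="\t", index=False)

    rng = np.random.default_rng(seeds[1])
    disease_gene_idx = np.sort(
        rng.choice(n_genes, size=n_disease_genes, replace=False)
    )
    disease_genes = [f"G{i + 1:04d}" for i in disease_gene_idx]
    causal_snps = [
        panel.variants["snp_id"].iloc[i * snps_per_gene + j]
        for i in disease_gene_idx
        for j in range(snps_per_gene)
    ]

    # signal trait: polygenic background, boosted inside the disease genes
    beta = rng.standard_normal(m_snps)
    boost_mask = panel.variants["snp_id"].isin(causal_snps).to_numpy()
    beta[boost_mask] *= disease_boost
    spec_sig = synth.TraitSpec(
        h2_true=h2_signal,
        n_causal=m_snps,
        causal_effects=pd.DataFrame(
            {"snp_id": panel.variants["snp_id"], "beta_true": beta}
        ),
    )
    y_sig, truth_sig = synth.simulate_trait(panel, spec_sig, seed=seeds[2])
    ss_sig = synth.compute_summary_stats(panel, y_sig, trait_id="tongue_pheno.1")
    synth.write_sumstats_tsv(ss_sig, outdir / "tongue_pheno.1.tsv")

    y_null, truth_null = synth.simulate_trait(
        panel, synth.TraitSpec(h2_true=0.0, n_causal=0), seed=seeds[3]
    )
    ss_null = synth.compute_summary_stats(panel, y_null, trait_id="saliva_pheno.1")
    synth.write_sumstats_tsv(ss_null, outdir / "saliva_pheno.1.tsv")

    traits = pd.DataFrame(
        {
            "trait_id": ["tongue_pheno.1", "saliva_pheno.1"],
            "path": ["tongue_pheno.1.tsv", "saliva_pheno.1.tsv"],
            "site": ["tongue", "saliva"],
            "taxonomy": [
                "k__Bacteria; p__Firmicutes; c__Clostridia; o__Lachnospirales; "
                "f__Lachnospiraceae; g__Oribacterium; s__unclassified_demo_1",
                "k__Bacteria; p__Bacteroidota; c__Bacteroidia; o__Bacteroidales; "
                "f__Prevotellaceae; g__Prevotella; s__unclassified_demo_2",
            ],
        }
    )
    traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)

    # single-cell counts: the panel genes plus a background universe so the
    # control-matching bins are well populated (as in real data)
    genes = gene_tab["gene_id"].tolist() + [f"BG{i + 1:04d}" for i in range(n_bg_genes)]
    base_means = np.exp(rng.normal(np.log(2.0), 1.0, size=len(genes)))
    cellspec = synth.CellPopSpec(
        cell_types=DEMO_CELL_TYPES,
        n_cells_per_type={ct: n_cells_per_type for ct in DEMO_CELL_TYPES},
        genes=list(genes),
        base_means=base_means,
        disease_genes=disease_genes,
        effect_log2=effect_log2,
        target_cell_types=[DEMO_TARGET_CELL_TYPE],
        group_effect_log2=group_effect_log2,
    )
    adata = synth.simulate_cells(cellspec, seed=seeds[4])
    synth.write_cell_matrix(adata, outdir / "cells")

    # pseudo-bulk expression: cis-driven for disease genes, noise otherwise
    expr_rows = []
    gmeta = gene_tab.set_index("gene_id")
    for k, gene_id in enumerate(disease_genes):
        cis = eqtl_twas.extract_cis_snps(panel, gmeta.loc[gene_id].rename(gene_id), cis_kb=1)
        w_raw = rng.standard_normal(cis.m_snps)
        g_raw = cis.standardized() @ w_raw
        w_true = w_raw * np.sqrt(cis_share) / g_raw.std()
        expr, _ = synth.simulate_pseudobulk_expression(
            panel,
            pd.DataFrame({"snp_id": cis.variants["snp_id"], "w_true": w_true}),
            noise_sd=np.sqrt(1.0 - cis_share),
            seed=seeds[5] + k,
        )
        expr_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "cell_type": DEMO_TARGET_CELL_TYPE,
                    "individual": panel.individuals,
                    "value": expr,
                }
            )
        )
    expr_null_rng = np.random.default_rng(seeds[6])
    for gene_id in gene_tab["gene_id"].tolist()[:10]:
        if gene_id in disease_genes:
            continue
        expr_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "cell_type": DEMO_TARGET_CELL_TYPE,
                    "individual": panel.individuals,
                    "value": expr_null_rng.standard_normal(n_ind),
                }
            )
        )
    pd.concat(expr_rows, ignore_index=True).to_csv(
        outdir / "expression.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # small GMT: one term enriched in the disease genes, two random terms
    with open(outdir / "sets.gmt", "w") as fh:
        fh.write(
            "disease_module\tsynthetic\t" + "\t".join(disease_genes + genes[:3]) + "\n"
        )
        fh.write("random_module_a\tsynthetic\t" + "\t".join(genes[10:25]) + "\n")
        fh.write("random_module_b\tsynthetic\t" + "\t".join(genes[30:50]) + "\n")

    truth = {
        "signal_trait": "tongue_pheno.1",
        "null_trait": "saliva_pheno.1",
        "disease_genes": disease_genes,
        "target_cell_type": DEMO_TARGET_CELL_TYPE,
        "h2_signal": h2_signal,
        "realized_h2_signal": truth_sig["realized_h2"],
        "realized_h2_null": truth_null["realized_h2"],
        "cis_share": cis_share,
        "effect_log2": effect_log2,
        "group_effect_log2": group_effect_log2,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))

    config = RunConfig(
        panel_prefix=str(outdir / "panel"),
        traits_file=str(outdir / "traits.tsv"),
        gene_table=str(outdir / "genes_table.tsv"),
        cells_dir=str(outdir / "cells"),
        expression_file=str(outdir / "expression.tsv"),
        gmt_file=str(outdir / "sets.gmt"),
        outdir=str(outdir / "results"),
        seed=seed,
        B=B,
        top_k=top_k,
        cis_kb=1.0,
        window_kb=0.0,
        max_twas_genes=5,
        ldsc_fixed_intercept=1.0,
    )
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=True)
    return config
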