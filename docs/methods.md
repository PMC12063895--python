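# Methods

This note documents the statistical models implemented in `florascore`,
the choices made where the procedure was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Summary-statistic QC and the heritability gate

Each microbial-abundance trait arrives as per-SNP marginal records
(SNP, CHR, BP, A1, A2, BETA, SE, N, FRQ). Six filters run in fixed order:
(i) autosomes 1–22; (ii) N ≥ 0.7·max(N) — the "detected in less than 70% of
samples" rule operationalized against the trait's own maximum reported N,
since no denominator is carried per record; (iii) alleles within {A,C,G,T};
(iv) finite beta and SE² > 0 — the only per-record variance available is
SE², so "variance of the summary statistic ≤ 0" is read as that; (v) SE > 0;
(vi) minor-allele frequency ≥ 0.001. The filter is idempotent and the
per-rule removal counts reconcile with input − output by construction.

LD scores are l_j = Σ_k r²_adj(j,k) over a window (default 1 Mb; the
reference panel's LD decay, not a property of the data, so a configuration
choice), with the small-sample correction r²_adj = r² − (1−r²)/(n−2) that
makes independent pairs contribute zero in expectation; the self term
contributes exactly 1.

Heritability is the slope of the weighted regression of χ²_j = z²_j on
N_j·l_j/M. Weights start at 1/max(l_j,1) (over-counting correction) and are
multiplied by one iteratively-reweighted pass of 1/(intercept + slope·x)²,
the variance model of LD-score regression; χ² values above max(80, 0.001·N)
are excluded as leverage points. Both refinements are the reference tool's
defaults and were necessary: without them the slope's sampling sd at desk
scale (M = 2000) is ~0.5 and no gate can separate h² = 0 from h² = 0.3.
The slope SE is a 20-block delete-one jackknife. The intercept is free by
default; `fixed_intercept=1` constrains it for confounding-free simulated
data, which keeps the slope identifiable when LD scores have little spread
(equal-size equal-rho blocks make l_j nearly constant). The gate is strict:
a trait proceeds iff ĥ² > 0.1.

## Gene-level association

SNPs map to a gene when their position lies in the closed interval
[start − w, end + w] (default flank w = 10 kb; no window is canonical, this
is the annotation tool's common default). The gene statistic is the
snp-wise mean, T = mean(z²). Under the null z ~ MVN(0, R) with R the local
LD correlation estimated from the reference panel, so T is distributed as
(1/k)Σ λ_i χ²₁ with λ_i = eigenvalues of R (clipped at 0 if the empirical
matrix is slightly non-PSD). The p-value uses the Liu-type four-moment
noncentral-χ² match rather than a two-moment gamma: the two-moment version
missed the 10% Monte-Carlo-agreement tolerance at rho = 0.7 (10.6% relative
error in the p ≈ 0.3 region), while the four-moment match stays within ~4%
across p ∈ [0.001, 0.5] and is exact at R = I, where the null is exactly
(1/k)χ²_k. A ≥10⁶-draw Monte-Carlo sampler of the eigenvalue mixture is the
independent oracle in tests, never the implementation.

Gene-level z is the one-sided probit z_gene = Φ⁻¹(1−p), with p floored at
1e-300 to keep z finite. The disease gene set is the top-k genes (default
1000) by z_gene, ties broken lexicographically by gene id so the set is
deterministic; weights ω_g = z_gene.

## Per-cell disease-relevance scoring

Scoring operates on log1p counts-per-10k (X_cg = log(1 + 10⁴·count/total)),
the scoring tool's documented input convention; the clustering-oriented
normalization used upstream of annotation is out of scope because synthetic
cells arrive labelled. Cell QC order is fixed: cells expressing < 200
genes, cells with total UMI ≥ 20 000, cells with mitochondrial fraction
≥ 15% (genes identified by a configurable name prefix), then genes detected
in < 3 cells.

Technical noise: genes are ranked by mean expression and split into 20
equal-size bins; σ_tech,g is the square root of the bin-median variance,
floored at 1e-4, so identical-mean genes share σ and a constant gene gets
σ = 0.01 rather than a division by zero.

The raw score is the σ-weighted average of disease-gene expression
(weights ω_g/σ_tech,g, normalized to sum 1). Negative ω_g are clipped at 0
before scoring — a gene whose association z is negative should not carry
negative weight in an expression average, and a top-k set rarely contains
one anyway; clipping is logged. The score is invariant to rescaling all
ω_g by a positive constant.

Controls: each disease gene is replaced, per Monte-Carlo draw, by a uniform
draw from its (20 mean-bins × 5 variance-bins) cell among all genes,
keeping the disease gene's ω but using the control gene's σ; an empty cell
falls back to the nearest nonempty mean bin. B = 1000 draws by default.

Normalization before the empirical p is the open point with the largest
judgment content: each cell's raw score and its B control scores are
centered and scaled by the mean and sd of that cell's own control scores,
then all n_cell·B normalized control values are pooled. This per-cell
recipe removes cell-level depth/complexity effects, which would otherwise
dominate the pooled comparison; it is isolated in `cell_pvalues` so a
gene-set-level alternative can be swapped in. The pooled empirical p is
P_c = (1 + ΣΣ 1[S_c ≤ S^ctrl]) / (1 + n_cell·B), bounded in
[1/(1+n_cell·B), 1] by construction; BH across cells, significance at
adjusted p < 0.05.

Cell-type association: the count of that type's cells with nominal
P_c < 0.05 is tested one-sided against Binomial(n_type, 0.05) — no specific
test is canonical for per-type reporting, and the binomial is the natural
test for "more nominally significant cells than chance";
BH runs across the pooled (cell type × trait) family.

## Cis-eQTL models and TWAS

Genotypes pass an imputation-quality filter (fill score ≥ 0.7, MAF ≥ 0.01).
Cis SNPs lie within ±500 kb of the gene body (the external tool's default;
none is stated for the original analysis). Pseudo-bulk expression per
(individual × cell type) is the mean normalized expression over that
individual's cells, inverse-normal transformed across individuals before
fitting — the aggregation is not specified upstream, and the transform
makes the HE regression and the penalized fits scale-free.

Cis heritability uses Haseman–Elston regression — off-diagonal products
y_i·y_j regressed (with intercept) on the cis-GRM entries (XXᵀ/m on
standardized dosages) — instead of REML: closed form, fast at desk scale,
and unbiased when the GRM spans the causal structure. Significance is a
200-permutation p on the HE slope; the gene gate is permutation p < 0.05
(the "significant heritability" threshold is unstated; 0.05 is the
package's choice). The estimate is clipped to [0, 1].

Weight training: four learners — top1 (best marginal SNP, its marginal
beta), ridge_blup (RidgeCV), lasso (LassoCV), enet (ElasticNetCV, α = 0.5),
penalties by inner cross-validation — evaluated by 5-fold outer CV;
cv_r² is the squared correlation of pooled out-of-fold predictions with
expression, the winner (ties resolved toward the later method in the order
top1 < ridge_blup < lasso < enet) is refit on all samples. A gene with no
learner achieving cv_r² > 0 is rejected.

TWAS: z = wᵀz_GWAS/√(wᵀRw) with R from the reference panel restricted to
the model SNPs; swapped alleles flip the GWAS z sign, other mismatches drop
the SNP; the denominator is floored at 1e-8 with a warning near
singularity. Two-sided normal p; BH across the full
(gene × cell type × trait) table, with both the nominal (p < 0.05) and
study-wide (adjusted p < 0.05) flags carried.

## Differential expression and enrichment

Wilcoxon rank-sum (two-sided) per gene between severe and mild cells of a
type, on the normalized scale: exact when both groups have < 8 tie-free
observations, otherwise the tie-corrected normal approximation, vectorized
across genes. Fold change is computed on de-logged normalized means with
pseudocount 1e-9 (the common single-cell convention; only the 0.25
threshold is prescribed). DEG ⇔ BH-adjusted p < 0.05 and |log₂FC| > 0.25,
BH within cell type.

Over-representation: hypergeometric upper tail of the query/term overlap
within a supplied universe (default: genes expressed in the analyzed cell
type — the original universe is unstated and this is the conservative
local choice), terms intersected with the universe first, zero-overlap
terms dropped, BH across terms. The enrichment ratio is
overlap/query_size, the convention that reproduces reported values such as
1/6 ≈ 0.167.

## Report tables

Phylum tabulation parses the p__ field of k__;p__;… taxonomy strings
(unparseable strings pool under "Others", warned), keeps the top 5 phyla by
count and pools the rest. Percentages are always derived from the stored
counts at read time, never stored: row-wise site shares reproduce exactly,
whereas grand-total percentage columns in published tables of this type can
be internally inconsistent at the second decimal, so they are not a
supported output.

## The synthetic-data generators

What they emulate: LD through a Gaussian copula with equicorrelation rho in
fixed-size blocks (two independent haplotype draws per individual, so
allele frequency is exact in expectation and the block LD structure is
analytically known); heritable Gaussian traits with an exact realized
genetic-variance share; marginal OLS summary statistics; single-cell counts
as NB with var = μ + μ²/size (size = 10, moderate overdispersion), cell-type
labels, a mild/severe label, and a fold-change injection of the disease
genes in target cell types; pseudo-bulk expression as a linear cis effect
plus Gaussian noise with a controlled cis share. All generators are
bit-reproducible given (parameters, seed); a single master seed is split
per stage via `SeedSequence`. Monomorphic SNPs (possible at small n) are
repaired by a deterministic single-heterozygote edit so every SNP is
polymorphic.

What they do not emulate: recombination maps and realistic haplotype
structure, imputation error, strand/allele harmonization issues, ambient
RNA, doublets, batch effects, and non-Gaussian trait scales (microbial
abundances are modelled as Gaussian after transformation — an assumption,
since the trait scale of the original abundance GWAS is not stated).
Passing calibration and recovery tests on these generators therefore
demonstrates correctness of the statistical machinery under the stated
models, not robustness to the artifacts of real cohort data.

## Problem sizes and the packaged demo

The packaged two-trait study uses a 1500-individual × 600-SNP panel with
6-SNP LD blocks aligned to 100 genes (latent rho 0.8), a polygenic signal
trait (h² = 0.5) whose per-SNP effects are amplified 6× inside three
disease genes, a null trait, 1200 cells across five types with the disease
genes upregulated 2-fold in CD16⁺ monocytes (plus a 2^0.5 severe-group
shift), pseudo-bulk expression with cis share 0.4, B = 100 control draws
and a top-30 gene set. Blocks coincide with genes so the gene statistic's
LD null is exercised; the strong within-block LD gives the constrained-
intercept h² fit the precision the gate needs at M = 600. A 900-gene
background universe accompanies the 100 panel genes so the control-matching
bins are populated the way they are in real expression data — with only
~5 genes per bin, matched "controls" would collapse onto the disease set
itself and the scoring null would absorb the signal. Calibration suites use
n = 5000, M = 2000 for LD-score regression, 5000 simulated genes for the
gene test's type-I error, 2000 cells × B = 100 for score sub-uniformity and
1000 genes for TWAS null normality; these sizes give the test bands quoted
in the suite comfortable sampling margins on one CPU.

## Known limitations

- The per-type binomial association test assumes independent cells; at very
  small B (≈20) the granularity of P_c plus cross-cell correlation from the
  shared control draws makes it anti-conservative (measured ~16% of null
  (type, trait) pairs at assoc_p < 0.05). At B = 100 the null rate is ~1–4%;
  keep B ≥ 100 (default 1000).
- The LD-score slope at desk-scale M has visible sampling variance; the
  gate's operating characteristics are demonstrated under strong-LD panels
  and a shared reference panel, the regime the pipeline targets.
- HE cis-h² attenuates when cis weights of opposite sign load on
  correlated SNPs (the GRM then misrepresents the causal covariance); the
  recovery guarantees are stated for concentrated cis architectures.
- Per-trait gene results are kept separate across traits; cross-trait
  de-duplication of genes is reporting, not a rule.
- No cross-population LD adjustment is attempted when the weight-training
  and GWAS populations differ; downstream of such a mismatch only nominal
  significance should be interpreted, which is why the TWAS stage carries
  both flags.
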