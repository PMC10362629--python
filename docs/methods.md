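# Methods

This note documents the statistical model, the synthetic-cohort design,
numerical choices, and known limitations of `irsqtl`.

## Intron clusters and PSI

Junctions are grouped into clusters by connected components of the
"shares a donor or shares an acceptor coordinate on the same chromosome"
relation (transitively closed). Coordinates follow the junction-table
convention: `start` is the 1-based first intronic base and
`end − start` is the intron length, so `end` is the first base of the
downstream exon. Cluster ids `clu_1..clu_N` are assigned in coordinate
order of each cluster's leftmost member, which makes event ids
(`chrom:start:end:clu_K`) reproducible across runs and across the
generator/reader boundary.

PSI is the within-cluster read-share: counts divided by the per-sample
cluster total, set to missing when that total is below
`min_cluster_depth` (default 5 reads — below that the ratio is mostly
noise). Within a cluster, non-missing PSI values sum to 1 per sample by
construction. Only junction reads enter the denominator; exon-body
coverage is not used, so retention evidence requires at least two introns
per cluster. Single-intron clusters (PSI identically 1) are dropped.

Strand is recorded from the junction table but ignored for clustering —
junction tables frequently carry unreliable strand, and the shared-
coordinate relation is strand-free anyway.

## Event filter

Four rules, applied as a sequential cascade with per-rule attrition
counts: junction support (≥ 5 reads in ≥ 25% of samples, on the raw
counts), host-gene expression (FPKM ≥ 1 in ≥ 95% of samples; events not
fully contained in exactly one annotated gene — smallest span wins for
nested genes — are excluded here, because a gene-level expression filter
is undefined for them), PSI variability (CV > 0.1 **and** SD > 0.1 over
non-missing samples, population SD; an event with mean PSI 0 has
undefined CV and fails), and intron length < 5000 bp (strict). For
values bounded in [0, 1] the CV arm is implied by the SD arm whenever the
mean is positive; both are kept because both are part of the standard
filter definition. The filter is idempotent.

## Genotypes, kinship, PCs, LD

Dosages are alt-allele counts from the VCF GT field; `./.` is missing.
Variant filtering keeps MAF > 0.05 and missing rate < 0.2 (both strict).
Missing dosages are mean-imputed per variant — adequate at the
missingness levels left after filtering, and exact for the generator's
default of 0% missingness; statistical phasing/imputation is out of
scope.

Kinship is the standardized GRM,
`K = (1/m) Σ_s (g_s − 2p_s)(g_s − 2p_s)ᵀ / (2p_s(1−p_s))`, skipping
zero-variance variants. Population structure covariates are the top
eigenvectors of K scaled by √eigenvalue, with a deterministic sign
convention (largest-magnitude loading positive); the scan uses the first
two. LD is squared Pearson correlation of dosage vectors over samples
observed at both variants (composite/dosage r², not haplotype r² — phase
is not available from dosages).

## Mixed-model scan

Model: `y = Xβ + u + ε`, `u ~ N(0, σ_g²K)`, `ε ~ N(0, σ_e²I)`, with
`y` the rank inverse-normal transform Φ⁻¹((rank − 0.5)/n) of the
molecular phenotype (average ranks for ties, missing samples dropped with
K and X subset accordingly) and X an intercept plus two PCs.

REML in δ = σ_e²/σ_g² uses the eigendecomposition of S K S (S the
projector orthogonal to X): the restricted likelihood becomes a 1-d
function of δ, evaluated on a 100-point grid over log δ ∈ [−10, 10] and
refined by Brent root-finding on the derivative inside every bracketing
interval. Both variance components are constrained non-negative by
construction. With K = I the model degenerates to OLS: the fitted total
variance equals the OLS residual variance and every per-SNP p-value
matches the covariate-adjusted OLS t-test (verified to 1e-8).

Per-SNP testing holds (σ_g², σ_e²) fixed from the null fit (the EMMAX
approximation — exact per-SNP REML does not scale to events × SNPs).
After rotation by the eigenvectors of K and whitening by
1/√(λ_i + δ), the test is an OLS partial regression; p-values use a t
distribution with n − rank(X) − 1 degrees of freedom. Zero-variance
variants are emitted with missing statistics. A dense oracle that forms
Σ = σ_g²K + σ_e²I explicitly and inverts it per SNP is kept in the test
suite and agrees to |Δlog₁₀p| < 1e-6.

The genome-wide threshold is α / n_effective. `n_effective` is normally
supplied by the user (so a published effective-test count, e.g.
0.05/2.18e-6 ≈ 22 936, is reproduced exactly); otherwise it is estimated
from the eigenvalues of the SNP correlation matrix (Li & Ji 2005). That
estimator is exact for independent or perfectly correlated panels but
can under-count under strong short-range autocorrelated LD; the demo
therefore uses the plain per-SNP Bonferroni count.

Clumping is greedy per (gene, event): the best remaining p becomes a
lead and absorbs all same-chromosome significant SNPs with r² ≥ 0.1 to
it; ties break by (p, chrom, pos); the clumps partition the significant
SNPs. cis/trans uses distance to the nearest intron boundary (0 inside
the intron), strict `< 1 Mb` for cis — a lead at exactly 1 Mb is trans.

## Integration

eQTLs reuse the same engine on rank-transformed log2(FPKM+1) with the
gene span as the cis anchor. Trait GWAS reuses it untransformed on the
phenotype columns; clumped leads become pSNPs when no external pSNP list
is supplied. Colocalization of two leads requires same chromosome,
distance ≤ 100 Kb (inclusive) and r² > 0.1; pairs between 100 Kb and
1 Mb are rescued when r² ≥ 0.5, because tight LD blocks can span more
than the distance window — both the window and the rescue threshold are
config keys and the rescue is flagged separately in the output. The rule
is symmetric in the two loci.

PSI–expression correlation pairs each event with its host gene (case)
and with a seeded uniformly random non-host gene (control), computed on
the identical sample mask so the two distributions are comparable; the
report includes the fraction of |PCC| above 0.6. Haplotype comparisons
are pooled-variance two-sided Student's t-tests between the two
homozygote dosage classes (heterozygotes reported, not tested; skipped
with a reason when either class has < 3 members). cis vs trans
significance is a two-sided Wilcoxon rank-sum on −log₁₀(p).

## Synthetic cohort

The generator's defaults are the study conditions the pipeline is
designed for: 279 samples in 2 subpopulations at F_ST 0.2; 2000 SNPs
with ancestral frequencies uniform on [0.1, 0.5] and Balding–Nichols
subpopulation frequencies Beta(p(1−F)/F, (1−p)(1−F)/F); mean cluster
depth 30 with negative-binomial dispersion 0.2; 150 clusters of 2–4
introns; logit-PSI scale SD 0.5 with heritabilities 0.3 (PSI), 0.4
(expression), 0.5 (trait). Local LD comes from a per-haplotype latent
AR(1) Gaussian copula (adjacent-SNP latent correlation 0.7, reset at
chromosome boundaries), which preserves the BN marginal frequencies —
Hudson's F_ST estimator recovers the configured value — while giving
distance-decaying dosage LD so clumping and lead/causal LD checks are
non-trivial.

True PSI for a focal intron is expit(μ_i + β·g + u + ε) with μ_i uniform
on logit([0.25, 0.75]), u an explicit polygenic sum over the standardized
simulated SNPs, and planted effects β on the logit scale. The cluster
depth is drawn once per cluster/sample; the focal spliced count is
Binomial(depth, PSI) and sibling introns split the remainder by a
Dirichlet-multinomial, so member counts sum exactly to the depth.
Expression is log2(FPKM+1) = μ_g + β_e·g + MVN(0, σ²K) + noise with μ_g
uniform on [3, 6] (so the FPKM filter passes by construction); traits
are Σβ_p·g plus a unit-variance polygenic/noise mix. Planted SNPs may be
auto-placed inside the target's host gene (recorded in the truth file)
or pinned to an explicit index, and one SNP can serve sQTL, eQTL and
trait channels to create a pleiotropic locus.

The synthetic genome gives each gene three CDS exons (random non-stop
codons, ATG...TAA), two introns with GT..AG (strand-aware) boundaries,
and sibling introns as alternative donors patched into the upstream exon
at positions verified not to create an in-frame stop; splicing all
introns out therefore reproduces the annotated protein exactly. What the
generator does **not** emulate: read-level errors and alignment
artifacts, admixed (as opposed to discrete) structure, allele-specific
expression, overdispersion beyond the NB depth model, UTR introns, and
multi-isoform genes. Passing tests on these cohorts demonstrate the
statistics and the plumbing, not robustness to alignment or annotation
error in real data.

Every channel draws from its own seeded stream, so each `simulate_*`
function is a pure function of (config, seed) and the emitted bundle
(VCF / junction TSV / FPKM TSV / phenotype TSV / GFF3 / FASTA / truth
JSON) round-trips byte-identically.

## Consequence prediction

Only introns lying exactly between two consecutive CDS segments are
classified (UTR or unannotated introns return `NOT_CDS_INTRON`).
Translation starts at the annotated ATG with the standard nuclear codon
table; N bases translate to X and never count as stops. A stop before
the annotated stop position is premature: `PTC_INFRAME` when the intron
length is divisible by 3, else `PTC_FRAMESHIFT`; truncation is reported
as annotated-protein length minus truncated length (negative when the
in-frame insertion lengthens the protein). A frameshifted transcript
whose shifted frame reaches the transcript end without a stop is
reported `NO_PTC` (stop-loss read-through) — a deliberate convention for
an edge the classification otherwise leaves undefined.

## Problem sizes and reproducibility experiments

The built-in experiments (`irsqtl.experiments`) run at desk scale chosen
to give stable estimates in minutes: null calibration uses 10 cohorts of
n = 200, 2000 SNPs and 200 events (~4 × 10⁵ tests per seed); power uses
50 replicates at n = 279 and 2000 SNPs; the demo pipeline uses n = 100,
1000 SNPs and 50 clusters. Under these conditions the mixed model's
empirical type-I error at α = 0.01 sits near 0.0095–0.010 with genomic
inflation ≈ 0.99, against 1.6–1.9 for structure-blind OLS; the planted
cis-sQTL is detected below 2.18 × 10⁻⁶ in ≈ 98% of replicates with the
lead SNP in r² ≥ 0.5 with the causal variant, and mean REML trait
heritability ≈ 0.5. These numbers are recomputed, not quoted, by
`scripts/acceptance.py` and the acceptance tests.

## Known limitations

- EMMAX p-values are approximate for SNPs explaining a large variance
  fraction (variance components are not refit per SNP).
- Mean imputation attenuates signal at high missingness; use upstream
  statistical imputation for sparse genotypes.
- The Li–Ji effective-test estimator under-counts under strong local
  LD; supply `n_effective` when a calibrated genome-wide threshold is
  available.
- Junction-only PSI cannot quantify retention for single-intron
  clusters; such events are excluded rather than approximated.
- Colocalization is a lead-SNP distance/LD rule, not a Bayesian
  posterior; it cannot distinguish shared causal variants from tight
  linkage of distinct ones.
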