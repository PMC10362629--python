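"""Synthetic structured cohort with known splicing/expression/trait truth.

Emulates the design of a population sQTL study: a two-or-more-subpopulation
cohort (Balding-Nichols allele frequencies, optional local LD through a
latent AR(1) copula), intron clusters whose per-sample spliced-read counts
are binomial draws around a genotype-driven true PSI, gene expression with
planted cis-eQTL effects and a polygenic background drawn from the kinship
covariance, and quantitative traits with planted causal loci. A synthetic
genome with valid splice-site dinucleotides and a translatable CDS per gene
makes the consequence predictor exercisable end to end.

Every generator is a pure function of (config, seed); the emitted file
bundle (VCF, junction/FPKM/phenotype TSVs, GFF3, FASTA, truth JSON) round
trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .consequences import GeneModel
from .genetics import GenotypeMatrix, KinshipMatrix, Variant, impute_mean, \
    kinship
from .junctions import IntronJunction, write_junction_table

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]

# rng stream ids, so each channel is independently reproducible
_STREAM_GENOME, _STREAM_GENO, _STREAM_PSI, _STREAM_EXPR, _STREAM_PHENO = \
    range(5)


def _rng(config: "CohortConfig", stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedEffect:
    """A causal (SNP, target, effect) triple.

    ``snp`` may be an explicit variant index, None (the generator places a
    SNP inside the target's host span and records the resolved index in the
    truth), or ("sqtl", i) to reuse the SNP resolved for the i-th planted
    sQTL (a pleiotropic locus).
    """

    snp: int | None | tuple
    target: int
    beta: float


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 279
    n_subpops: int = 2
    fst: float = 0.2
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.7
    missing_rate: float = 0.0
    n_chroms: int = 2
    n_clusters: int = 150
    introns_per_cluster: tuple[int, int] = (2, 4)
    n_extra_genes: int = 20
    mean_cluster_depth: float = 30.0
    depth_dispersion: float = 0.2
    psi_logit_sd: float = 0.5
    expr_sd: float = 0.7
    expr_mu_range: tuple[float, float] = (3.0, 6.0)
    causal_sqtls: list[PlantedEffect] = field(default_factory=list)
    causal_eqtls: list[PlantedEffect] = field(default_factory=list)
    causal_pheno: list[PlantedEffect] = field(default_factory=list)
    causal_snp_maf: float | None = 0.3
    heritabilities: dict = field(default_factory=lambda: {
        "psi": 0.3, "expr": 0.4, "pheno": 0.5})
    traits: tuple[str, ...] = ("LP",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if min(self.n_snps, self.n_subpops, self.n_clusters,
               self.n_chroms) < 1:
            raise ValueError("dimensions must be positive")
        if self.introns_per_cluster[0] < 2:
            raise ValueError("clusters need at least 2 introns (a "
                             "single-intron cluster has constant PSI)")
        for h in self.heritabilities.values():
            if not (0.0 <= h < 1.0):
                raise ValueError("heritabilities must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_genes(self) -> int:
        return self.n_clusters + self.n_extra_genes


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside an emitted cohort."""

    causal_sqtls: list[dict] = field(default_factory=list)
    causal_eqtls: list[dict] = field(default_factory=list)
    causal_pheno: list[dict] = field(default_factory=list)
    subpops: list[int] = field(default_factory=list)
    variance_components: dict = field(default_factory=dict)
    focal_events: list[str] = field(default_factory=list)
    true_psi: dict = field(default_factory=dict)  # event -> list of floats
    samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def true_psi_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.true_psi, orient="index",
                                      columns=self.samples)


# ---------------------------------------------------------------------------
# Genome and gene synthesis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGene:
    """A placed gene plus the intron-cluster geometry it hosts."""

    model: GeneModel
    cluster_id: str | None
    junctions: list[tuple[str, int, int]]   # cluster introns, focal first
    focal_junction: tuple[str, int, int] | None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _has_internal_stop(cds: str) -> bool:
    for i in range(0, len(cds) - 3, 3):
        if cds[i:i + 3] in _STOPS:
            return True
    return False


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                offset: int, cluster_size: int | None,
                cluster_id: str | None) -> tuple[SyntheticGene, str]:
    """Synthesize one 3-exon gene starting at 1-based genomic ``offset``.

    Returns the gene (with genomic coordinates) and its genomic sequence.
    Cluster siblings are alternative 5' donors inside the exon upstream of
    the focal intron; their GT dinucleotide is patched into the exon at
    positions that do not create an in-frame stop.
    """
    n_codons = int(rng.integers(80, 160))
    cds = "ATG" + "".join(
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS),
                                              n_codons)) + "TAA"
    L = len(cds)
    min_e = 40
    c1 = int(rng.integers(min_e, L - 2 * min_e))
    c2 = int(rng.integers(c1 + min_e, L - min_e))
    exon_seqs = [cds[:c1], cds[c1:c2], cds[c2:]]
    intron_lens = [int(x) for x in rng.integers(70, 400, 2)]
    intron_seqs = ["GT" + _random_seq(rng, ln - 4) + "AG"
                   for ln in intron_lens]

    focal_idx = int(rng.integers(0, 2)) if cluster_size else None
    sibling_offsets: list[int] = []
    if cluster_size and cluster_size > 1:
        up = list(exon_seqs[focal_idx])
        el = len(up)
        cand = list(rng.permutation(np.arange(6, el - 6)))
        exon_start_in_cds = 0 if focal_idx == 0 else c1
        while cand and len(sibling_offsets) < cluster_size - 1:
            o = int(cand.pop())
            trial = list(cds)
            pos = exon_start_in_cds + el - o  # 0-based donor position in CDS
            for done in sibling_offsets:
                p2 = exon_start_in_cds + el - done
                trial[p2], trial[p2 + 1] = "G", "T"
            trial[pos], trial[pos + 1] = "G", "T"
            if not _has_internal_stop("".join(trial)):
                sibling_offsets.append(o)
        if len(sibling_offsets) < (cluster_size or 1) - 1:
            raise RuntimeError(f"could not place siblings for {gene_id}")
        patched = list(cds)
        for o in sibling_offsets:
            pos = exon_start_in_cds + el - o
            patched[pos], patched[pos + 1] = "G", "T"
        cds = "".join(patched)
        exon_seqs = [cds[:c1], cds[c1:c2], cds[c2:]]

    # transcript assembly and transcript-space intervals (1-based inclusive)
    parts, exon_iv, intron_iv = [], [], []
    t = 0
    for i in range(3):
        parts.append(exon_seqs[i])
        exon_iv.append((t + 1, t + len(exon_seqs[i])))
        t += len(exon_seqs[i])
        if i < 2:
            parts.append(intron_seqs[i])
            intron_iv.append((t + 1, t + intron_lens[i]))
            t += intron_lens[i]
    transcript = "".join(parts)
    gene_len = len(transcript)
    strand = "+" if rng.random() < 0.5 else "-"
    g_start, g_end = offset, offset + gene_len - 1

    def to_genomic(ts: int, te: int) -> tuple[int, int]:
        if strand == "+":
            return g_start - 1 + ts, g_start - 1 + te
        return g_end - te + 1, g_end - ts + 1

    def junction(ts: int, te: int) -> tuple[str, int, int]:
        a, b = to_genomic(ts, te)
        return chrom, a, b + 1  # end - start = intron length

    cds_segs = [to_genomic(*iv) for iv in exon_iv]
    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                      cds=cds_segs)

    junctions: list[tuple[str, int, int]] = []
    focal = None
    if cluster_size:
        f_ts, f_te = intron_iv[focal_idx]
        focal = junction(f_ts, f_te)
        junctions.append(focal)
        for o in sibling_offsets:
            junctions.append(junction(f_ts - o, f_te))
    seq = transcript if strand == "+" else _revcomp_str(transcript)
    return SyntheticGene(model=model, cluster_id=cluster_id,
                         junctions=junctions, focal_junction=focal), seq


def _revcomp_str(s: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return s.translate(comp)[::-1]


def build_genome(config: CohortConfig,
                 ) -> tuple[list[SyntheticGene], dict[str, str]]:
    """Lay out all genes on ``n_chroms`` chromosomes and emit sequences."""
    rng = _rng(config, _STREAM_GENOME)
    sizes = rng.integers(config.introns_per_cluster[0],
                         config.introns_per_cluster[1] + 1,
                         config.n_clusters)
    chrom_names = [f"A{c + 1:02d}" for c in range(config.n_chroms)]
    pieces = {c: [] for c in chrom_names}
    cursor = {c: 0 for c in chrom_names}
    genes: list[SyntheticGene] = []
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chroms]
        gap = int(rng.integers(500, 2000))
        pieces[chrom].append(_random_seq(rng, gap))
        cursor[chrom] += gap
        hosts = i < config.n_clusters
        gene, seq = _build_gene(
            rng, f"GENE{i + 1:04d}", chrom, cursor[chrom] + 1,
            int(sizes[i]) if hosts else None,
            f"clu_{i + 1}" if hosts else None)
        pieces[chrom].append(seq)
        cursor[chrom] += len(seq)
        genes.append(gene)
    for chrom in chrom_names:
        tail = int(rng.integers(500, 2000))
        pieces[chrom].append(_random_seq(rng, tail))
    genome = {c: "".join(pieces[c]) for c in chrom_names}

    # renumber clusters in coordinate order, matching the deterministic
    # labelling cluster_introns() will assign when the counts are re-read
    hosts = [g for g in genes if g.cluster_id is not None]
    hosts.sort(key=lambda g: min((c, a, b) for c, a, b in g.junctions))
    for k, g in enumerate(hosts, start=1):
        g.cluster_id = f"clu_{k}"
    return genes, genome


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: CohortConfig,
                       chrom_lengths: dict[str, int] | None = None,
                       causal_spans: Sequence[tuple[str, int, int]] = (),
                       genome: dict[str, str] | None = None,
                       ) -> tuple[GenotypeMatrix, np.ndarray, list[int]]:
    """Balding-Nichols genotypes with local LD from a latent AR(1) copula.

    Each SNP draws an ancestral frequency p from ``maf_range`` and
    subpopulation frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F); haplotype
    alleles are thresholded latent Gaussians with adjacent-SNP correlation
    ``ld_rho`` (reset across chromosomes), so marginal frequencies follow
    the BN model while dosages carry distance-decaying LD.

    Returns (genotypes, subpopulation labels, resolved indices of the
    requested causal SNPs, one per entry of ``causal_spans``).
    """
    rng = _rng(config, _STREAM_GENO)
    if chrom_lengths is None:
        chrom_lengths = {f"A{c + 1:02d}": 1_000_000
                         for c in range(config.n_chroms)}
    chroms = list(chrom_lengths)
    n, m = config.n_samples, config.n_snps
    n_causal = len(causal_spans)
    if m <= n_causal:
        raise ValueError("n_snps must exceed the number of causal SNPs")

    total_len = sum(chrom_lengths.values())
    records: list[tuple[str, int, bool, int]] = []  # chrom,pos,causal,slot
    m_bg = m - n_causal
    for ci, chrom in enumerate(chroms):
        share = (chrom_lengths[chrom] * m_bg) // total_len
        if ci == len(chroms) - 1:
            share = m_bg - sum(1 for r in records)
        pos = np.sort(rng.choice(
            np.arange(1, chrom_lengths[chrom] + 1), size=share,
            replace=False))
        records.extend((chrom, int(p), False, -1) for p in pos)
    for slot, (chrom, a, b) in enumerate(causal_spans):
        records.append((chrom, int(rng.integers(a, b + 1)), True, slot))
    order = {c: i for i, c in enumerate(chroms)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    causal_idx = [-1] * n_causal
    for i, r in enumerate(records):
        if r[2]:
            causal_idx[r[3]] = i

    p_anc = rng.uniform(*config.maf_range, size=m)
    if config.causal_snp_maf is not None:
        for i in causal_idx:
            p_anc[i] = config.causal_snp_maf
    F = config.fst
    a_par = p_anc * (1 - F) / F
    b_par = (1 - p_anc) * (1 - F) / F
    freqs = rng.beta(a_par[None, :].repeat(config.n_subpops, axis=0),
                     b_par[None, :].repeat(config.n_subpops, axis=0))

    labels = np.sort(np.arange(n) % config.n_subpops)
    eps = rng.standard_normal((2, n, m))
    z = np.empty_like(eps)
    z[:, :, 0] = eps[:, :, 0]
    rho = config.ld_rho
    sq = np.sqrt(1.0 - rho * rho)
    chrom_of = [r[0] for r in records]
    for j in range(1, m):
        if chrom_of[j] == chrom_of[j - 1] and rho > 0:
            z[:, :, j] = rho * z[:, :, j - 1] + sq * eps[:, :, j]
        else:
            z[:, :, j] = eps[:, :, j]
    from scipy.stats import norm
    thr = norm.ppf(np.clip(freqs, 1e-12, 1 - 1e-12))[labels, :]  # n x m
    dosage = ((z[0] < thr).astype(float) + (z[1] < thr)).T  # m x n

    if config.missing_rate > 0:
        mask = rng.random((m, n)) < config.missing_rate
        dosage[mask] = np.nan

    variants = []
    for (chrom, pos, _, _) in records:
        if genome is not None and pos <= len(genome[chrom]):
            ref = genome[chrom][pos - 1]
        else:
            ref = str(_BASES[rng.integers(0, 4)])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(Variant(chrom, pos, ref, alt, f"{chrom}_{pos}"))
    G = GenotypeMatrix([f"S{i + 1:03d}" for i in range(n)], variants, dosage)
    return G, labels, causal_idx


# ---------------------------------------------------------------------------
# PSI / junction counts
# ---------------------------------------------------------------------------

def _chain_multinomial(rng: np.random.Generator, totals: np.ndarray,
                       probs: np.ndarray) -> np.ndarray:
    """Vectorized multinomial via chained binomials; probs rows sum to 1."""
    n, k = probs.shape
    out = np.zeros((k, n), dtype=np.int64)
    remaining = totals.astype(np.int64).copy()
    acc = np.ones(n)
    for j in range(k):
        if j == k - 1:
            out[j] = remaining
            break
        pj = np.clip(probs[:, j] / np.maximum(acc, 1e-300), 0.0, 1.0)
        out[j] = rng.binomial(remaining, pj)
        remaining -= out[j]
        acc -= probs[:, j]
    return out


def simulate_psi_and_counts(G: GenotypeMatrix, config: CohortConfig,
                            truth: SyntheticTruth,
                            genes: Sequence[SyntheticGene],
                            ) -> tuple[list[IntronJunction], list[str],
                                       pd.DataFrame]:
    """Draw junction counts around genotype-driven true PSI.

    For the focal intron of cluster i and sample s, true
    PSI = expit(mu_i + beta_s g + u_s + eps) with u a polygenic term of the
    configured heritability; cluster depth is negative-binomial and the
    focal spliced count binomial(T, PSI); sibling introns share the
    remaining reads through a Dirichlet-multinomial, so counts sum exactly
    to the drawn depth. Returns (junction rows, cluster label per row, true
    PSI per event).
    """
    rng = _rng(config, _STREAM_PSI)
    hosts = [g for g in genes if g.cluster_id is not None]
    nc, n = len(hosts), G.n_samples
    for pe in config.causal_sqtls:
        if not (0 <= pe.target < nc):
            raise ValueError(f"causal sQTL event index {pe.target} out of "
                             f"range (0..{nc - 1})")

    h2 = config.heritabilities.get("psi", 0.0)
    s2 = config.psi_logit_sd ** 2
    sig_u, sig_e = np.sqrt(h2 * s2), np.sqrt((1 - h2) * s2)

    dos = G.dosages
    if np.isnan(dos).any():
        dos = impute_mean(G).dosages
    mu = rng.uniform(logit(0.25), logit(0.75), nc)
    logit_psi = np.tile(mu[:, None], (1, n))
    if sig_u > 0:
        p_freq = dos.mean(axis=1) / 2.0
        poly = (p_freq > 0) & (p_freq < 1)
        Z = ((dos[poly] - 2 * p_freq[poly, None])
             / np.sqrt(2 * p_freq[poly, None] * (1 - p_freq[poly, None])))
        W = rng.standard_normal((Z.shape[0], nc))
        logit_psi += (Z.T @ W).T * (sig_u / np.sqrt(Z.shape[0]))
    logit_psi += sig_e * rng.standard_normal((nc, n))

    resolved_sqtls = []
    for pe in config.causal_sqtls:
        snp = pe.snp if isinstance(pe.snp, (int, np.integer)) else None
        if snp is None:
            raise ValueError("unresolved planted SNP; use generate_cohort "
                             "or pass explicit indices")
        logit_psi[pe.target] += pe.beta * np.nan_to_num(
            dos[snp], nan=float(np.nanmean(dos[snp])))
        resolved_sqtls.append(
            {"snp_index": int(snp), "snp_id": G.variants[snp].id,
             "event_index": int(pe.target), "beta": float(pe.beta)})

    psi_f = expit(logit_psi)

    disp = config.depth_dispersion
    mean_d = config.mean_cluster_depth
    if disp > 0:
        r = 1.0 / disp
        depth = rng.negative_binomial(r, r / (r + mean_d), (nc, n))
    else:
        depth = rng.poisson(mean_d, (nc, n))

    junctions: list[IntronJunction] = []
    clusters: list[str] = []
    true_rows: dict[str, np.ndarray] = {}
    focal_ids: list[str] = []
    for i, gene in enumerate(hosts):
        n_f = rng.binomial(depth[i], psi_f[i])
        rem = depth[i] - n_f
        sibs = gene.junctions[1:]
        k = len(sibs)
        if k == 1:
            sib_counts = rem[None, :]
            sib_probs = np.ones((n, 1))
        else:
            w = rng.dirichlet(np.full(k, 2.0))
            gam = rng.gamma(np.tile(10.0 * w, (n, 1)))
            sib_probs = gam / gam.sum(axis=1, keepdims=True)
            sib_counts = _chain_multinomial(rng, rem, sib_probs)
        members = [(gene.focal_junction, n_f, psi_f[i])] + [
            (sibs[j], sib_counts[j], (1.0 - psi_f[i]) * sib_probs[:, j])
            for j in range(k)]
        members.sort(key=lambda t: (t[0][1], t[0][2]))
        for (chrom, a, b), counts, tpsi in members:
            jid = f"{chrom}:{a}:{b}:{gene.cluster_id}"
            junctions.append(IntronJunction(chrom=chrom, start=a, end=b,
                                            strand=gene.model.strand,
                                            counts=np.asarray(counts)))
            clusters.append(gene.cluster_id)
            true_rows[jid] = np.asarray(tpsi, dtype=float)
            if (chrom, a, b) == gene.focal_junction:
                focal_ids.append(jid)

    true_psi = pd.DataFrame.from_dict(true_rows, orient="index",
                                      columns=G.samples)
    truth.causal_sqtls = [
        dict(r, event_id=focal_ids[r["event_index"]]) for r in resolved_sqtls]
    truth.focal_events = focal_ids
    truth.variance_components["psi"] = {"sigma_u2": float(sig_u ** 2),
                                        "sigma_e2": float(sig_e ** 2)}
    return junctions, clusters, true_psi


# ---------------------------------------------------------------------------
# Expression and phenotype
# ---------------------------------------------------------------------------

def _mvn_polygenic(rng: np.random.Generator, K: KinshipMatrix, n_draws: int,
                   sigma: float) -> np.ndarray:
    """n_samples x n_draws draws from N(0, sigma^2 K)."""
    w, V = np.linalg.eigh(K.values)
    A = V * np.sqrt(np.clip(w, 0.0, None))
    return sigma * (A @ rng.standard_normal((K.n, n_draws)))


def simulate_expression(G: GenotypeMatrix, K: KinshipMatrix,
                        config: CohortConfig, truth: SyntheticTruth,
                        genes: Sequence[SyntheticGene]) -> pd.DataFrame:
    """FPKM table: log2(FPKM+1) = mu_g + beta_e g + polygenic + noise."""
    rng = _rng(config, _STREAM_EXPR)
    ng, n = len(genes), G.n_samples
    for pe in config.causal_eqtls:
        if not (0 <= pe.target < ng):
            raise ValueError(f"causal eQTL gene index {pe.target} out of "
                             f"range (0..{ng - 1})")
    h2 = config.heritabilities.get("expr", 0.0)
    s = config.expr_sd
    sig_u, sig_e = np.sqrt(h2) * s, np.sqrt(1 - h2) * s
    mu = rng.uniform(*config.expr_mu_range, ng)
    x = np.tile(mu[:, None], (1, n))
    if sig_u > 0:
        x += _mvn_polygenic(rng, K, ng, sig_u).T
    x += sig_e * rng.standard_normal((ng, n))
    dos = G.dosages
    resolved = []
    for pe in config.causal_eqtls:
        snp = int(pe.snp)
        g = np.nan_to_num(dos[snp], nan=float(np.nanmean(dos[snp])))
        x[pe.target] += pe.beta * g
        resolved.append({"snp_index": snp, "snp_id": G.variants[snp].id,
                         "gene_index": int(pe.target),
                         "gene_id": genes[pe.target].model.gene_id,
                         "beta": float(pe.beta)})
    fpkm = np.clip(np.power(2.0, x) - 1.0, 0.0, None)
    truth.causal_eqtls = resolved
    truth.variance_components["expr"] = {"sigma_u2": float(sig_u ** 2),
                                         "sigma_e2": float(sig_e ** 2)}
    return pd.DataFrame(fpkm, index=[g.model.gene_id for g in genes],
                        columns=G.samples)


def simulate_phenotype(G: GenotypeMatrix, config: CohortConfig,
                       truth: SyntheticTruth,
                       K: KinshipMatrix | None = None) -> pd.DataFrame:
    """Trait table: y = sum beta_p g + polygenic + noise, per trait column.

    The non-QTL part has unit variance split as h2 polygenic / (1 - h2)
    noise, so a planted SNP with effect beta explains about
    beta^2 Var(g) / (1 + beta^2 Var(g)) of the trait variance.
    """
    rng = _rng(config, _STREAM_PHENO)
    n = G.n_samples
    if K is None:
        K = kinship(impute_mean(G))
    h2 = config.heritabilities.get("pheno", 0.0)
    sig_u, sig_e = np.sqrt(h2), np.sqrt(1 - h2)
    out = {}
    resolved = []
    for t_i, trait in enumerate(config.traits):
        y = np.zeros(n)
        if sig_u > 0:
            y += _mvn_polygenic(rng, K, 1, sig_u)[:, 0]
        y += sig_e * rng.standard_normal(n)
        for pe in config.causal_pheno:
            if pe.target != t_i:
                continue
            snp = int(pe.snp)
            g = np.nan_to_num(G.dosages[snp],
                              nan=float(np.nanmean(G.dosages[snp])))
            y += pe.beta * g
            resolved.append({"snp_index": snp, "snp_id": G.variants[snp].id,
                             "trait": trait, "beta": float(pe.beta)})
        out[trait] = y
    truth.causal_pheno = resolved
    truth.variance_components["pheno"] = {"sigma_u2": float(sig_u ** 2),
                                          "sigma_e2": float(sig_e ** 2)}
    return pd.DataFrame(out, index=G.samples)


# ---------------------------------------------------------------------------
# Cohort assembly and file bundle
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    genes: list[SyntheticGene]
    genome: dict[str, str]
    G: GenotypeMatrix
    K: KinshipMatrix
    subpops: np.ndarray
    junctions: list[IntronJunction]
    junction_clusters: list[str]
    true_psi: pd.DataFrame
    fpkm: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth

    @property
    def samples(self) -> list[str]:
        return list(self.G.samples)

    @property
    def gene_models(self) -> dict[str, GeneModel]:
        return {g.model.gene_id: g.model for g in self.genes}


def _resolve_planted(config: CohortConfig, genes: list[SyntheticGene],
                     ) -> tuple[CohortConfig, list[tuple[str, int, int]],
                                list[tuple[str, int]]]:
    """Collect host spans for auto-placed causal SNPs.

    Returns the spans to hand to simulate_genotypes plus bookkeeping of
    which PlantedEffect gets which resolved slot.
    """
    spans: list[tuple[str, int, int]] = []
    slots: list[tuple[str, int]] = []  # (channel, position in channel list)
    for pe in config.causal_sqtls:
        if not (0 <= pe.target < config.n_clusters):
            raise ValueError(f"causal sQTL event index {pe.target} out of "
                             f"range (0..{config.n_clusters - 1})")
    for pe in config.causal_eqtls:
        if not (0 <= pe.target < config.n_genes):
            raise ValueError(f"causal eQTL gene index {pe.target} out of "
                             f"range (0..{config.n_genes - 1})")
    for i, pe in enumerate(config.causal_sqtls):
        if pe.snp is None:
            g = genes[pe.target]
            a, b = g.model.span
            spans.append((g.model.chrom, a, b))
            slots.append(("sqtl", i))
    for i, pe in enumerate(config.causal_eqtls):
        if pe.snp is None:
            g = genes[pe.target]
            a, b = g.model.span
            spans.append((g.model.chrom, a, b))
            slots.append(("eqtl", i))
    for i, pe in enumerate(config.causal_pheno):
        if pe.snp is None:
            raise ValueError("phenotype causal SNPs need an explicit index "
                             "or a ('sqtl', i) reference")
    return config, spans, slots


def generate_cohort(config: CohortConfig) -> Cohort:
    """End-to-end cohort synthesis: genome, genotypes, counts, expression,
    phenotypes, with resolved ground truth."""
    import copy

    config = copy.deepcopy(config)
    genes, genome = build_genome(config)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    _, spans, slots = _resolve_planted(config, genes)
    G, labels, causal_idx = simulate_genotypes(
        config, chrom_lengths, causal_spans=spans, genome=genome)
    for (channel, i), vi in zip(slots, causal_idx):
        if channel == "sqtl":
            config.causal_sqtls[i].snp = vi
        else:
            config.causal_eqtls[i].snp = vi
    for pe in config.causal_eqtls + config.causal_pheno:
        if isinstance(pe.snp, tuple) and pe.snp[0] == "sqtl":
            pe.snp = int(config.causal_sqtls[pe.snp[1]].snp)
    for pe in (config.causal_sqtls + config.causal_eqtls
               + config.causal_pheno):
        if not (0 <= int(pe.snp) < config.n_snps):
            raise ValueError(f"causal SNP index {pe.snp} out of range")

    K = kinship(impute_mean(G))
    truth = SyntheticTruth(subpops=[int(x) for x in labels],
                           samples=list(G.samples))
    junctions, clusters, true_psi = simulate_psi_and_counts(
        G, config, truth, genes)
    fpkm = simulate_expression(G, K, config, truth, genes)
    phenotypes = simulate_phenotype(G, config, truth, K)
    truth.true_psi = {k: [float(v) for v in row]
                      for k, row in true_psi.iterrows()}
    return Cohort(config=config, genes=genes, genome=genome, G=G, K=K,
                  subpops=labels, junctions=junctions,
                  junction_clusters=clusters, true_psi=true_psi, fpkm=fpkm,
                  phenotypes=phenotypes, truth=truth)


def resample_counts(cohort: Cohort, seed: int) -> list[IntronJunction]:
    """Technical replicate: fresh depths and counts around the same true PSI."""
    rng = np.random.default_rng([seed, 97])
    cfg = cohort.config
    out = []
    by_cluster: dict[str, list[int]] = {}
    for i, cl in enumerate(cohort.junction_clusters):
        by_cluster.setdefault(cl, []).append(i)
    disp, mean_d = cfg.depth_dispersion, cfg.mean_cluster_depth
    n = len(cohort.samples)
    for cl, idxs in by_cluster.items():
        if disp > 0:
            r = 1.0 / disp
            depth = rng.negative_binomial(r, r / (r + mean_d), n)
        else:
            depth = rng.poisson(mean_d, n)
        probs = np.vstack([
            cohort.true_psi.loc[
                f"{cohort.junctions[i].chrom}:{cohort.junctions[i].start}:"
                f"{cohort.junctions[i].end}:{cl}"].to_numpy()
            for i in idxs]).T
        probs = probs / np.maximum(probs.sum(axis=1, keepdims=True), 1e-12)
        counts = _chain_multinomial(rng, depth, probs)
        for row, i in enumerate(idxs):
            j = cohort.junctions[i]
            out.append(IntronJunction(chrom=j.chrom, start=j.start,
                                      end=j.end, strand=j.strand,
                                      counts=counts[row]))
    return out


def write_fasta(genome: dict[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fpkm(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", float_format="%.6g", index_label="sample")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features (exons equal CDS segments here)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            a, b = g.span
            fh.write(f"{g.chrom}\tirsqtl\tgene\t{a}\t{b}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tirsqtl\tmRNA\t{a}\t{b}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            phase = 0
            for ci, (s, e) in enumerate(g.cds_in_transcription_order(), 1):
                fh.write(f"{g.chrom}\tirsqtl\texon\t{s}\t{e}\t.\t{g.strand}"
                         f"\t.\tID={mrna}.exon{ci};Parent={mrna}\n")
                fh.write(f"{g.chrom}\tirsqtl\tCDS\t{s}\t{e}\t.\t{g.strand}"
                         f"\t{phase}\tID={mrna}.cds{ci};Parent={mrna}\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


@dataclass
class LoadedCohort:
    """A cohort bundle re-read from disk (truth included when present)."""

    G: GenotypeMatrix
    junctions: list[IntronJunction]
    junction_clusters: list[str] | None
    fpkm: pd.DataFrame
    phenotypes: pd.DataFrame
    gene_models: dict[str, GeneModel]
    genome: dict[str, str]
    truth: SyntheticTruth | None

    @property
    def samples(self) -> list[str]:
        return list(self.G.samples)


FILES = {
    "vcf": "genotypes.vcf",
    "junctions": "junctions.tsv",
    "fpkm": "fpkm.tsv",
    "phenotypes": "phenotypes.tsv",
    "gff3": "genes.gff3",
    "fasta": "genome.fa",
    "truth": "truth.json",
}


def write_cohort(cohort: "Cohort | LoadedCohort", outdir: str | Path,
                 ) -> dict[str, Path]:
    """Emit the full file bundle; returns the path of each artifact.

    Writing the same in-memory cohort twice, or writing what
    :func:`read_cohort` returned, produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FILES.items()}
    chrom_lengths = {c: len(s) for c, s in cohort.genome.items()}
    cohort.G.to_vcf(paths["vcf"], contig_lengths=chrom_lengths)
    write_junction_table(cohort.junctions, cohort.samples,
                         paths["junctions"],
                         clusters=cohort.junction_clusters)
    write_fpkm(cohort.fpkm, paths["fpkm"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    models = (cohort.gene_models.values()
              if isinstance(cohort.gene_models, dict)
              else [g.model for g in cohort.genes])
    write_gff3(list(models), paths["gff3"])
    write_fasta(cohort.genome, paths["fasta"])
    if cohort.truth is not None:
        cohort.truth.to_json(paths["truth"])
    return paths


def read_cohort(outdir: str | Path) -> LoadedCohort:
    """Re-read a bundle written by :func:`write_cohort`."""
    from .consequences import read_gene_models
    from .junctions import read_junction_table

    outdir = Path(outdir)
    G = GenotypeMatrix.from_vcf(outdir / FILES["vcf"])
    df = pd.read_csv(outdir / FILES["junctions"], sep="\t")
    junctions, _ = read_junction_table(outdir / FILES["junctions"])
    clusters = (list(df["cluster"]) if "cluster" in df.columns else None)
    fpkm = read_fpkm(outdir / FILES["fpkm"])
    pheno = read_phenotypes(outdir / FILES["phenotypes"])
    models = read_gene_models(outdir / FILES["gff3"])
    genome: dict[str, str] = {}
    with open(outdir / FILES["fasta"]) as fh:
        name, buf = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(buf)
                name, buf = line[1:].split()[0], []
            else:
                buf.append(line)
        if name is not None:
            genome[name] = "".join(buf)
    truth_path = outdir / FILES["truth"]
    truth = SyntheticTruth.from_json(truth_path) if truth_path.exists() \
        else None
    return LoadedCohort(G=G, junctions=junctions, junction_clusters=clusters,
                        fpkm=fpkm, phenotypes=pheno, gene_models=models,
                        genome=genome, truth=truth)
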