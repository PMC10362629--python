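"""End-to-end orchestration: inputs -> PSI -> sQTLs -> integration -> PTC.

A single declarative configuration (key = value text file or the
:class:`PipelineConfig` dataclass) drives the stages in order:

    junctions -> genetics -> mixed model sQTL scan -> eQTL/coloc/haplotype
    -> consequences

Every stage writes its table into the output directory and contributes
record counts to a run manifest, so the attrition funnel of a run can be
compared against expectations. Demo mode generates a synthetic cohort with
a planted pleiotropic locus and runs the full pipeline on it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consequences import (gene_spans_from_gff3, load_genome,
                           predict_consequences, read_gene_models)
from .genetics import (GenotypeMatrix, filter_variants, impute_mean, kinship,
                       pca)
from .integration import (coloc_qtls, coloc_table, compare_cis_trans_significance,
                          map_eqtls, haplotype_test,
                          psi_expression_correlation, read_psnp_table,
                          trait_gwas_psnps)
from .junctions import (assign_events_to_genes, build_psi_matrix,
                        filter_events, read_junction_table)
from .mixed_model import (ScanEngine, annotate_cis_trans, clump_to_sqtls,
                          significance_threshold, sqtl_table)
from .synthetic import (Cohort, CohortConfig, PlantedEffect, generate_cohort,
                        read_fpkm, read_phenotypes, write_cohort)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a run; defaults are the standard design.

    Thresholds: MAF > 0.05, missing rate < 0.2, junction support 5 reads in
    25% of samples, FPKM >= 1 in 95%, CV > 0.1 and SD > 0.1, intron length
    < 5000 bp, genome-wide alpha 0.05 over n_effective tests, cis window
    1 Mb, clump r^2 0.1, coloc window 100 Kb with r^2 > 0.1, PCC threshold
    0.6.
    """

    vcf: str | None = None
    junctions: str | None = None
    fpkm: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    phenotypes: str | None = None
    psnps: str | None = None
    outdir: str = "irsqtl_out"
    seed: int = 0

    maf_min: float = 0.05
    missing_max: float = 0.2
    min_cluster_depth: int = 5
    junction_min_reads: int = 5
    junction_min_fraction: float = 0.25
    fpkm_min: float = 1.0
    fpkm_fraction: float = 0.95
    cv_min: float = 0.1
    sd_min: float = 0.1
    intron_max_len: int = 5000
    alpha: float = 0.05
    n_effective: float | None = None
    n_pcs: int = 2
    cis_window: int = 1_000_000
    clump_r2: float = 0.1
    coloc_window: int = 100_000
    coloc_r2: float = 0.1
    coloc_rescue_window: int = 1_000_000
    coloc_rescue_r2: float = 0.5
    pcc_threshold: float = 0.6

    def __post_init__(self) -> None:
        for name in ("missing_max", "junction_min_fraction", "fpkm_fraction",
                     "cv_min", "sd_min", "alpha", "clump_r2", "coloc_r2",
                     "coloc_rescue_r2", "pcc_threshold"):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a ``key = value`` text config (# comments allowed)."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise KeyError(f"unknown config key: {key}")
            if raw.lower() in ("none", ""):
                kwargs[key] = None
                continue
            ftype = fields[key].type
            if "int" in str(ftype):
                kwargs[key] = int(float(raw))
            elif "float" in str(ftype):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Pre-flight checks; returns a machine-readable issue list (empty = ok)."""
    issues: list[dict] = []
    paths = {k: getattr(config, k)
             for k in ("vcf", "junctions", "fpkm", "gff3", "fasta",
                       "phenotypes", "psnps")}
    for kind, p in paths.items():
        if p is not None and not Path(p).exists():
            issues.append({"kind": "missing_file", "input": kind, "path": p})
    if issues:
        return issues
    sample_sets = {}
    if config.vcf:
        G = GenotypeMatrix.from_vcf(config.vcf)
        sample_sets["vcf"] = set(G.samples)
    if config.junctions:
        junctions, samples = read_junction_table(config.junctions)
        sample_sets["junctions"] = set(samples)
        if config.fasta:
            genome = load_genome(config.fasta)
            lengths = {k: len(genome[k]) for k in genome.keys()}
            for j in junctions:
                if j.chrom not in lengths:
                    issues.append({"kind": "unknown_chrom",
                                   "junction": j.id})
                elif j.end - 1 > lengths[j.chrom]:
                    issues.append({"kind": "junction_beyond_chrom_end",
                                   "junction": j.id,
                                   "chrom_length": lengths[j.chrom]})
    if config.fpkm:
        sample_sets["fpkm"] = set(read_fpkm(config.fpkm).columns)
    if config.phenotypes:
        sample_sets["phenotypes"] = set(read_phenotypes(config.phenotypes
                                                        ).index)
    if config.gff3:
        try:
            read_gene_models(config.gff3)
        except Exception as exc:  # pragma: no cover
            issues.append({"kind": "gff3_parse_error", "error": str(exc)})
    names = list(sample_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            only_a = sorted(sample_sets[a] - sample_sets[b])
            only_b = sorted(sample_sets[b] - sample_sets[a])
            if only_a or only_b:
                issues.append({"kind": "sample_mismatch", "inputs": [a, b],
                               f"only_in_{a}": only_a[:10],
                               f"only_in_{b}": only_b[:10]})
    return issues


@dataclass
class RunManifest:
    """Stage-by-stage record counts and provenance of one run."""

    config: dict
    version: str = __version__
    counts: dict = field(default_factory=dict)
    wallclock: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True,
                      default=str)
            fh.write("\n")


def demo_config(seed: int = 0, n_samples: int = 100, n_snps: int = 1000,
                n_clusters: int = 50) -> CohortConfig:
    """Demo cohort: one planted pleiotropic locus driving splicing of event
    0, expression of its host gene, and the trait."""
    return CohortConfig(
        n_samples=n_samples, n_snps=n_snps, n_clusters=n_clusters,
        n_extra_genes=15, seed=seed,
        causal_sqtls=[PlantedEffect(None, 0, 1.2)],
        causal_eqtls=[PlantedEffect(("sqtl", 0), 0, 1.0)],
        causal_pheno=[PlantedEffect(("sqtl", 0), 0, 1.3)])


def run_pipeline(config: PipelineConfig,
                 cohort: Cohort | None = None) -> RunManifest:
    """Execute every stage; returns the manifest (also written to outdir).

    When ``cohort`` is given (demo mode) its file bundle is written into
    the output directory first and then consumed through the same file
    contracts as user-supplied inputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    t_all = time.time()

    if cohort is not None:
        bundle = write_cohort(cohort, outdir / "cohort")
        config = dataclasses.replace(
            config, vcf=str(bundle["vcf"]), junctions=str(bundle["junctions"]),
            fpkm=str(bundle["fpkm"]), gff3=str(bundle["gff3"]),
            fasta=str(bundle["fasta"]), phenotypes=str(bundle["phenotypes"]))

    for kind in ("vcf", "junctions", "fpkm", "gff3", "fasta"):
        p = getattr(config, kind)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input '{kind}' missing: {p}")

    # --- genetics ---------------------------------------------------------
    t0 = time.time()
    G_raw = GenotypeMatrix.from_vcf(config.vcf)
    G = filter_variants(G_raw, maf_min=config.maf_min,
                        missing_max=config.missing_max)
    manifest.counts["variants_in"] = G_raw.n_variants
    manifest.counts["variants_pass"] = G.n_variants
    G = impute_mean(G)
    K = kinship(G)
    pcs = pca(K, min(10, K.n)).scores
    K.to_tsv(outdir / "kinship.tsv")
    manifest.wallclock["genetics"] = time.time() - t0

    # --- junctions / PSI --------------------------------------------------
    t0 = time.time()
    junctions, samples = read_junction_table(config.junctions)
    if samples != G.samples:
        raise ValueError(
            "sample sets differ between VCF and junction table: "
            f"only_vcf={sorted(set(G.samples) - set(samples))[:5]} "
            f"only_junc={sorted(set(samples) - set(G.samples))[:5]}")
    psi = build_psi_matrix(junctions, samples,
                           min_cluster_depth=config.min_cluster_depth)
    manifest.counts["junctions_in"] = len(junctions)
    manifest.counts["events_quantified"] = len(psi.event_ids)
    gene_spans = gene_spans_from_gff3(config.gff3)
    gene_map = assign_events_to_genes(psi, gene_spans)
    expr = read_fpkm(config.fpkm)
    filtered, attrition = filter_events(
        psi, expr, gene_map,
        {"junction_min_reads": config.junction_min_reads,
         "junction_min_fraction": config.junction_min_fraction,
         "fpkm_min": config.fpkm_min, "fpkm_fraction": config.fpkm_fraction,
         "cv_min": config.cv_min, "sd_min": config.sd_min,
         "intron_max_len": config.intron_max_len})
    manifest.counts["event_filter"] = attrition
    filtered.to_tsv(outdir / "psi.tsv")
    manifest.wallclock["junctions"] = time.time() - t0

    # --- sQTL scan --------------------------------------------------------
    t0 = time.time()
    p_thresh = significance_threshold(config.alpha, config.n_effective,
                                      G if config.n_effective is None
                                      else None)
    manifest.counts["p_threshold"] = p_thresh
    engine = ScanEngine(G, K, pcs, n_pcs=config.n_pcs)
    assoc, _ = engine.scan_matrix(filtered.values)
    hits = assoc[assoc["p"] < p_thresh]
    manifest.counts["significant_snp_event_pairs"] = int(len(hits))
    sqtls = clump_to_sqtls(hits, G, r2_thresh=config.clump_r2,
                           gene_map=gene_map.to_dict())
    anchors = filtered.meta[["chrom", "start", "end"]]
    sqtls = annotate_cis_trans(sqtls, anchors, cis_window=config.cis_window)
    stab = sqtl_table(sqtls)
    stab.to_csv(outdir / "sqtls.tsv", sep="\t", index=False)
    manifest.counts["sqtls"] = len(sqtls)
    manifest.counts["cis_sqtls"] = int((stab["cis_trans"] == "cis").sum())
    manifest.counts["trans_sqtls"] = int((stab["cis_trans"] == "trans").sum())
    manifest.wallclock["sqtl_scan"] = time.time() - t0

    # --- integration ------------------------------------------------------
    t0 = time.time()
    eqtls = map_eqtls(expr, G, K, pcs, gene_spans, p_threshold=p_thresh,
                      r2_thresh=config.clump_r2,
                      cis_window=config.cis_window, n_pcs=config.n_pcs)
    manifest.counts["eqtls"] = len(eqtls)
    epartners = pd.DataFrame(
        [{"tag": "eQTL", "id": r.event_id, "chrom": r.chrom, "pos": r.pos,
          "vidx": r.vidx, "gene": r.gene} for r in eqtls])
    cis_sqtls = [r for r in sqtls if r.cis_trans == "cis"]
    se_pairs = (coloc_qtls(cis_sqtls, epartners, G,
                           window=config.coloc_window, r2_min=config.coloc_r2,
                           rescue_window=config.coloc_rescue_window,
                           rescue_r2=config.coloc_rescue_r2, same_gene=True)
                if len(epartners) else [])
    coloc_table(se_pairs).to_csv(outdir / "coloc_sqtl_eqtl.tsv", sep="\t",
                                 index=False)
    manifest.counts["sqtl_eqtl_coloc"] = int(sum(p.colocalized
                                                 for p in se_pairs))

    if config.psnps:
        psnps = read_psnp_table(config.psnps, G)
    elif config.phenotypes:
        pheno = read_phenotypes(config.phenotypes).loc[G.samples]
        psnps = trait_gwas_psnps(pheno, G, K, pcs, p_threshold=p_thresh,
                                 r2_thresh=config.clump_r2,
                                 n_pcs=config.n_pcs)
    else:
        psnps = pd.DataFrame(columns=["tag", "id", "chrom", "pos", "vidx",
                                      "trait", "p"])
    manifest.counts["psnps"] = int(len(psnps))
    sp_pairs = (coloc_qtls(cis_sqtls, psnps, G, window=config.coloc_window,
                           r2_min=config.coloc_r2,
                           rescue_window=config.coloc_rescue_window,
                           rescue_r2=config.coloc_rescue_r2)
                if len(psnps) else [])
    coloc_table(sp_pairs).to_csv(outdir / "coloc_sqtl_gwas.tsv", sep="\t",
                                 index=False)
    manifest.counts["sqtl_gwas_coloc"] = int(sum(p.colocalized
                                                 for p in sp_pairs))

    corr = psi_expression_correlation(filtered, expr, gene_map,
                                      seed=config.seed,
                                      threshold=config.pcc_threshold)
    corr.table.to_csv(outdir / "psi_expression_pcc.tsv", sep="\t",
                      index=False)
    manifest.counts["pcc_case_fraction_above"] = corr.fraction_case_above
    manifest.counts["pcc_control_fraction_above"] = \
        corr.fraction_control_above

    hap_rows = []
    for r in sqtls:
        res = haplotype_test(
            filtered.values.loc[r.event_id].to_numpy(dtype=float), G, r.vidx)
        hap_rows.append({"event_id": r.event_id, "variant": res.variant_id,
                         "t": res.t_stat, "p": res.p,
                         "skipped": res.skipped or ""})
    pd.DataFrame(hap_rows, columns=["event_id", "variant", "t", "p",
                                    "skipped"]
                 ).to_csv(outdir / "haplotype_tests.tsv", sep="\t",
                          index=False)
    manifest.counts["cis_trans_comparison"] = \
        compare_cis_trans_significance(sqtls)
    manifest.wallclock["integration"] = time.time() - t0

    # --- consequences -----------------------------------------------------
    t0 = time.time()
    genome = load_genome(config.fasta)
    gene_models = read_gene_models(config.gff3)
    cis_events = (filtered.meta.loc[[r.event_id for r in cis_sqtls]]
                  .assign(gene=[r.gene for r in cis_sqtls]))
    cis_events = cis_events[~cis_events.index.duplicated()]
    cons = predict_consequences(cis_events, gene_models, genome)
    cons.to_csv(outdir / "consequences.tsv", sep="\t", index=False)
    manifest.counts["consequences"] = {
        str(k): int(v) for k, v in cons["class"].value_counts().items()}
    manifest.wallclock["consequences"] = time.time() - t0

    # --- pleiotropic chain check (demo/truth mode) ------------------------
    if cohort is not None and cohort.truth.causal_sqtls:
        from .genetics import ld_r2
        planted = cohort.truth.causal_sqtls[0]
        lookup = {(v.chrom, v.pos): i for i, v in enumerate(G.variants)}
        raw = cohort.G.variants[planted["snp_index"]]
        vi = lookup.get((raw.chrom, raw.pos), -1)
        found = [r for r in sqtls if r.event_id == planted["event_id"]
                 and vi >= 0 and (r.vidx == vi
                                  or (ld_r2(G, r.vidx, vi) or 0) >= 0.5)]
        chain = {"sqtl_recovered": bool(found)}
        if found:
            lead = found[0]
            chain["sqtl_eqtl_coloc"] = any(
                p.colocalized and p.sqtl_event == lead.event_id
                for p in se_pairs)
            chain["sqtl_gwas_coloc"] = any(
                p.colocalized and p.sqtl_event == lead.event_id
                for p in sp_pairs)
            chain["full_chain"] = bool(chain["sqtl_eqtl_coloc"]
                                       and chain["sqtl_gwas_coloc"])
        manifest.flags["pleiotropic_chain"] = chain

    manifest.wallclock["total"] = time.time() - t_all
    manifest.to_json(outdir / "manifest.json")
    return manifest


def run_demo(seed: int = 0, outdir: str | Path = "irsqtl_demo",
             **cohort_kwargs) -> RunManifest:
    """Generate the demo cohort and run the full pipeline on it."""
    cohort = generate_cohort(demo_config(seed=seed, **cohort_kwargs))
    config = PipelineConfig(outdir=str(outdir), seed=seed,
                            n_effective=cohort.config.n_snps)
    return run_pipeline(config, cohort=cohort)
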