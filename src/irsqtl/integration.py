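"""Cross-layer analyses linking sQTLs to expression and trait genetics.

Covers eQTL mapping with the same mixed-model engine, lead-SNP
colocalization of sQTLs with eQTLs or trait-GWAS loci (distance window
plus LD arm), PSI-expression correlation with a random-gene control, and
haplotype-stratified comparisons of a quantitative value between the two
homozygote genotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GenotypeMatrix, KinshipMatrix, ld_r2
from .junctions import PsiMatrix
from .mixed_model import (ScanEngine, SQTLRecord, annotate_cis_trans,
                          clump_to_sqtls, rank_inverse_normal)


def map_eqtls(expr: pd.DataFrame, G: GenotypeMatrix, K: KinshipMatrix,
              pcs: np.ndarray, gene_spans: pd.DataFrame,
              p_threshold: float, r2_thresh: float = 0.1,
              cis_window: int = 1_000_000, n_pcs: int = 2,
              ) -> list[SQTLRecord]:
    """eQTL scan: the sQTL engine run on log-expression, gene span as anchor.

    Per gene, log2(FPKM+1) is rank-inverse-normal transformed and scanned;
    significant SNPs are clumped per gene and classified cis/trans against
    the gene span. Zero-variance genes are skipped with a warning.
    """
    import warnings

    engine = ScanEngine(G, K, pcs, n_pcs=n_pcs)
    spans = gene_spans.set_index("gene_id")
    frames = []
    for gene_id, row in expr.iterrows():
        vals = np.log2(row.to_numpy(dtype=float) + 1.0)
        if np.nanstd(vals) == 0:
            warnings.warn(f"gene {gene_id} has zero expression variance; "
                          "skipped")
            continue
        res, _ = engine.scan_event(vals, str(gene_id))
        res = res[res["p"] < p_threshold]
        if len(res):
            frames.append(res)
    if not frames:
        return []
    hits = pd.concat(frames, ignore_index=True)
    gene_map = {g: g for g in hits["event_id"].unique()}
    records = clump_to_sqtls(hits, G, r2_thresh=r2_thresh, gene_map=gene_map)
    anchors = spans.loc[[r.event_id for r in records],
                        ["chrom", "start", "end"]]
    anchors = anchors[~anchors.index.duplicated()]
    return annotate_cis_trans(records, anchors, cis_window=cis_window)


@dataclass
class ColocPair:
    """A tested sQTL/partner lead-SNP pair with its colocalization metrics."""

    sqtl_event: str
    sqtl_gene: str | None
    sqtl_chrom: str
    sqtl_pos: int
    partner_tag: str            # "eQTL" or "pSNP"
    partner_id: str
    partner_chrom: str
    partner_pos: int
    distance: float
    r2: float
    colocalized: bool
    rescued: bool = False       # LD arm beyond the distance window


def coloc_qtls(sqtls: Sequence[SQTLRecord], partners: pd.DataFrame,
               G: GenotypeMatrix, window: int = 100_000,
               r2_min: float = 0.1, rescue_window: int = 1_000_000,
               rescue_r2: float = 0.5, same_gene: bool = False,
               ) -> list[ColocPair]:
    """Lead-SNP colocalization of sQTLs with partner loci.

    ``partners`` needs columns tag, id, chrom, pos, vidx (and gene when
    ``same_gene``). A pair colocalizes when the two lead SNPs sit on the
    same chromosome within ``window`` bp and are in LD (r^2 > ``r2_min``);
    pairs farther apart (up to ``rescue_window``) are rescued when LD is
    strong (r^2 >= ``rescue_r2``), since tight linkage can span more than
    the distance window. The rule is symmetric in the two loci.
    """
    out: list[ColocPair] = []
    for s in sqtls:
        for _, p in partners.iterrows():
            if same_gene and p.get("gene") != s.gene:
                continue
            if p["chrom"] != s.chrom:
                dist, r2 = float("inf"), float("nan")
                flag = rescued = False
            else:
                dist = float(abs(int(p["pos"]) - s.pos))
                r2 = (ld_r2(G, s.vidx, int(p["vidx"]))
                      if int(p["vidx"]) >= 0 else float("nan"))
                near = dist <= window and (not np.isnan(r2)) and r2 > r2_min
                rescued = (window < dist <= rescue_window
                           and (not np.isnan(r2)) and r2 >= rescue_r2)
                flag = bool(near or rescued)
            out.append(ColocPair(
                sqtl_event=s.event_id, sqtl_gene=s.gene, sqtl_chrom=s.chrom,
                sqtl_pos=s.pos, partner_tag=str(p["tag"]),
                partner_id=str(p["id"]), partner_chrom=str(p["chrom"]),
                partner_pos=int(p["pos"]), distance=dist, r2=float(r2),
                colocalized=flag, rescued=bool(rescued)))
    return out


def coloc_table(pairs: Sequence[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": p.sqtl_event, "gene": p.sqtl_gene,
        "sSNP": f"{p.sqtl_chrom}:{p.sqtl_pos}", "partner_tag": p.partner_tag,
        "partner": p.partner_id,
        "partner_pos": f"{p.partner_chrom}:{p.partner_pos}",
        "distance": p.distance, "r2": p.r2, "colocalized": p.colocalized,
        "rescued": p.rescued} for p in pairs])


@dataclass
class CorrelationReport:
    """Case vs random-control PSI-expression correlations."""

    table: pd.DataFrame          # event, gene, control_gene, pcc_case, pcc_control, n
    threshold: float

    @property
    def fraction_case_above(self) -> float:
        v = self.table["pcc_case"].abs()
        return float((v > self.threshold).mean()) if len(v) else float("nan")

    @property
    def fraction_control_above(self) -> float:
        v = self.table["pcc_control"].abs()
        return float((v > self.threshold).mean()) if len(v) else float("nan")


def psi_expression_correlation(psi: PsiMatrix, expr: pd.DataFrame,
                               gene_map: pd.Series, seed: int,
                               threshold: float = 0.6) -> CorrelationReport:
    """Pearson correlation of each event's PSI with its host gene expression.

    The control pairs the same PSI values with a uniformly random non-host
    gene (seeded), computed on the identical sample mask so the comparison
    is fair.
    """
    rng = np.random.default_rng(seed)
    genes = list(expr.index)
    rows = []
    for event_id in psi.event_ids:
        host = gene_map.get(event_id)
        if not isinstance(host, str) or host not in expr.index:
            continue
        others = [g for g in genes if g != host]
        control = others[rng.integers(0, len(others))] if others else None
        x = psi.values.loc[event_id].to_numpy(dtype=float)
        y = expr.loc[host].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if control is not None:
            ok &= ~np.isnan(expr.loc[control].to_numpy(dtype=float))
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        pcc_case = float(np.corrcoef(x[ok], y[ok])[0, 1])
        pcc_ctrl = float("nan")
        if control is not None:
            z = expr.loc[control].to_numpy(dtype=float)
            if np.std(z[ok]) > 0:
                pcc_ctrl = float(np.corrcoef(x[ok], z[ok])[0, 1])
        rows.append({"event_id": event_id, "gene": host,
                     "control_gene": control, "pcc_case": pcc_case,
                     "pcc_control": pcc_ctrl, "n": int(ok.sum())})
    return CorrelationReport(table=pd.DataFrame(
        rows, columns=["event_id", "gene", "control_gene", "pcc_case",
                       "pcc_control", "n"]), threshold=threshold)


@dataclass
class HaplotypeComparison:
    """Two-sided Student's t-test between the homozygote genotype classes."""

    variant_id: str
    group_n: dict[str, int]
    group_means: dict[str, float]
    t_stat: float
    p: float
    skipped: str | None = None


def haplotype_test(values: np.ndarray, G: GenotypeMatrix, vidx: int,
                   min_group: int = 3) -> HaplotypeComparison:
    """Pooled-variance t-test of a value between hom-ref and hom-alt samples.

    Heterozygotes are reported (count/mean) but not tested. The test is
    skipped with a reason when either homozygote class has fewer than
    ``min_group`` members with a non-missing value.
    """
    values = np.asarray(values, dtype=float)
    dos = G.dosages[vidx]
    vid = G.variants[vidx].id
    groups = {}
    for code, name in ((0, "hom_ref"), (1, "het"), (2, "hom_alt")):
        sel = (dos == code) & ~np.isnan(values)
        groups[name] = values[sel]
    n = {k: int(len(v)) for k, v in groups.items()}
    means = {k: (float(np.mean(v)) if len(v) else float("nan"))
             for k, v in groups.items()}
    if n["hom_ref"] < min_group or n["hom_alt"] < min_group:
        return HaplotypeComparison(variant_id=vid, group_n=n,
                                   group_means=means, t_stat=float("nan"),
                                   p=float("nan"),
                                   skipped="homozygote class below "
                                           f"min_group={min_group}")
    t, p = stats.ttest_ind(groups["hom_ref"], groups["hom_alt"],
                           equal_var=True)
    return HaplotypeComparison(variant_id=vid, group_n=n, group_means=means,
                               t_stat=float(t), p=float(p))


def compare_cis_trans_significance(sqtls: Sequence[SQTLRecord],
                                   ) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum on -log10(p) between cis and trans sets."""
    cis = np.array([-np.log10(r.p) for r in sqtls if r.cis_trans == "cis"])
    trans = np.array([-np.log10(r.p) for r in sqtls
                      if r.cis_trans == "trans"])
    if len(cis) == 0 or len(trans) == 0:
        return {"n_cis": float(len(cis)), "n_trans": float(len(trans)),
                "stat": float("nan"), "p": float("nan")}
    stat, p = stats.ranksums(cis, trans)
    return {"n_cis": float(len(cis)), "n_trans": float(len(trans)),
            "stat": float(stat), "p": float(p),
            "median_cis": float(np.median(cis)),
            "median_trans": float(np.median(trans))}


def trait_gwas_psnps(phenotypes: pd.DataFrame, G: GenotypeMatrix,
                     K: KinshipMatrix, pcs: np.ndarray, p_threshold: float,
                     r2_thresh: float = 0.1, n_pcs: int = 2) -> pd.DataFrame:
    """Trait GWAS with the same engine; returns lead pSNPs per trait.

    Output columns match the partner-table contract of :func:`coloc_qtls`
    (tag, id, chrom, pos, vidx, trait, p).
    """
    engine = ScanEngine(G, K, pcs, n_pcs=n_pcs)
    rows = []
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        res, _ = engine.scan_event(y, str(trait), transform=False)
        hits = res[res["p"] < p_threshold]
        if not len(hits):
            continue
        leads = clump_to_sqtls(hits, G, r2_thresh=r2_thresh,
                               gene_map={str(trait): None})
        for r in leads:
            rows.append({"tag": "pSNP", "id": f"{r.chrom}:{r.pos}",
                         "chrom": r.chrom, "pos": r.pos, "vidx": r.vidx,
                         "trait": trait, "p": r.p})
    return pd.DataFrame(rows, columns=["tag", "id", "chrom", "pos", "vidx",
                                       "trait", "p"])


def read_psnp_table(path, G: GenotypeMatrix | None = None) -> pd.DataFrame:
    """External pSNP list: TSV with columns trait, snp ("chrom:pos"), p.

    When ``G`` is given, pSNPs are matched to genotyped variants by exact
    chrom:pos so the LD arm of colocalization can be evaluated; unmatched
    pSNPs keep vidx -1 and can only fail the LD arm.
    """
    df = pd.read_csv(path, sep="\t")
    chrom_pos = df["snp"].str.split(":", expand=True)
    out = pd.DataFrame({"tag": "pSNP", "id": df["snp"],
                        "chrom": chrom_pos[0],
                        "pos": chrom_pos[1].astype(int),
                        "trait": df["trait"], "p": df["p"]})
    out["vidx"] = -1
    if G is not None:
        lookup = {(v.chrom, v.pos): i for i, v in enumerate(G.variants)}
        out["vidx"] = [lookup.get((c, p), -1)
                       for c, p in zip(out["chrom"], out["pos"])]
    return out
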