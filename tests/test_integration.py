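"""Colocalization logic, PSI-expression correlation, haplotype tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irsqtl.genetics import GenotypeMatrix, Variant, impute_mean, pca
from irsqtl.integration import (coloc_qtls, compare_cis_trans_significance,
                                haplotype_test, map_eqtls,
                                psi_expression_correlation)
from irsqtl.junctions import PsiMatrix, build_psi_matrix
from irsqtl.mixed_model import SQTLRecord
from irsqtl.synthetic import CohortConfig, PlantedEffect, generate_cohort


def _sqtl(vidx, chrom, pos, gene="G1", event="e1", p=1e-8):
    return SQTLRecord(event_id=event, gene=gene, vidx=vidx, chrom=chrom,
                      pos=pos, ref="A", alt="G", p=p, beta=1.0,
                      n_clumped_snps=1)


def _ld_genotypes(n=400, seed=0):
    """Variant pairs with controlled LD for the coloc fixtures."""
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, 0.5, n).astype(float)
    b_high = np.where(rng.random(n) < 0.9, a, rng.binomial(2, 0.5, n))
    b_low = rng.binomial(2, 0.5, n).astype(float)
    variants = [Variant("c1", 100, "A", "G", "a"),
                Variant("c1", 50_100, "A", "G", "b_high"),
                Variant("c1", 50_200, "A", "G", "b_low"),
                Variant("c1", 400_100, "A", "G", "far_high"),
                Variant("c2", 100, "A", "G", "other_chrom")]
    dos = np.vstack([a, b_high, b_low,
                     np.where(rng.random(n) < 0.9, a,
                              rng.binomial(2, 0.5, n)),
                     a.copy()])
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dos)


class TestColoc:
    def test_near_pair_in_ld_colocalizes(self):
        G = _ld_genotypes()
        partners = pd.DataFrame([{"tag": "eQTL", "id": "e", "chrom": "c1",
                                  "pos": 50_100, "vidx": 1, "gene": "G1"}])
        pairs = coloc_qtls([_sqtl(0, "c1", 100)], partners, G)
        assert pairs[0].colocalized and not pairs[0].rescued

    def test_near_pair_without_ld_fails(self):
        G = _ld_genotypes()
        partners = pd.DataFrame([{"tag": "eQTL", "id": "e", "chrom": "c1",
                                  "pos": 50_200, "vidx": 2, "gene": "G1"}])
        pairs = coloc_qtls([_sqtl(0, "c1", 100)], partners, G)
        assert not pairs[0].colocalized

    def test_distant_pair_rescued_only_by_strong_ld(self):
        G = _ld_genotypes()
        partners = pd.DataFrame([{"tag": "pSNP", "id": "p", "chrom": "c1",
                                  "pos": 400_100, "vidx": 3}])
        pairs = coloc_qtls([_sqtl(0, "c1", 100)], partners, G)
        assert pairs[0].colocalized and pairs[0].rescued

    def test_other_chromosome_never_colocalizes(self):
        G = _ld_genotypes()
        partners = pd.DataFrame([{"tag": "pSNP", "id": "p", "chrom": "c2",
                                  "pos": 100, "vidx": 4}])
        pairs = coloc_qtls([_sqtl(0, "c1", 100)], partners, G)
        assert not pairs[0].colocalized and np.isinf(pairs[0].distance)

    def test_twenty_pair_fixture_matches_enumeration(self):
        """Random distances/r2 against exhaustive rule evaluation."""
        rng = np.random.default_rng(3)
        n = 600
        base = rng.binomial(2, 0.5, (20, n)).astype(float)
        partner_dos, svars, pvars = [], [], []
        dists = rng.choice([10_000, 90_000, 110_000, 800_000, 2_000_000], 20)
        mix = rng.uniform(0.3, 1.0, 20)
        for i in range(20):
            svars.append(Variant("c1", 10_000_0 + i, "A", "G", f"s{i}"))
            pvars.append(Variant("c1", 10_000_0 + i + int(dists[i]),
                                 "A", "G", f"p{i}"))
            partner_dos.append(np.where(rng.random(n) < mix[i], base[i],
                                        rng.binomial(2, 0.5, n)))
        G = GenotypeMatrix([f"x{i}" for i in range(n)], svars + pvars,
                           np.vstack([base, np.vstack(partner_dos)]))
        sqtls = [_sqtl(i, "c1", svars[i].pos, event=f"e{i}")
                 for i in range(20)]
        partners = pd.DataFrame(
            [{"tag": "pSNP", "id": f"p{i}", "chrom": "c1",
              "pos": pvars[i].pos, "vidx": 20 + i} for i in range(20)])
        pairs = coloc_qtls(sqtls, partners, G)
        from irsqtl.genetics import ld_r2
        for i in range(20):
            pr = [p for p in pairs if p.sqtl_event == f"e{i}"
                  and p.partner_id == f"p{i}"][0]
            d = dists[i]
            r2 = ld_r2(G, i, 20 + i)
            expect = (d <= 100_000 and r2 > 0.1) or \
                (100_000 < d <= 1_000_000 and r2 >= 0.5)
            assert pr.colocalized == expect, (i, d, r2)

    def test_rule_is_symmetric(self):
        G = _ld_genotypes()
        fwd = coloc_qtls([_sqtl(0, "c1", 100)],
                         pd.DataFrame([{"tag": "pSNP", "id": "p",
                                        "chrom": "c1", "pos": 50_100,
                                        "vidx": 1}]), G)
        rev = coloc_qtls([_sqtl(1, "c1", 50_100)],
                         pd.DataFrame([{"tag": "pSNP", "id": "p",
                                        "chrom": "c1", "pos": 100,
                                        "vidx": 0}]), G)
        assert fwd[0].colocalized == rev[0].colocalized
        assert fwd[0].distance == rev[0].distance


def _psi_and_expr(n=50, coupled=False, seed=1):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    ids = [f"c:{i * 100 + 100}:{i * 100 + 180}:clu_{i + 1}"
           for i in range(20)]
    vals = rng.uniform(0.1, 0.9, (20, n))
    meta = pd.DataFrame({"chrom": "c",
                         "start": [i * 100 + 100 for i in range(20)],
                         "end": [i * 100 + 180 for i in range(20)],
                         "strand": "?",
                         "cluster": [f"clu_{i + 1}" for i in range(20)],
                         "length": 80}, index=ids)
    psi = PsiMatrix(pd.DataFrame(vals, index=ids, columns=samples), meta)
    genes = [f"G{i}" for i in range(25)]
    expr = pd.DataFrame(rng.uniform(1, 20, (25, n)), index=genes,
                        columns=samples)
    gene_map = pd.Series({ids[i]: f"G{i}" for i in range(20)})
    if coupled:
        for i in range(20):
            expr.loc[f"G{i}"] = 5.0 + 10.0 * vals[i]
    return psi, expr, gene_map


class TestPsiExpressionCorrelation:
    def test_affine_coupling_gives_unit_correlation(self):
        psi, expr, gene_map = _psi_and_expr(coupled=True)
        rep = psi_expression_correlation(psi, expr, gene_map, seed=0)
        assert np.allclose(rep.table["pcc_case"], 1.0)
        assert rep.fraction_case_above == 1.0

    def test_independent_channels_near_zero(self):
        psi, expr, gene_map = _psi_and_expr(coupled=False)
        rep = psi_expression_correlation(psi, expr, gene_map, seed=0)
        assert abs(rep.table["pcc_case"].mean()) < 0.15
        assert rep.fraction_case_above <= 0.1

    def test_case_and_control_distinguishable_when_coupled(self):
        psi, expr, gene_map = _psi_and_expr(coupled=True)
        rep = psi_expression_correlation(psi, expr, gene_map, seed=0)
        assert rep.fraction_case_above > rep.fraction_control_above

    def test_control_excludes_host_gene_and_is_seeded(self):
        psi, expr, gene_map = _psi_and_expr()
        r1 = psi_expression_correlation(psi, expr, gene_map, seed=7)
        r2 = psi_expression_correlation(psi, expr, gene_map, seed=7)
        assert (r1.table["control_gene"] != r1.table["gene"]).all()
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestHaplotypeTest:
    def _g(self, dosages):
        return GenotypeMatrix([f"s{i}" for i in range(len(dosages))],
                              [Variant("c", 1, "A", "G", "v")],
                              np.asarray([dosages], dtype=float))

    def test_identical_groups_give_t_zero_p_one(self):
        dos = [0, 0, 0, 2, 2, 2]
        res = haplotype_test(np.array([1, 2, 3, 1, 2, 3.0]), self._g(dos), 0)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        dos = [0, 0, 0, 2, 2, 2]
        vals = np.array([1, 2, 3, 4, 5, 6.0])
        res = haplotype_test(vals, self._g(dos), 0)
        a, b = vals[:3], vals[3:]
        sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert res.t_stat == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_small_homozygote_class_skipped(self):
        dos = [0, 0, 2, 2, 2, 1]
        res = haplotype_test(np.arange(6, dtype=float), self._g(dos), 0)
        assert res.skipped is not None and np.isnan(res.p)

    def test_heterozygotes_reported_untested(self):
        dos = [0, 0, 0, 1, 1, 2, 2, 2]
        res = haplotype_test(np.arange(8, dtype=float), self._g(dos), 0)
        assert res.group_n["het"] == 2
        assert not np.isnan(res.p)

    def test_sign_agrees_with_planted_effect(self):
        """Positive logit-PSI effect -> hom-alt PSI above hom-ref."""
        agree = 0
        for seed in range(10):
            cfg = CohortConfig(n_samples=150, n_snps=150, n_clusters=3,
                               n_extra_genes=0, seed=300 + seed,
                               causal_sqtls=[PlantedEffect(None, 0, 1.0)])
            c = generate_cohort(cfg)
            ev = c.truth.causal_sqtls[0]["event_id"]
            snp = c.truth.causal_sqtls[0]["snp_index"]
            psi = build_psi_matrix(c.junctions, c.samples)
            res = haplotype_test(psi.values.loc[ev].to_numpy(dtype=float),
                                 c.G, snp)
            if res.skipped is None and \
                    res.group_means["hom_alt"] > res.group_means["hom_ref"]:
                agree += 1
        assert agree >= 9

    def test_eqtl_scan_recovers_planted_gene(self):
        cfg = CohortConfig(n_samples=150, n_snps=300, n_clusters=3,
                           n_extra_genes=5, seed=17,
                           causal_eqtls=[PlantedEffect(None, 4, 1.0)])
        c = generate_cohort(cfg)
        G = impute_mean(c.G)
        pcs = pca(c.K, 2).scores
        spans = pd.DataFrame(
            [{"gene_id": g.model.gene_id, "chrom": g.model.chrom,
              "start": g.model.span[0], "end": g.model.span[1]}
             for g in c.genes])
        recs = map_eqtls(c.fpkm, G, c.K, pcs, spans,
                         p_threshold=0.05 / 300)
        target = c.truth.causal_eqtls[0]["gene_id"]
        hits = [r for r in recs if r.event_id == target]
        assert hits and hits[0].cis_trans == "cis"


class TestCisTransComparison:
    def _mk(self, ps, label):
        return [_sqtl(0, "c1", 100, event=f"{label}{i}", p=p)
                for i, p in enumerate(ps)]

    def test_identical_distributions_not_significant(self, rng):
        ps = 10.0 ** -rng.uniform(6, 10, 30)
        recs = self._mk(ps, "a") + self._mk(ps, "b")
        for r in recs[:30]:
            r.cis_trans = "cis"
        for r in recs[30:]:
            r.cis_trans = "trans"
        rep = compare_cis_trans_significance(recs)
        assert rep["p"] > 0.9

    def test_shifted_cis_set_detected(self, rng):
        base = rng.uniform(6, 8, 30)
        cis = self._mk(10.0 ** -(base + 2), "a")
        trans = self._mk(10.0 ** -base, "b")
        for r in cis:
            r.cis_trans = "cis"
        for r in trans:
            r.cis_trans = "trans"
        rep = compare_cis_trans_significance(cis + trans)
        assert rep["p"] < 0.05 and rep["median_cis"] > rep["median_trans"]

    def test_invariant_to_record_order(self, rng):
        base = rng.uniform(6, 8, 20)
        cis = self._mk(10.0 ** -(base + 1), "a")
        trans = self._mk(10.0 ** -base, "b")
        for r in cis:
            r.cis_trans = "cis"
        for r in trans:
            r.cis_trans = "trans"
        a = compare_cis_trans_significance(cis + trans)
        b = compare_cis_trans_significance(trans[::-1] + cis[::-1])
        assert a["p"] == pytest.approx(b["p"])
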