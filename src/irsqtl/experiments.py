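"""Built-in reproducibility experiments on synthetic cohorts.

These drive the full stack (generator -> PSI -> mixed model) under known
truth and measure the operating characteristics a user should expect:
type-I error and genomic inflation on a structured null cohort, and power,
lead-SNP LD with the causal variant, and REML heritability recovery under
a planted cis-sQTL. They are used by the test suite and the acceptance
script, and are runnable directly for larger designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetics import impute_mean, ld_r2, pca
from .junctions import build_psi_matrix
from .mixed_model import ScanEngine, fit_null_reml, rank_inverse_normal
from .synthetic import CohortConfig, PlantedEffect, generate_cohort


def genomic_inflation(p: np.ndarray) -> float:
    """Median-based lambda: median chi^2(1) of the tests over 0.4549."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    return float(np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1))


def _naive_ols_p(y: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Marginal OLS (intercept only, no kinship/PCs) across all SNPs."""
    ok = ~np.isnan(y)
    yy = y[ok] - y[ok].mean()
    gg = dosages[:, ok] - dosages[:, ok].mean(axis=1, keepdims=True)
    den = np.maximum((gg ** 2).sum(axis=1), 1e-12)
    b = (gg @ yy) / den
    rss = np.clip(yy @ yy - b ** 2 * den, 0.0, None)
    df = int(ok.sum()) - 2
    t = b / np.sqrt(rss / df / den)
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class NullCalibrationResult:
    type_i_error: list[float]      # per seed, at the requested alpha
    lambda_mixed: list[float]
    lambda_ols: list[float]
    alpha: float
    n_tests_per_seed: int


def null_calibration_experiment(base_seed: int = 0, n_seeds: int = 10,
                                n_samples: int = 200, n_snps: int = 2000,
                                n_events: int = 200, alpha: float = 0.01,
                                ) -> NullCalibrationResult:
    """Structured null cohort: no planted sQTLs, polygenic PSI background.

    Per seed, scans every focal event and pools the p-values; reports the
    empirical type-I error at ``alpha`` and the genomic inflation of the
    mixed model versus naive (structure-blind) OLS.
    """
    t1, lam_mm, lam_ols = [], [], []
    n_tests = 0
    for s in range(n_seeds):
        cfg = CohortConfig(n_samples=n_samples, n_snps=n_snps,
                           n_clusters=n_events, n_extra_genes=0,
                           seed=base_seed + s)
        c = generate_cohort(cfg)
        G = impute_mean(c.G)
        pcs = pca(c.K, 2).scores
        engine = ScanEngine(G, c.K, pcs)
        psi = build_psi_matrix(c.junctions, c.samples)
        ps, ops = [], []
        for ev in c.truth.focal_events:
            vals = psi.values.loc[ev].to_numpy(dtype=float)
            res, _ = engine.scan_event(vals, ev)
            ps.append(res["p"].to_numpy())
            ops.append(_naive_ols_p(rank_inverse_normal(vals), G.dosages))
        ps = np.concatenate(ps)
        ps = ps[~np.isnan(ps)]
        ops = np.concatenate(ops)
        t1.append(float(np.mean(ps < alpha)))
        lam_mm.append(genomic_inflation(ps))
        lam_ols.append(genomic_inflation(ops))
        n_tests = len(ps)
    return NullCalibrationResult(type_i_error=t1, lambda_mixed=lam_mm,
                                 lambda_ols=lam_ols, alpha=alpha,
                                 n_tests_per_seed=n_tests)


@dataclass
class PowerResult:
    n_replicates: int
    power: float                 # fraction detected below p_threshold
    lead_in_ld: float            # fraction with lead r2 >= ld_r2_min
    h2_estimates: list[float]
    h2_true: float
    p_threshold: float


def power_experiment(base_seed: int = 0, n_replicates: int = 50,
                     n_samples: int = 279, n_snps: int = 2000,
                     effect: float = 1.0, depth: float = 30.0,
                     p_threshold: float = 2.18e-6,
                     ld_r2_min: float = 0.5) -> PowerResult:
    """Planted cis-sQTL recovery plus trait-heritability recovery.

    Each replicate plants one cis-sQTL (logit-PSI effect ``effect``, causal
    MAF 0.3) in a fresh structured cohort, scans its event, and checks the
    lead SNP against the causal variant; REML heritability is estimated on
    the simulated polygenic trait (true h2 from the config, default 0.5).
    """
    hits = ld_ok = 0
    h2s = []
    h2_true = None
    for s in range(n_replicates):
        cfg = CohortConfig(n_samples=n_samples, n_snps=n_snps, n_clusters=5,
                           n_extra_genes=0, mean_cluster_depth=depth,
                           seed=base_seed + s,
                           causal_sqtls=[PlantedEffect(None, 0, effect)])
        h2_true = cfg.heritabilities["pheno"]
        c = generate_cohort(cfg)
        G = impute_mean(c.G)
        pcs = pca(c.K, 2).scores
        engine = ScanEngine(G, c.K, pcs)
        psi = build_psi_matrix(c.junctions, c.samples)
        ev = c.truth.causal_sqtls[0]["event_id"]
        snp = c.truth.causal_sqtls[0]["snp_index"]
        res, _ = engine.scan_event(psi.values.loc[ev].to_numpy(dtype=float),
                                   ev)
        lead = res.loc[res["p"].idxmin()]
        if lead["p"] < p_threshold:
            hits += 1
        r2 = 1.0 if int(lead["vidx"]) == snp \
            else ld_r2(G, int(lead["vidx"]), snp)
        if not np.isnan(r2) and r2 >= ld_r2_min:
            ld_ok += 1
        y = c.phenotypes.iloc[:, 0].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n_samples), pcs[:, :2]])
        h2s.append(fit_null_reml(y, X, c.K).heritability)
    return PowerResult(n_replicates=n_replicates,
                       power=hits / n_replicates,
                       lead_in_ld=ld_ok / n_replicates, h2_estimates=h2s,
                       h2_true=float(h2_true), p_threshold=p_threshold)
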