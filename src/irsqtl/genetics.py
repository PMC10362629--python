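"""Genotype handling: VCF IO, variant filtering, kinship, PCA and LD.

Dosages are alt-allele counts in {0, 1, 2}; missing genotypes are NaN.
The kinship estimator is the standardized (allele-frequency scaled) genomic
relationship matrix, and population structure is summarized by the
eigendecomposition of that matrix, so the mixed-model scan downstream sees
the same relatedness structure that generated confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")


class GenotypeMatrix:
    """Variants x samples dosage matrix (alt-allele counts, NaN = missing)."""

    def __init__(self, samples: Sequence[str], variants: Sequence[Variant],
                 dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples")
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosages = dosages

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, over non-missing samples."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": [v.chrom for v in self.variants],
             "pos": [v.pos for v in self.variants],
             "ref": [v.ref for v in self.variants],
             "alt": [v.alt for v in self.variants],
             "id": [v.id for v in self.variants]})

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix([self.samples[i] for i in idx],
                              self.variants, self.dosages[:, idx])

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read GT dosages from a VCF 4.2 file (biallelic records only)."""
        from cyvcf2 import VCF

        reader = VCF(str(path))
        samples = list(reader.samples)
        variants: list[Variant] = []
        rows: list[np.ndarray] = []
        for rec in reader:
            if len(rec.ALT) != 1:
                warnings.warn(
                    f"skipping non-biallelic record {rec.CHROM}:{rec.POS}")
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types.astype(float)
            dos = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
            rows.append(dos)
            variants.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                                    rec.ID or "."))
        reader.close()
        dosages = (np.vstack(rows) if rows
                   else np.empty((0, len(samples))))
        return cls(samples, variants, dosages)

    def to_vcf(self, path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
        """Write a minimal VCF 4.2 with GT fields.

        Non-integer (imputed) dosages cannot be represented and raise.
        """
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            if contig_lengths:
                for chrom, length in contig_lengths.items():
                    fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                     "\t" + "\t".join(self.samples) + "\n")
            for var, row in zip(self.variants, self.dosages):
                calls = []
                for d in row:
                    if np.isnan(d):
                        calls.append("./.")
                    else:
                        if d != int(d):
                            raise ValueError(
                                "cannot write imputed (fractional) dosages "
                                "to VCF")
                        calls.append(gt_code[int(d)])
                fh.write(f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t"
                         f"{var.alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(calls) + "\n")


class KinshipMatrix:
    """Symmetric PSD relatedness matrix keyed by sample ids."""

    SYM_TOL = 1e-10
    PSD_TOL = -1e-8

    def __init__(self, samples: Sequence[str], values: np.ndarray,
                 check: bool = True):
        values = np.asarray(values, dtype=float)
        n = len(samples)
        if values.shape != (n, n):
            raise ValueError("kinship must be n x n")
        if check:
            if not np.allclose(values, values.T, atol=self.SYM_TOL, rtol=0):
                raise ValueError("kinship matrix is not symmetric")
            w = np.linalg.eigvalsh(values)
            if w.min() < self.PSD_TOL * max(1.0, w.max()):
                raise ValueError("kinship matrix is not PSD within tolerance")
        self.samples = list(samples)
        self.values = 0.5 * (values + values.T)

    @property
    def n(self) -> int:
        return len(self.samples)

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        return KinshipMatrix([self.samples[i] for i in idx],
                             self.values[np.ix_(idx, idx)], check=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.samples,
                     columns=self.samples).to_csv(path, sep="\t",
                                                  float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


@dataclass
class PCResult:
    """Principal components of the kinship matrix.

    ``scores`` are eigenvectors scaled by sqrt(eigenvalue); eigenvalues are
    descending and clipped at zero.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    samples: list[str] = field(default_factory=list)


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05,
                    missing_max: float = 0.2) -> GenotypeMatrix:
    """Keep variants with MAF > ``maf_min`` and missing rate < ``missing_max``.

    Both comparisons are strict, matching the usual GWAS convention of
    dropping MAF <= 5% and missingness >= 20%. Variant order is preserved.
    """
    keep = (G.maf() > maf_min) & (G.missing_rate() < missing_max)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(G.samples, [G.variants[i] for i in idx],
                          G.dosages[idx])


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean over observed samples."""
    dos = G.dosages.copy()
    miss = np.isnan(dos)
    if miss.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(dos, axis=1)
        means = np.where(np.isnan(means), 0.0, means)
        rows = np.nonzero(miss.any(axis=1))[0]
        for i in rows:
            dos[i, miss[i]] = means[i]
    return GenotypeMatrix(G.samples, G.variants, dos)


def kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Standardized (allele-frequency scaled) genomic relationship matrix.

    K = (1/m) sum_s (g_s - 2 p_s)(g_s - 2 p_s)^T / (2 p_s (1 - p_s)) over
    polymorphic variants; monomorphic variants are skipped with a warning.
    Requires complete dosages (``impute_mean`` first).
    """
    if np.isnan(G.dosages).any():
        raise ValueError("kinship requires imputed (complete) dosages")
    p = G.dosages.mean(axis=1) / 2.0
    poly = G.dosages.std(axis=1) > 0
    if not poly.all():
        warnings.warn(f"skipping {np.sum(~poly)} monomorphic variants "
                      "in kinship")
    if not poly.any():
        raise ValueError("no polymorphic variants for kinship")
    Z = ((G.dosages[poly] - 2.0 * p[poly, None])
         / np.sqrt(2.0 * p[poly, None] * (1.0 - p[poly, None])))
    K = Z.T @ Z / Z.shape[0]
    return KinshipMatrix(G.samples, K, check=False)


def pca(K: KinshipMatrix, k: int) -> PCResult:
    """Top-k principal components of the kinship matrix.

    Deterministic sign convention: in each component the loading of largest
    magnitude is made positive.
    """
    if k > K.n:
        raise ValueError("k cannot exceed the number of samples")
    w, V = np.linalg.eigh(K.values)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = V[:, :k] * np.sqrt(w[:k])
    return PCResult(scores=scores, eigenvalues=w[:k], samples=list(K.samples))


def ld_r2(G: GenotypeMatrix, a: int, b: int) -> float:
    """Squared Pearson correlation of dosages at variants ``a`` and ``b``.

    Computed over samples non-missing at both; NaN when either variant has
    zero variance on that sample set.
    """
    x, y = G.dosages[a], G.dosages[b]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 for a (variants x samples) block (no missing).

    Zero-variance variants yield NaN rows/columns.
    """
    X = np.asarray(dosages, dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        R = Z @ Z.T / X.shape[1]
    R2 = R * R
    bad = sd == 0
    R2[bad, :] = np.nan
    R2[:, bad] = np.nan
    return R2
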