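"""Intron clusters, percent-spliced-in (PSI) and the event filter cascade.

A splice junction records, per sample, how many reads support excision of
one intron. Introns that share a donor or acceptor coordinate form a
cluster; the cluster's total junction count is the denominator of PSI, so
PSI(i, s) = n_i(s) / sum_j n_j(s) is the fraction of the cluster's splicing
evidence supporting excision of intron i in sample s. A PSI of 0 means the
intron was never observed spliced out (fully retained); PSI values within a
cluster sum to 1 per sample.

Coordinate convention: ``start`` is the 1-based first intronic base and
``end - start`` is the intron length in bp (so ``end`` is the first base of
the downstream exon). Event ids render as "chrom:start:end" and, once
clustered, "chrom:start:end:clu_K".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class IntronJunction:
    chrom: str
    start: int
    end: int
    strand: str = "?"
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"junction end must exceed start: {self.chrom}:{self.start}:"
                f"{self.end}")
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("junction counts must be non-negative")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntronCluster:
    cluster_id: str
    members: list[IntronJunction]

    def __len__(self) -> int:
        return len(self.members)


def cluster_introns(junctions: Sequence[IntronJunction]) -> list[IntronCluster]:
    """Group introns into clusters connected by shared splice coordinates.

    Two introns join the same cluster iff they are linked by a chain of
    shared start or shared end coordinates on the same chromosome. Cluster
    ids ``clu_1..clu_N`` are assigned in coordinate order of each cluster's
    leftmost member, so the labelling is deterministic.
    """
    ids = [j.id for j in junctions]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise ValueError("duplicate junction rows: "
                         + ", ".join(dup[dup > 1].index[:5]))
    g = nx.Graph()
    g.add_nodes_from(range(len(junctions)))
    by_coord: dict[tuple, int] = {}
    for i, j in enumerate(junctions):
        for key in ((j.chrom, "s", j.start), (j.chrom, "e", j.end)):
            if key in by_coord:
                g.add_edge(by_coord[key], i)
            else:
                by_coord[key] = i
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min((junctions[i].chrom, junctions[i].start,
                                  junctions[i].end) for i in c))
    out = []
    for k, comp in enumerate(comps, start=1):
        members = sorted((junctions[i] for i in comp),
                         key=lambda j: (j.chrom, j.start, j.end))
        out.append(IntronCluster(cluster_id=f"clu_{k}", members=members))
    return out


class PsiMatrix:
    """Events x samples PSI values with per-event metadata and raw counts.

    ``values``: DataFrame in [0, 1] (NaN where the cluster depth fell below
    the missingness threshold); ``meta``: per-event chrom/start/end/cluster/
    length/gene; ``counts``: the raw junction counts on the same index.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame,
                 counts: pd.DataFrame | None = None):
        if not values.index.equals(meta.index):
            raise ValueError("values and meta must share an index")
        bad = values.to_numpy()
        if np.nanmin(bad, initial=0.0) < -1e-12 or \
                np.nanmax(bad, initial=0.0) > 1 + 1e-12:
            raise ValueError("PSI values must lie in [0, 1]")
        self.values = values
        self.meta = meta
        self.counts = counts

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, event_ids: Iterable[str]) -> "PsiMatrix":
        idx = list(event_ids)
        return PsiMatrix(self.values.loc[idx], self.meta.loc[idx],
                         None if self.counts is None else
                         self.counts.loc[idx])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g",
                           index_label="event_id")


def compute_psi(cluster: IntronCluster, samples: Sequence[str],
                min_cluster_depth: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSI rows for one cluster: per-sample count over cluster total.

    Entries are missing where the cluster's total junction count in that
    sample is below ``min_cluster_depth``; per sample the non-missing PSI
    values of a cluster sum to 1.
    """
    if min_cluster_depth < 1:
        raise ValueError("min_cluster_depth must be >= 1")
    counts = np.vstack([j.counts for j in cluster.members]).astype(float)
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = counts / total
    psi[:, total < min_cluster_depth] = np.nan
    ids = [f"{j.id}:{cluster.cluster_id}" for j in cluster.members]
    values = pd.DataFrame(psi, index=ids, columns=list(samples))
    meta = pd.DataFrame(
        {"chrom": [j.chrom for j in cluster.members],
         "start": [j.start for j in cluster.members],
         "end": [j.end for j in cluster.members],
         "strand": [j.strand for j in cluster.members],
         "cluster": cluster.cluster_id,
         "length": [j.length for j in cluster.members]}, index=ids)
    return values, meta


def build_psi_matrix(junctions: Sequence[IntronJunction],
                     samples: Sequence[str],
                     min_cluster_depth: int = 5,
                     drop_singletons: bool = True) -> PsiMatrix:
    """Cluster junctions and assemble the full PSI matrix.

    Single-intron clusters carry no splicing ratio signal (their PSI is
    identically 1 wherever observed) and are dropped by default.
    """
    clusters = cluster_introns(junctions)
    vals, metas, cnts = [], [], []
    for cl in clusters:
        if drop_singletons and len(cl) < 2:
            continue
        v, m = compute_psi(cl, samples, min_cluster_depth)
        vals.append(v)
        metas.append(m)
        cnts.append(pd.DataFrame(
            np.vstack([j.counts for j in cl.members]),
            index=v.index, columns=list(samples)))
    if not vals:
        empty = pd.DataFrame(columns=list(samples))
        return PsiMatrix(empty, pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "cluster", "length"]),
            empty.copy())
    return PsiMatrix(pd.concat(vals), pd.concat(metas), pd.concat(cnts))


def assign_events_to_genes(psi: PsiMatrix,
                           gene_spans: pd.DataFrame) -> pd.Series:
    """Map each event to the gene whose span fully contains the intron.

    ``gene_spans``: columns gene_id, chrom, start, end (1-based inclusive).
    Containment is strand-agnostic; when several genes contain the intron
    the smallest span wins (ties by gene_id, deterministic); events
    contained by no gene map to NaN.
    """
    spans = gene_spans.sort_values(
        ["chrom", "start", "end"]).reset_index(drop=True)
    out = {}
    by_chrom = {c: s for c, s in spans.groupby("chrom")}
    for event_id, row in psi.meta.iterrows():
        sub = by_chrom.get(row["chrom"])
        gene = np.nan
        if sub is not None:
            # intron occupies [start, end-1]
            hit = sub[(sub["start"] <= row["start"])
                      & (sub["end"] >= row["end"] - 1)]
            if len(hit):
                widths = hit["end"] - hit["start"]
                hit = hit.assign(w=widths).sort_values(["w", "gene_id"])
                gene = hit.iloc[0]["gene_id"]
        out[event_id] = gene
    return pd.Series(out, name="gene")


DEFAULT_FILTER_PARAMS = {
    "junction_min_reads": 5,
    "junction_min_fraction": 0.25,
    "fpkm_min": 1.0,
    "fpkm_fraction": 0.95,
    "cv_min": 0.1,
    "sd_min": 0.1,
    "intron_max_len": 5000,
}


def filter_events(psi: PsiMatrix, expr: pd.DataFrame, gene_map: pd.Series,
                  params: dict | None = None,
                  ) -> tuple[PsiMatrix, dict[str, int]]:
    """Apply the four-rule event filter, returning survivors and attrition.

    Rules, applied as a sequential cascade (each counted on the events that
    survived the previous rules):

    1. junction support: raw junction count >= junction_min_reads in at
       least junction_min_fraction of samples;
    2. host gene mapped, and highly expressed: FPKM >= fpkm_min in at least
       fpkm_fraction of samples;
    3. PSI variation: coefficient of variation > cv_min AND standard
       deviation > sd_min over non-missing samples (events with mean PSI 0
       have undefined CV and fail);
    4. intron length < intron_max_len bp.

    SD uses the population (ddof=0) convention. Filtering is idempotent:
    survivors re-filtered with the same parameters all survive.
    """
    p = dict(DEFAULT_FILTER_PARAMS)
    if params:
        p.update(params)
    report = {"events_in": len(psi.event_ids)}
    ids = np.array(psi.event_ids)

    counts = psi.counts.to_numpy()
    support = (np.mean(counts >= p["junction_min_reads"], axis=1)
               >= p["junction_min_fraction"])
    report["removed_low_support"] = int(np.sum(~support))
    keep = support

    genes = gene_map.reindex(ids).to_numpy(dtype=object)
    mapped = pd.notna(genes)
    report["removed_unmapped_gene"] = int(np.sum(keep & ~mapped))
    keep = keep & mapped

    expr_frac = (expr.reindex(
        [g if isinstance(g, str) else "" for g in genes])
        .to_numpy(dtype=float) >= p["fpkm_min"])
    expressed = np.zeros(len(ids), dtype=bool)
    expressed[mapped] = (expr_frac[mapped].mean(axis=1)
                         >= p["fpkm_fraction"])
    report["removed_low_expression"] = int(np.sum(keep & ~expressed))
    keep = keep & expressed

    vals = psi.values.to_numpy()
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1)
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    varying = (np.nan_to_num(cv) > p["cv_min"]) & (sd > p["sd_min"])
    report["removed_low_variation"] = int(np.sum(keep & ~varying))
    keep = keep & varying

    lengths = psi.meta["length"].to_numpy()
    short = lengths < p["intron_max_len"]
    report["removed_long_intron"] = int(np.sum(keep & ~short))
    keep = keep & short

    report["events_out"] = int(keep.sum())
    surv = psi.subset(list(ids[keep]))
    surv.meta = surv.meta.assign(gene=gene_map.reindex(surv.event_ids))
    return surv, report


# ---------------------------------------------------------------------------
# Junction table IO
# ---------------------------------------------------------------------------

def read_junction_table(path: str | Path,
                        ) -> tuple[list[IntronJunction], list[str]]:
    """Read a junction TSV: chrom, start, end, strand[, cluster], samples..."""
    df = pd.read_csv(path, sep="\t")
    fixed = [c for c in ("chrom", "start", "end", "strand", "cluster")
             if c in df.columns]
    samples = [c for c in df.columns if c not in fixed]
    junctions = [
        IntronJunction(chrom=str(r["chrom"]), start=int(r["start"]),
                       end=int(r["end"]), strand=str(r.get("strand", "?")),
                       counts=np.array([int(r[s]) for s in samples]))
        for _, r in df.iterrows()]
    return junctions, samples


def write_junction_table(junctions: Sequence[IntronJunction],
                         samples: Sequence[str], path: str | Path,
                         clusters: Sequence[str] | None = None) -> None:
    rows = []
    for i, j in enumerate(junctions):
        row = {"chrom": j.chrom, "start": j.start, "end": j.end,
               "strand": j.strand}
        if clusters is not None:
            row["cluster"] = clusters[i]
        row.update({s: int(c) for s, c in zip(samples, j.counts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
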