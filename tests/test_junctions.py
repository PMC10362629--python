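"""Intron clustering, PSI arithmetic, and the event filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsqtl.junctions import (IntronJunction, PsiMatrix, build_psi_matrix,
                              assign_events_to_genes, cluster_introns,
                              compute_psi, filter_events,
                              read_junction_table, write_junction_table)
from irsqtl.synthetic import CohortConfig, generate_cohort, resample_counts


def _j(chrom, start, end, counts=(1,)):
    return IntronJunction(chrom=chrom, start=start, end=end,
                          counts=np.asarray(counts))


class _UnionFind:
    """Independent clustering oracle over the shared-coordinate graph."""

    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        self.p[self.find(a)] = self.find(b)


def _oracle_components(junctions):
    uf = _UnionFind(len(junctions))
    for i, a in enumerate(junctions):
        for k, b in enumerate(junctions[:i]):
            if a.chrom == b.chrom and (a.start == b.start or a.end == b.end):
                uf.union(i, k)
    comps = {}
    for i in range(len(junctions)):
        comps.setdefault(uf.find(i), set()).add(junctions[i].id)
    return sorted(tuple(sorted(c)) for c in comps.values())


class TestClustering:
    def test_shared_donor_forms_one_cluster(self):
        cl = cluster_introns([_j("c", 100, 200), _j("c", 100, 300)])
        assert len(cl) == 1 and len(cl[0]) == 2

    def test_disjoint_coordinates_stay_separate(self):
        cl = cluster_introns([_j("c", 100, 200), _j("c", 150, 300)])
        assert len(cl) == 2 and all(len(c) == 1 for c in cl)

    def test_chain_linkage_merges_transitively(self):
        js = [_j("c", 100, 200), _j("c", 100, 300), _j("c", 250, 300),
              _j("c", 250, 400)]
        cl = cluster_introns(js)
        assert len(cl) == 1 and len(cl[0]) == 4
        assert _oracle_components(js) == [
            tuple(sorted(j.id for j in js))]

    def test_same_coordinates_different_chrom_do_not_link(self):
        cl = cluster_introns([_j("c1", 100, 200), _j("c2", 100, 200)])
        assert len(cl) == 2

    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cluster_introns([_j("c", 100, 200), _j("c", 100, 200)])

    def test_cluster_ids_deterministic_in_coordinate_order(self):
        js = [_j("c", 500, 600), _j("c", 100, 200), _j("c", 100, 250)]
        cl = cluster_introns(js)
        assert [c.cluster_id for c in cl] == ["clu_1", "clu_2"]
        assert cl[0].members[0].start == 100

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["c1", "c2"]),
                              st.integers(1, 30), st.integers(1, 30)),
                    min_size=1, max_size=25, unique=True))
    def test_matches_union_find_oracle(self, coords):
        js = [_j(c, s, s + ln) for c, s, ln in coords]
        got = sorted(tuple(sorted(j.id for j in c.members))
                     for c in cluster_introns(js))
        assert got == _oracle_components(js)


class TestPsi:
    def test_zero_count_means_fully_retained(self):
        cl = cluster_introns([_j("c", 100, 200, [0]), _j("c", 100, 300, [40])])
        vals, _ = compute_psi(cl[0], ["s1"])
        assert vals.iloc[0, 0] == 0.0 and vals.iloc[1, 0] == 1.0

    def test_simple_ratio(self):
        cl = cluster_introns([_j("c", 100, 200, [10]),
                              _j("c", 100, 300, [30])])
        vals, _ = compute_psi(cl[0], ["s1"])
        assert vals.iloc[0, 0] == 0.25 and vals.iloc[1, 0] == 0.75

    def test_low_depth_becomes_missing(self):
        cl = cluster_introns([_j("c", 100, 200, [1, 3]),
                              _j("c", 100, 300, [3, 10])])
        vals, _ = compute_psi(cl[0], ["s1", "s2"], min_cluster_depth=5)
        assert np.isnan(vals.iloc[0, 0]) and vals.iloc[0, 1] == 3 / 13

    def test_random_clusters_match_long_division(self, rng):
        """100 random clusters against independent per-sample division."""
        for _ in range(100):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(2, 8))
            counts = rng.integers(0, 50, size=(k, n))
            js = [_j("c", 100, 200 + 10 * i, counts[i]) for i in range(k)]
            cl = cluster_introns(js)
            assert len(cl) == 1
            vals, _ = compute_psi(cl[0], [f"s{i}" for i in range(n)],
                                  min_cluster_depth=1)
            total = counts.sum(axis=0)
            for i in range(k):
                for s in range(n):
                    expect = (counts[i, s] / total[s] if total[s] >= 1
                              else np.nan)
                    got = vals.iloc[i, s]
                    assert (np.isnan(got) and np.isnan(expect)) \
                        or got == expect
            sums = vals.sum(axis=0, skipna=False).to_numpy()
            assert np.allclose(sums[total >= 1], 1.0)

    def test_cluster_row_sums_conserved(self, small_cohort):
        psi = build_psi_matrix(small_cohort.junctions, small_cohort.samples)
        for _, grp in psi.values.groupby(psi.meta["cluster"]):
            sums = grp.sum(axis=0, skipna=False).to_numpy()
            ok = ~np.isnan(sums)
            assert np.allclose(sums[ok], 1.0)

    def test_high_depth_estimates_track_true_psi(self):
        cfg = CohortConfig(n_samples=40, n_snps=100, n_clusters=10,
                           n_extra_genes=0, mean_cluster_depth=2000,
                           seed=5)
        c = generate_cohort(cfg)
        psi = build_psi_matrix(c.junctions, c.samples)
        for ev in c.truth.focal_events:
            est = psi.values.loc[ev].to_numpy(dtype=float)
            true = c.true_psi.loc[ev].to_numpy(dtype=float)
            ok = ~np.isnan(est)
            assert np.corrcoef(est[ok], true[ok])[0, 1] > 0.95

    def test_replicates_correlate_more_than_distinct_samples(self):
        """Technical replicates share true PSI, so their profiles agree
        better than profiles of different accessions."""
        cfg = CohortConfig(n_samples=30, n_snps=100, n_clusters=40,
                           n_extra_genes=0, seed=9)
        c = generate_cohort(cfg)
        rep = resample_counts(c, seed=1234)
        p1 = build_psi_matrix(c.junctions, c.samples).values.to_numpy()
        p2 = build_psi_matrix(rep, c.samples).values.to_numpy()
        same, diff = [], []
        for s in range(10):
            ok = ~(np.isnan(p1[:, s]) | np.isnan(p2[:, s]))
            same.append(np.corrcoef(p1[ok, s], p2[ok, s])[0, 1])
            t = (s + 7) % 30
            ok = ~(np.isnan(p1[:, s]) | np.isnan(p1[:, t]))
            diff.append(np.corrcoef(p1[ok, s], p1[ok, t])[0, 1])
        assert np.mean(same) > np.mean(diff)


def _fixture_psi():
    """10 events with hand-chosen failures of each filter rule."""
    n = 40
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(n)]
    ids = [f"c:{100 * (i + 1)}:{100 * (i + 1) + 80}:clu_{i + 1}"
           for i in range(10)]
    base = np.clip(rng.uniform(0.2, 0.8, (10, n)), 0, 1)  # sd ~ 0.17, ok
    values = base.copy()
    values[2] = 0.5 + rng.normal(0, 0.01, n)     # low sd -> rule (ii)
    values[3] = 0.0                              # mean 0: CV undefined, fails
    counts = np.full((10, n), 20)
    counts[1] = 2                                 # low support -> rule (i)
    meta = pd.DataFrame({
        "chrom": "c", "start": [100 * (i + 1) for i in range(10)],
        "end": [100 * (i + 1) + 80 for i in range(10)],
        "strand": "?", "cluster": [f"clu_{i + 1}" for i in range(10)],
        "length": [80] * 10}, index=ids)
    meta.loc[ids[4], "length"] = 6000             # long intron -> rule (iii)
    meta.loc[ids[5], "length"] = 5000             # boundary: not < 5000
    gene_map = pd.Series({i: "G1" for i in ids})
    gene_map[ids[6]] = np.nan                     # unmapped
    gene_map[ids[7]] = "G2"                       # lowly expressed gene
    expr = pd.DataFrame(
        {s: {"G1": 10.0, "G2": 0.5} for s in samples})
    psi = PsiMatrix(pd.DataFrame(values, index=ids, columns=samples), meta,
                    pd.DataFrame(counts, index=ids, columns=samples))
    expected_survivors = {ids[0], ids[8], ids[9]}
    return psi, expr, gene_map, expected_survivors


class TestFilter:
    def test_fixture_matches_hand_enumeration(self):
        psi, expr, gene_map, expected = _fixture_psi()
        out, report = filter_events(psi, expr, gene_map)
        assert set(out.event_ids) == expected
        assert report["events_in"] == 10
        assert report["events_out"] == 3
        assert report["removed_low_support"] == 1
        assert report["removed_unmapped_gene"] == 1
        assert report["removed_low_expression"] == 1
        assert report["removed_low_variation"] == 2
        assert report["removed_long_intron"] == 2
        removed = sum(v for k, v in report.items()
                      if k.startswith("removed"))
        assert report["events_in"] - removed == report["events_out"]

    def test_low_sd_event_dropped(self):
        psi, expr, gene_map, _ = _fixture_psi()
        out, _ = filter_events(psi, expr, gene_map)
        low_sd = psi.event_ids[2]
        assert np.nanstd(psi.values.loc[low_sd]) < 0.1
        assert low_sd not in out.event_ids

    def test_long_intron_dropped_strictly_below_5000(self):
        psi, expr, gene_map, _ = _fixture_psi()
        out, _ = filter_events(psi, expr, gene_map)
        assert psi.event_ids[4] not in out.event_ids   # 6000 bp
        assert psi.event_ids[5] not in out.event_ids   # exactly 5000 bp

    def test_filtering_is_idempotent(self):
        psi, expr, gene_map, _ = _fixture_psi()
        once, _ = filter_events(psi, expr, gene_map)
        twice, rep = filter_events(once, expr, gene_map)
        assert list(once.event_ids) == list(twice.event_ids)
        assert rep["events_in"] == rep["events_out"]


class TestGeneAssignment:
    spans = pd.DataFrame({
        "gene_id": ["Gbig", "Gsmall", "Gfar"],
        "chrom": ["c", "c", "c"],
        "start": [50, 90, 5000],
        "end": [1000, 400, 6000]})

    def _psi_for(self, start, end):
        ids = [f"c:{start}:{end}:clu_1"]
        meta = pd.DataFrame({"chrom": "c", "start": start, "end": end,
                             "strand": "?", "cluster": "clu_1",
                             "length": end - start}, index=ids)
        vals = pd.DataFrame([[0.5]], index=ids, columns=["s1"])
        return PsiMatrix(vals, meta)

    def test_single_containing_gene(self):
        gm = assign_events_to_genes(self._psi_for(500, 600), self.spans)
        assert gm.iloc[0] == "Gbig"

    def test_no_containing_gene_is_unmapped(self):
        gm = assign_events_to_genes(self._psi_for(2000, 2100), self.spans)
        assert pd.isna(gm.iloc[0])

    def test_nested_genes_pick_smallest(self):
        gm = assign_events_to_genes(self._psi_for(100, 200), self.spans)
        assert gm.iloc[0] == "Gsmall"


class TestIO:
    def test_junction_table_roundtrip(self, tmp_path, small_cohort):
        path = tmp_path / "j.tsv"
        write_junction_table(small_cohort.junctions, small_cohort.samples,
                             path, clusters=small_cohort.junction_clusters)
        back, samples = read_junction_table(path)
        assert samples == small_cohort.samples
        assert [j.id for j in back] == [j.id for j in small_cohort.junctions]
        path2 = tmp_path / "j2.tsv"
        write_junction_table(back, samples, path2,
                             clusters=small_cohort.junction_clusters)
        assert path.read_bytes() == path2.read_bytes()
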