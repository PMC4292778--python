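"""Triangle integration, peak-region chaining, candidate filters, cis flags."""

import numpy as np
import pandas as pd
import pytest

from pgx_triangulate.integration import (
    PeakRegion, TriangleThresholds, annotate_cis, find_peak_regions,
    hits_frame, regions_to_bed, select_expression_candidates, triangle_scan,
)


def _edge(ids, ps, rs=None):
    rs = rs if rs is not None else [0.25] * len(ids)
    return pd.DataFrame({"id_a": ids, "p": ps, "r": rs})


def _pair_edge(pairs, ps):
    return pd.DataFrame(
        {"id_a": [a for a, _ in pairs], "id_b": [b for _, b in pairs],
         "p": ps, "r": [0.3] * len(pairs)}
    )


# ---------------------------------------------------------------------------
# triangle scan
# ---------------------------------------------------------------------------

def test_single_planted_chain_is_recovered_exactly():
    snp_auc = _edge(["snp_1", "snp_2"], [1e-6, 0.3])
    expr_auc = _edge(["probe_1", "probe_2"], [1e-5, 0.5])
    snp_expr = _pair_edge(
        [("snp_1", "probe_1"), ("snp_1", "probe_2"), ("snp_2", "probe_1")],
        [1e-8, 0.2, 0.4],
    )
    hits, n_unique = triangle_scan(snp_auc, snp_expr, expr_auc)
    assert len(hits) == 1 and n_unique == 1
    h = hits[0]
    assert (h.snp_id, h.probe_id) == ("snp_1", "probe_1")
    assert h.p_snp_auc == 1e-6 and h.p_snp_expr == 1e-8 and h.p_expr_auc == 1e-5


def test_zero_thresholds_give_empty_result():
    snp_auc = _edge(["snp_1"], [1e-10])
    expr_auc = _edge(["probe_1"], [1e-10])
    snp_expr = _pair_edge([("snp_1", "probe_1")], [1e-10])
    hits, n = triangle_scan(snp_auc, snp_expr, expr_auc,
                            TriangleThresholds(0.0, 0.0, 0.0))
    assert hits == [] and n == 0


def test_failing_expr_auc_edge_excludes_triangle():
    """snp~auc and snp~expr pass but expr~auc = 0.01 > 1e-3: excluded."""
    snp_auc = _edge(["snp_1"], [1e-6])
    expr_auc = _edge(["probe_1"], [0.01])
    snp_expr = _pair_edge([("snp_1", "probe_1")], [1e-8])
    hits, _ = triangle_scan(snp_auc, snp_expr, expr_auc)
    assert hits == []


def test_missing_edge_table_is_configuration_error():
    with pytest.raises(ValueError, match="snp_expr"):
        triangle_scan(_edge(["s"], [0.1]), None, _edge(["p"], [0.1]))


def test_triangles_are_subset_of_each_edge_set_and_monotone(rng):
    n_snp, n_probe = 40, 20
    snp_ids = [f"s{i}" for i in range(n_snp)]
    probe_ids = [f"p{i}" for i in range(n_probe)]
    snp_auc = _edge(snp_ids, rng.uniform(size=n_snp) ** 3)
    expr_auc = _edge(probe_ids, rng.uniform(size=n_probe) ** 3)
    pairs = [(s, p) for s in snp_ids for p in probe_ids]
    snp_expr = _pair_edge(pairs, rng.uniform(size=len(pairs)) ** 3)
    thr = TriangleThresholds(0.05, 0.05, 0.1)
    hits, _ = triangle_scan(snp_auc, snp_expr, expr_auc, thr)
    sa = set(snp_auc[snp_auc.p < thr.snp_auc].id_a)
    ea = set(expr_auc[expr_auc.p < thr.expr_auc].id_a)
    for h in hits:
        assert h.snp_id in sa and h.probe_id in ea
    # loosening every threshold never loses a hit
    loose, _ = triangle_scan(snp_auc, snp_expr, expr_auc,
                             TriangleThresholds(0.1, 0.1, 0.2))
    tight_keys = {(h.snp_id, h.probe_id) for h in hits}
    loose_keys = {(h.snp_id, h.probe_id) for h in loose}
    assert tight_keys <= loose_keys


# ---------------------------------------------------------------------------
# peak regions
# ---------------------------------------------------------------------------

def _snp_auc_table(rows):
    return pd.DataFrame(rows, columns=["id_a", "chrom", "pos", "p"])


def test_peak_region_hand_traced_chaining():
    """chr1:100 + chr1:40,100 chain (40 kb gap); chr1:200,000 stays alone."""
    tbl = _snp_auc_table([
        ("a", "1", 100, 1e-5), ("b", "1", 40_100, 5e-5),
        ("c", "1", 200_000, 1e-6), ("d", "1", 300_000, 0.5),
    ])
    regions = find_peak_regions(tbl)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.snp_ids) == (100, 40_100, ["a", "b"])
    assert r.min_p == 1e-5


def test_no_qualifying_snps_gives_no_regions():
    tbl = _snp_auc_table([("a", "1", 100, 0.5), ("b", "1", 200, 0.01)])
    assert find_peak_regions(tbl) == []


def test_gap_boundary_is_inclusive():
    """Spacings of exactly 50,000 bp chain all three SNPs into one region."""
    tbl = _snp_auc_table([
        ("a", "2", 1, 1e-5), ("b", "2", 50_001, 1e-5), ("c", "2", 100_001, 1e-5),
    ])
    regions = find_peak_regions(tbl)
    assert len(regions) == 1 and regions[0].n_snps == 3


def test_unsorted_positions_rejected():
    tbl = _snp_auc_table([("a", "1", 500, 1e-5), ("b", "1", 100, 1e-5)])
    with pytest.raises(ValueError, match="unsorted"):
        find_peak_regions(tbl)


def _oracle_regions(tbl, p_max=1e-4, gap=50_000, min_snps=2):
    """O(n^2) pair-merging oracle: union-find over qualifying SNP pairs."""
    out = []
    for chrom, grp in tbl.groupby("chrom"):
        q = grp[grp.p < p_max].reset_index(drop=True)
        n = len(q)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                # single linkage: any chain of <= gap steps merges, so only
                # adjacent-in-position pairs need direct edges
                between = q[(q.pos > min(q.pos[i], q.pos[j]))
                            & (q.pos < max(q.pos[i], q.pos[j]))]
                if between.empty and abs(q.pos[i] - q.pos[j]) <= gap:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            if len(members) >= min_snps:
                pos = sorted(q.pos[m] for m in members)
                out.append((str(chrom), pos[0], pos[-1], len(members)))
    return sorted(out)


def test_region_calling_matches_quadratic_oracle(rng):
    for trial in range(10):
        n = 80
        pos = np.sort(rng.integers(1, 2_000_000, size=n))
        tbl = _snp_auc_table([
            (f"s{i}", str(rng.integers(1, 3)), int(pos[i]),
             float(rng.uniform() ** 4)) for i in range(n)
        ]).sort_values(["chrom", "pos"], ignore_index=True)
        regions = find_peak_regions(tbl, p_max=0.05)
        got = sorted((r.chrom, r.start, r.end, r.n_snps) for r in regions)
        assert got == _oracle_regions(tbl, p_max=0.05)


def test_regions_partition_their_members(rng):
    pos = np.arange(1, 600) * 20_000
    tbl = _snp_auc_table([
        (f"s{i}", "1", int(p), float(rng.uniform() ** 5))
        for i, p in enumerate(pos)
    ])
    regions = find_peak_regions(tbl)
    seen = set()
    for r in regions:
        assert len(set(r.snp_ids) & seen) == 0
        seen |= set(r.snp_ids)


def test_bed_conversion_is_zero_based_half_open():
    regions = [PeakRegion("7", 100, 500, ["a", "b"], 1e-6)]
    bed = regions_to_bed(regions)
    assert bed.loc[0, "start"] == 99 and bed.loc[0, "end"] == 500
    assert bed.loc[0, "end"] - bed.loc[0, "start"] == 500 - 100 + 1


# ---------------------------------------------------------------------------
# expression candidates
# ---------------------------------------------------------------------------

def _linear_matrix(levels):
    return pd.DataFrame(
        {f"S{j}": levels for j in range(4)},
        index=pd.Index([f"p{i}" for i in range(len(levels))], name="probe_id"),
    )


def test_strong_probe_with_high_expression_is_retained():
    expr_auc = _edge(["p0"], [6.24e-6], rs=[-0.27])
    linear = _linear_matrix([400.0])
    out = select_expression_candidates(expr_auc, linear)
    assert list(out.probe_id) == ["p0"]
    assert out.loc[0, "median_expr"] == 400.0


def test_low_expression_probe_removed_despite_tiny_p():
    expr_auc = _edge(["p0"], [1e-6])
    out = select_expression_candidates(expr_auc, _linear_matrix([10.0]))
    assert out.empty


def test_candidates_match_brute_force_filter(rng):
    n = 10
    ps = [1e-6, 1e-5, 5e-5, 0.2, 0.3, 1e-6, 0.5, 0.9, 2e-5, 0.7]
    levels = [400, 300, 10, 500, 600, 90, 20, 30, 200, 100]
    expr_auc = _edge([f"p{i}" for i in range(n)], ps)
    linear = _linear_matrix([float(v) for v in levels])
    out = select_expression_candidates(expr_auc, linear)
    oracle = {
        f"p{i}" for i in range(n) if ps[i] < 1e-4 and levels[i] >= 50
    }
    assert set(out.probe_id) == oracle == {"p0", "p1", "p5", "p8"}


def test_probe_missing_from_matrix_is_hard_error():
    expr_auc = _edge(["ghost"], [1e-6])
    with pytest.raises(KeyError, match="ghost"):
        select_expression_candidates(expr_auc, _linear_matrix([100.0]))


def test_candidates_grouped_by_gene():
    expr_auc = _edge(["p0", "p1"], [1e-6, 2e-6])
    linear = _linear_matrix([100.0, 100.0])
    gene_map = pd.DataFrame({"probe_id": ["p0", "p1"], "gene": ["GENEA", "GENEA"]})
    out = select_expression_candidates(expr_auc, linear, probe_gene_map=gene_map)
    assert list(out.gene) == ["GENEA", "GENEA"]


# ---------------------------------------------------------------------------
# cis annotation
# ---------------------------------------------------------------------------

def _hit(snp="s1", probe="p1"):
    from pgx_triangulate.integration import TriangleHit
    return TriangleHit(snp, probe, 1e-5, 1e-5, 1e-4, 0.3, 0.3, 0.3)


def test_cis_within_window():
    snps = pd.DataFrame({"snp_id": ["s1"], "chrom": ["1"], "pos": [1_500_000]})
    pmap = pd.DataFrame({"probe_id": ["p1"], "chrom": ["1"],
                         "start": [2_000_000], "end": [2_020_000]})
    (h,) = annotate_cis([_hit()], snps, pmap, window=1_000_000)
    assert h.cis_flag == "cis"  # 500 kb away, window 1 Mb


def test_trans_on_other_chromosome():
    snps = pd.DataFrame({"snp_id": ["s1"], "chrom": ["2"], "pos": [2_000_000]})
    pmap = pd.DataFrame({"probe_id": ["p1"], "chrom": ["1"],
                         "start": [2_000_000], "end": [2_020_000]})
    (h,) = annotate_cis([_hit()], snps, pmap)
    assert h.cis_flag == "trans"


def test_unmapped_probe_stays_unknown():
    snps = pd.DataFrame({"snp_id": ["s1"], "chrom": ["1"], "pos": [100]})
    pmap = pd.DataFrame({"probe_id": ["other"], "chrom": ["1"],
                         "start": [1], "end": [2]})
    (h,) = annotate_cis([_hit()], snps, pmap)
    assert h.cis_flag == "unknown"
    (h2,) = annotate_cis([_hit()], snps, None)
    assert h2.cis_flag == "unknown"


def test_hits_frame_columns():
    df = hits_frame([_hit()])
    assert list(df.columns)[:2] == ["snp_id", "probe_id"]
    assert df.loc[0, "cis_flag"] == "unknown"
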