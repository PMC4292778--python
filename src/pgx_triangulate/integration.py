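"""Triangle integration, SNP peak-region calling and candidate selection.

The integrated ("triangle") analysis requires a SNP–probe pair to pass three
association thresholds simultaneously: SNP with drug AUC (default p < 1e-4),
SNP with the probe's expression (p < 1e-4), and that expression with AUC
(p < 1e-3).  Peak regions chain AUC-associated SNPs (p < 1e-4) along a
chromosome with single linkage at an inter-SNP gap of <= 50 kb, keeping
chains of at least two members.  Expression candidates additionally require
the probe not to be low-expressed on the linear scale (median < 50 removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TriangleThresholds",
    "TriangleHit",
    "PeakRegion",
    "triangle_scan",
    "find_peak_regions",
    "select_expression_candidates",
    "annotate_cis",
    "regions_to_bed",
]


@dataclass(frozen=True)
class TriangleThresholds:
    snp_auc: float = 1e-4
    snp_expr: float = 1e-4
    expr_auc: float = 1e-3


@dataclass
class TriangleHit:
    """A SNP–gene–AUC triple passing all three association thresholds."""

    snp_id: str
    probe_id: str
    p_snp_auc: float
    p_snp_expr: float
    p_expr_auc: float
    r_snp_auc: float
    r_snp_expr: float
    r_expr_auc: float
    cis_flag: str = "unknown"  # cis | trans | unknown


@dataclass
class PeakRegion:
    """Cluster of >= min_snps AUC-associated SNPs within the gap distance."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    snp_ids: list[str] = field(default_factory=list)
    min_p: float = np.nan

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def triangle_scan(
    snp_auc: pd.DataFrame,
    snp_expr: pd.DataFrame,
    expr_auc: pd.DataFrame,
    thresholds: TriangleThresholds | None = None,
) -> tuple[list[TriangleHit], int]:
    """All (SNP, probe) pairs passing the three edge thresholds.

    ``snp_auc``: columns id_a(=snp), p, r; ``expr_auc``: id_a(=probe), p, r;
    ``snp_expr``: id_a(=snp), id_b(=probe), p, r.  Returns hits ordered by
    (p_snp_auc, snp_id, probe_id) plus the count of unique SNPs across hits.
    """
    thr = thresholds or TriangleThresholds()
    for name, tbl in (("snp_auc", snp_auc), ("snp_expr", snp_expr),
                      ("expr_auc", expr_auc)):
        if tbl is None:
            raise ValueError(f"missing edge table: {name}")

    sa = snp_auc[snp_auc["p"] < thr.snp_auc].set_index("id_a")
    ea = expr_auc[expr_auc["p"] < thr.expr_auc].set_index("id_a")
    se = snp_expr[
        snp_expr["p"].lt(thr.snp_expr)
        & snp_expr["id_a"].isin(sa.index)
        & snp_expr["id_b"].isin(ea.index)
    ]

    hits = [
        TriangleHit(
            snp_id=row.id_a,
            probe_id=row.id_b,
            p_snp_auc=float(sa.at[row.id_a, "p"]),
            p_snp_expr=float(row.p),
            p_expr_auc=float(ea.at[row.id_b, "p"]),
            r_snp_auc=float(sa.at[row.id_a, "r"]),
            r_snp_expr=float(row.r),
            r_expr_auc=float(ea.at[row.id_b, "r"]),
        )
        for row in se.itertuples(index=False)
    ]
    hits.sort(key=lambda h: (h.p_snp_auc, h.snp_id, h.probe_id))
    unique_snps = len({h.snp_id for h in hits})
    return hits, unique_snps


def find_peak_regions(
    snp_auc: pd.DataFrame,
    p_max: float = 1e-4,
    gap: int = 50_000,
    min_snps: int = 2,
) -> list[PeakRegion]:
    """Single-linkage chaining of qualifying SNPs along each chromosome.

    ``snp_auc`` needs columns id_a, chrom, pos, p with positions 1-based and
    sorted within chromosome.  Consecutive qualifying SNPs <= ``gap`` bp
    apart join one chain (boundary inclusive); chains shorter than
    ``min_snps`` are discarded.
    """
    required = {"id_a", "chrom", "pos", "p"}
    if not required <= set(snp_auc.columns):
        raise ValueError(f"snp~auc table needs columns {sorted(required)}")
    regions: list[PeakRegion] = []
    for chrom, grp in snp_auc.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions unsorted within chromosome {chrom}")
        qual = grp[grp["p"] < p_max]
        if qual.empty:
            continue
        chain_rows: list[tuple[str, int, float]] = []
        last_pos = None
        for row in qual.itertuples(index=False):
            if last_pos is not None and row.pos - last_pos > gap:
                _emit(regions, chrom, chain_rows, min_snps)
                chain_rows = []
            chain_rows.append((row.id_a, int(row.pos), float(row.p)))
            last_pos = row.pos
        _emit(regions, chrom, chain_rows, min_snps)
    return regions


def _emit(regions: list[PeakRegion], chrom, chain, min_snps: int) -> None:
    if len(chain) >= min_snps:
        regions.append(
            PeakRegion(
                chrom=str(chrom),
                start=chain[0][1],
                end=chain[-1][1],
                snp_ids=[c[0] for c in chain],
                min_p=min(c[2] for c in chain),
            )
        )


def regions_to_bed(regions: list[PeakRegion]) -> pd.DataFrame:
    """Peak regions as BED (0-based half-open) with member count and min p."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start - 1,  # 1-based inclusive -> 0-based half-open
                "end": r.end,
                "name": f"peak_{i + 1}",
                "n_snps": r.n_snps,
                "min_p": r.min_p,
            }
            for i, r in enumerate(regions)
        ],
        columns=["chrom", "start", "end", "name", "n_snps", "min_p"],
    )


def select_expression_candidates(
    expr_auc: pd.DataFrame,
    linear_expression: pd.DataFrame,
    p_max: float = 1e-4,
    min_expr: float = 50.0,
    probe_gene_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Probes associated with AUC that are not low-expressed.

    Keeps probes with p < ``p_max`` whose *median* linear-scale expression
    across samples is >= ``min_expr``; when a probe→gene map is supplied the
    output is grouped by gene, listing every qualifying probe per gene.
    """
    hits = expr_auc[expr_auc["p"] < p_max]
    missing = set(hits["id_a"]) - set(linear_expression.index.astype(str))
    if missing:
        raise KeyError(
            f"probes absent from linear expression matrix: {sorted(missing)[:5]}"
        )
    rows = []
    for row in hits.itertuples(index=False):
        med = float(np.median(linear_expression.loc[row.id_a].to_numpy(dtype=float)))
        if med >= min_expr:
            rows.append(
                {"probe_id": row.id_a, "p": row.p, "r": row.r, "median_expr": med}
            )
    out = pd.DataFrame(rows, columns=["probe_id", "p", "r", "median_expr"])
    if probe_gene_map is not None and len(out):
        gene_of = probe_gene_map.set_index("probe_id")["gene"]
        out["gene"] = out["probe_id"].map(gene_of)
    out.sort_values(["p", "probe_id"], inplace=True, ignore_index=True)
    return out


def annotate_cis(
    hits: list[TriangleHit],
    snp_positions: pd.DataFrame,
    probe_map: pd.DataFrame | None,
    window: int = 1_000_000,
) -> list[TriangleHit]:
    """Flag each triangle hit cis/trans relative to its probe's gene span.

    A hit is cis when the SNP sits on the probe gene's chromosome within
    ``window`` bp of the gene span; hits whose probe lacks a map entry stay
    'unknown' (never silently cis or trans).  ``snp_positions`` needs columns
    snp_id, chrom, pos; ``probe_map`` needs probe_id, chrom, start, end.
    """
    snp_loc = snp_positions.set_index("snp_id")
    if probe_map is not None:
        required = {"probe_id", "chrom", "start", "end"}
        if not required <= set(probe_map.columns):
            raise ValueError(f"probe map needs columns {sorted(required)}")
        gene_loc = probe_map.set_index("probe_id")
    else:
        gene_loc = None
    for h in hits:
        if gene_loc is None or h.probe_id not in gene_loc.index:
            h.cis_flag = "unknown"
            continue
        g = gene_loc.loc[h.probe_id]
        s = snp_loc.loc[h.snp_id]
        if str(s["chrom"]) != str(g["chrom"]):
            h.cis_flag = "trans"
        else:
            pos = int(s["pos"])
            dist = max(int(g["start"]) - pos, pos - int(g["end"]), 0)
            h.cis_flag = "cis" if dist <= window else "trans"
    return hits


def hits_frame(hits: list[TriangleHit]) -> pd.DataFrame:
    """Triangle hits as the final candidate table."""
    return pd.DataFrame(
        [
            {
                "snp_id": h.snp_id, "probe_id": h.probe_id,
                "p_snp_expr": h.p_snp_expr, "r_snp_expr": h.r_snp_expr,
                "p_snp_auc": h.p_snp_auc, "r_snp_auc": h.r_snp_auc,
                "p_expr_auc": h.p_expr_auc, "r_expr_auc": h.r_expr_auc,
                "cis_flag": h.cis_flag,
            }
            for h in hits
        ],
        columns=[
            "snp_id", "probe_id", "p_snp_expr", "r_snp_expr",
            "p_snp_auc", "r_snp_auc", "p_expr_auc", "r_expr_auc", "cis_flag",
        ],
    )
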