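"""End-to-end pipeline orchestration, configuration and run reports.

Stages execute in the fixed order

    simulate? -> fit-curves -> qc -> adjust -> associate -> integrate

each writing its artifacts under the configured output directory and logging
entry/exit record counts (the QC-ledger discipline applied pipeline-wide).
A :class:`RunReport` collects per-stage counts, the QC ledger, association
tier counts (p < 1e-3 / 1e-4 / 1e-5 and the genome-wide 1e-8 note), triangle
and peak-region counts, plus a config hash and an artifact manifest with
SHA-256 checksums; reruns with the same config and seed are bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import PartialCorrelationScan, storey_qvalues
from .cohort import CohortSpec, generate_cohort
from .covariates import (
    CovariateTable, build_design, ld_thin, residualize, van_der_waerden,
    within_race_pca,
)
from .dose_response import DoseResponseModel
from .integration import (
    TriangleThresholds, annotate_cis, find_peak_regions, hits_frame,
    regions_to_bed, select_expression_candidates, triangle_scan,
)
from .io import read_covariates, read_expression, read_vcf, read_viability
from .qc import QCThresholds, qc_records_from_matrix, run_qc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline", "render_tiers"]

ALL_STAGES = ("simulate", "fit_curves", "qc", "adjust", "associate", "integrate")

#: reporting tiers for association counts; 1e-8 is the genome-wide line
REPORT_TIERS = (1e-3, 1e-4, 1e-5)
GENOME_WIDE_P = 1e-8


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with per-stage sections.

    Thresholds default to the study's reported settings: QC at call rate
    95% / MAF 5% / HWE 1e-6 (imputed: MAF 1% / dosage R-squared 0.3), AUC
    integrated on [0, 320] nmol/L, 5 stratification PCs per race, and
    triangle thresholds (1e-4, 1e-4, 1e-3).
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate: keyword overrides for CohortSpec (seed is injected)
    cohort: dict = field(default_factory=dict)
    # input paths (resolved against outdir/cohort when simulate runs)
    vcf: str | None = None
    expression_log2: str | None = None
    expression_linear: str | None = None
    viability: str | None = None
    covariates: str | None = None
    probe_map: str | None = None
    # dose-response
    dose_lower: float = 0.0
    dose_upper: float = 320.0
    # qc
    qc_call_rate: float = 0.95
    qc_maf: float = 0.05
    qc_hwe_p: float = 1e-6
    qc_imputed_maf: float = 0.01
    qc_dosage_r2: float = 0.30
    # adjust
    n_pcs: int = 5
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.2
    # associate
    storey_lambda: float = 0.5
    pi0_mode: str = "storey"
    # integrate
    thr_snp_auc: float = 1e-4
    thr_snp_expr: float = 1e-4
    thr_expr_auc: float = 1e-3
    peak_p_max: float = 1e-4
    peak_gap: int = 50_000
    peak_min_snps: int = 2
    candidate_p_max: float = 1e-4
    candidate_min_expr: float = 50.0
    cis_window: int = 1_000_000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("qc_call_rate", "qc_maf", "qc_hwe_p", "thr_snp_auc",
                     "thr_snp_expr", "thr_expr_auc", "peak_p_max",
                     "candidate_p_max", "storey_lambda"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dose_lower >= self.dose_upper:
            raise ValueError("dose_lower must be < dose_upper")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Key-order-independent SHA-256 of the canonical config JSON."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str = __version__
    config_hash: str = ""
    stage_counts: dict = field(default_factory=dict)
    qc_ledger: list = field(default_factory=list)
    convergence_rate: float = float("nan")
    tier_counts: dict = field(default_factory=dict)
    n_genome_wide: int = 0
    n_triangles: int = 0
    n_unique_triangle_snps: int = 0
    n_peak_regions: int = 0
    n_peak_snps: int = 0
    n_candidates: int = 0
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def summary(self) -> str:
        lines = [
            f"pgx-triangulate v{self.version}  (config {self.config_hash})",
            "",
            "Stage record counts:",
        ]
        for stage, counts in self.stage_counts.items():
            lines.append(f"  {stage:12s} {counts}")
        if self.qc_ledger:
            lines.append("QC ledger:")
            for f, t, n in self.qc_ledger:
                lines.append(f"  removed {n:>8,}  {f} (< {t:g})")
        if np.isfinite(self.convergence_rate):
            lines.append(f"Dose-response convergence: {100 * self.convergence_rate:.1f}%")
        for fam, tiers in self.tier_counts.items():
            tl = ", ".join(f"p<{t:g}: {c}" for t, c in tiers.items())
            lines.append(f"Associations [{fam}]: {tl}")
        lines.append(
            f"Genome-wide significant SNPs (p < {GENOME_WIDE_P:g}): {self.n_genome_wide}"
        )
        lines.append(
            f"Triangles: {self.n_triangles} ({self.n_unique_triangle_snps} unique SNPs)"
        )
        lines.append(
            f"Peak regions: {self.n_peak_regions} covering {self.n_peak_snps} SNPs"
        )
        lines.append(f"Expression candidates: {self.n_candidates}")
        return "\n".join(lines)


def render_tiers(assoc: pd.DataFrame, thresholds=REPORT_TIERS) -> dict[float, int]:
    """Count records strictly below each reporting threshold."""
    if assoc is None or len(assoc) == 0:
        return {float(t): 0 for t in thresholds}
    p = assoc["p"].to_numpy(dtype=float)
    return {float(t): int((p < t).sum()) for t in thresholds}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages end-to-end and write all artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash())
    stages = set(config.stages)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s: start", name)

    def fail(name, exc):
        (out / f"{name}.partial").touch()
        raise StageError(f"stage {name!r} failed: {exc}") from exc

    paths = {
        "vcf": config.vcf, "expression_log2": config.expression_log2,
        "expression_linear": config.expression_linear,
        "viability": config.viability, "covariates": config.covariates,
        "probe_map": config.probe_map,
    }

    # ---- simulate ----------------------------------------------------------
    if "simulate" in stages:
        stage("simulate")
        try:
            spec = CohortSpec(**{**config.cohort, "seed": config.seed})
            _, files = generate_cohort(spec, out / "cohort")
        except Exception as exc:
            fail("simulate", exc)
        for key in paths:
            paths[key] = str(getattr(files, key if key != "vcf" else "vcf"))
        report.stage_counts["simulate"] = {
            "samples": spec.n_samples, "snps": spec.m_snps, "probes": spec.m_probes,
        }
        for key, p in paths.items():
            artifacts[f"cohort/{Path(p).name}"] = Path(p)

    if not stages - {"simulate"}:
        report.manifest = {k: _sha256(p) for k, p in artifacts.items()}
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.summary() + "\n")
        return report

    # ---- fit curves --------------------------------------------------------
    auc_table = None
    if "fit_curves" in stages:
        stage("fit_curves")
        try:
            viability = read_viability(paths["viability"])
            results = DoseResponseModel(
                viability, config.dose_lower, config.dose_upper
            ).fit()
            auc_table = results.frame()
            report.convergence_rate = results.convergence_rate
        except Exception as exc:
            fail("fit_curves", exc)
        p = out / "auc_phenotype.tsv"
        auc_table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        artifacts["auc_phenotype.tsv"] = p
        report.stage_counts["fit_curves"] = {
            "samples": len(auc_table),
            "converged": int(auc_table["converged"].sum()),
        }

    # ---- qc ----------------------------------------------------------------
    genotypes = snp_sites = vcf_samples = None
    if "qc" in stages:
        stage("qc")
        try:
            genotypes, snp_sites, vcf_samples, _ = read_vcf(paths["vcf"])
            records = qc_records_from_matrix(
                genotypes, snp_sites,
                imputed=snp_sites["imputed"].to_numpy(),
                dosage_r2=snp_sites["dosage_r2"].to_numpy(),
            )
            thr = QCThresholds(
                call_rate=config.qc_call_rate, maf=config.qc_maf,
                hwe_p=config.qc_hwe_p, imputed_maf=config.qc_imputed_maf,
                dosage_r2=config.qc_dosage_r2,
            )
            retained, ledger = run_qc(records, thr)
            keep_ids = {r.snp_id for r in retained}
            keep = snp_sites["snp_id"].isin(keep_ids).to_numpy()
            genotypes = genotypes[keep]
            snp_sites = snp_sites.loc[keep].reset_index(drop=True)
        except Exception as exc:
            fail("qc", exc)
        report.qc_ledger = [list(s) for s in ledger.steps]
        ledger_path = out / "qc_ledger.tsv"
        ledger.frame().to_csv(ledger_path, sep="\t", index=False)
        per_snp = out / "snp_qc.tsv"
        pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                    "call_rate": r.call_rate, "maf": r.maf, "hwe_p": r.hwe_p,
                    "imputed": r.imputed, "fail_reason": r.fail_reason or "",
                }
                for r in records
            ]
        ).to_csv(per_snp, sep="\t", index=False, float_format="%.6g")
        artifacts["qc_ledger.tsv"] = ledger_path
        artifacts["snp_qc.tsv"] = per_snp
        report.stage_counts["qc"] = {
            "input": ledger.n_input, "retained": ledger.n_retained,
        }

    # ---- adjust ------------------------------------------------------------
    adjusted = {}
    n_cov = None
    expr_log2 = expr_linear = probe_map = None
    if "adjust" in stages:
        stage("adjust")
        try:
            if genotypes is None:
                genotypes, snp_sites, vcf_samples, _ = read_vcf(paths["vcf"])
            if auc_table is None:
                auc_table = pd.read_csv(out / "auc_phenotype.tsv", sep="\t")
            expr_log2 = read_expression(paths["expression_log2"])
            expr_linear = read_expression(paths["expression_linear"])
            cov_df = read_covariates(paths["covariates"])
            if paths["probe_map"]:
                probe_map = pd.read_csv(paths["probe_map"], sep="\t")

            samples = list(vcf_samples)
            cov_df = cov_df.set_index("sample").loc[samples].reset_index()
            expr_log2 = expr_log2[samples]
            expr_linear = expr_linear[samples]
            auc = auc_table.set_index("sample_id").loc[samples, "auc"]

            cov = CovariateTable.from_frame(cov_df)
            thin_idx = ld_thin(
                genotypes, snp_sites["chrom"].to_numpy(), snp_sites["pos"].to_numpy(),
                config.ld_window, config.ld_step, config.ld_r2,
            )
            cov.pcs = within_race_pca(
                genotypes[thin_idx], cov.race, samples, k=config.n_pcs
            )
            design = build_design(cov)
            n_cov = design.shape[1] - 1

            vdw = van_der_waerden(auc.to_numpy())
            auc_mat = pd.DataFrame([vdw], index=["auc"], columns=samples)
            adjusted["auc"] = residualize(auc_mat, design, "auc")
            adjusted["expression"] = residualize(expr_log2, design, "expression")

            gmat = pd.DataFrame(
                genotypes.astype(float), index=snp_sites["snp_id"], columns=samples
            )
            miss = pd.DataFrame(
                genotypes < 0, index=snp_sites["snp_id"], columns=samples
            )
            gmat = gmat.mask(miss.to_numpy())
            adjusted["genotype"] = residualize(gmat, design, "genotype", miss)
        except Exception as exc:
            fail("adjust", exc)
        design_path = out / "design_matrix.tsv"
        design.to_csv(design_path, sep="\t", float_format="%.6g")
        artifacts["design_matrix.tsv"] = design_path
        for name, mat in adjusted.items():
            p = out / f"adjusted_{name}.tsv"
            mat.values.to_csv(p, sep="\t", float_format="%.6g")
            artifacts[p.name] = p
        report.stage_counts["adjust"] = {
            name: mat.values.shape[0] for name, mat in adjusted.items()
        }

    # ---- associate ---------------------------------------------------------
    assoc = {}
    if "associate" in stages:
        stage("associate")
        try:
            scans = {
                "snp~auc": (adjusted["genotype"], adjusted["auc"]),
                "expr~auc": (adjusted["expression"], adjusted["auc"]),
                "snp~expr": (adjusted["genotype"], adjusted["expression"]),
            }
            for fam, (a, b) in scans.items():
                res = PartialCorrelationScan(
                    a, b, fam, config.storey_lambda, config.pi0_mode
                ).fit()
                assoc[fam] = res.frame
        except Exception as exc:
            fail("associate", exc)
        for fam, frame in assoc.items():
            p = out / f"assoc_{fam.replace('~', '_')}.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
            artifacts[p.name] = p
            report.tier_counts[fam] = render_tiers(frame)
        # Manhattan-ready TSV for the SNP scan
        man = assoc["snp~auc"].merge(
            snp_sites[["snp_id", "chrom", "pos"]],
            left_on="id_a", right_on="snp_id",
        )[["chrom", "pos", "p"]]
        man["neg_log10_p"] = -np.log10(man.pop("p"))
        man_path = out / "manhattan_snp_auc.tsv"
        man.to_csv(man_path, sep="\t", index=False, float_format="%.6g")
        artifacts[man_path.name] = man_path
        report.n_genome_wide = int(
            (assoc["snp~auc"]["p"] < GENOME_WIDE_P).sum()
        )
        report.stage_counts["associate"] = {f: len(t) for f, t in assoc.items()}

    # ---- integrate ---------------------------------------------------------
    if "integrate" in stages:
        stage("integrate")
        try:
            snp_auc = assoc["snp~auc"].merge(
                snp_sites[["snp_id", "chrom", "pos"]],
                left_on="id_a", right_on="snp_id",
            ).sort_values(["chrom", "pos"], ignore_index=True)
            hits, n_unique = triangle_scan(
                assoc["snp~auc"], assoc["snp~expr"], assoc["expr~auc"],
                TriangleThresholds(
                    config.thr_snp_auc, config.thr_snp_expr, config.thr_expr_auc
                ),
            )
            pm = probe_map if probe_map is not None else None
            annotate_cis(
                hits, snp_sites[["snp_id", "chrom", "pos"]], pm, config.cis_window
            )
            regions = find_peak_regions(
                snp_auc, config.peak_p_max, config.peak_gap, config.peak_min_snps
            )
            candidates = select_expression_candidates(
                assoc["expr~auc"], expr_linear,
                config.candidate_p_max, config.candidate_min_expr, pm,
            )
        except Exception as exc:
            fail("integrate", exc)
        tri_path = out / "triangles.tsv"
        hits_frame(hits).to_csv(tri_path, sep="\t", index=False, float_format="%.6g")
        bed_path = out / "peak_regions.bed"
        regions_to_bed(regions).to_csv(bed_path, sep="\t", index=False, header=False)
        cand_path = out / "expression_candidates.tsv"
        candidates.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")
        artifacts.update(
            {p.name: p for p in (tri_path, bed_path, cand_path)}
        )
        report.n_triangles = len(hits)
        report.n_unique_triangle_snps = n_unique
        report.n_peak_regions = len(regions)
        report.n_peak_snps = sum(r.n_snps for r in regions)
        report.n_candidates = len(candidates)
        report.stage_counts["integrate"] = {
            "triangles": len(hits), "peak_regions": len(regions),
            "candidates": len(candidates),
        }

    report.manifest = {k: _sha256(p) for k, p in artifacts.items()}
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.summary() + "\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report
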