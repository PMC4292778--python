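"""Sequential SNP quality control with an auditable ledger.

Filters mirror standard array-era GWAS practice: call rate < 95% removed,
minor allele frequency < 5% removed, Hardy–Weinberg disequilibrium removed at
a configurable p cutoff (default 1e-6); imputed markers are additionally
dropped at MAF < 0.01 or dosage-quality R² < 0.3.  Removal conditions are
strict inequalities — a SNP exactly at a boundary is retained.  Every run
produces a :class:`QCLedger` whose arithmetic (input = retained + Σ removed)
is asserted, and each SNP carries at most one fail_reason: the first filter
it failed in the configured order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCLedger",
    "SnpQCRecord",
    "call_rate",
    "minor_allele_freq",
    "hwe_test",
    "qc_records_from_matrix",
    "filter_imputed",
    "run_qc",
    "dedup_platforms",
]


@dataclass(frozen=True)
class QCThresholds:
    """Removal thresholds; all comparisons are strict (`<` removes)."""

    call_rate: float = 0.95
    maf: float = 0.05
    hwe_p: float = 1e-6
    imputed_maf: float = 0.01
    dosage_r2: float = 0.30


@dataclass
class QCLedger:
    """Ordered per-filter removal accounting for one QC run."""

    n_input: int
    steps: list[tuple[str, float, int]] = field(default_factory=list)

    def add(self, filter_name: str, threshold: float, n_removed: int) -> None:
        if n_removed < 0:
            raise ValueError("n_removed must be >= 0")
        self.steps.append((filter_name, float(threshold), int(n_removed)))

    @property
    def n_removed_total(self) -> int:
        return sum(n for _, _, n in self.steps)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_total

    def validate(self) -> None:
        """Assert the conservation invariant input = retained + Σ removed."""
        if self.n_retained < 0 or any(n < 0 for _, _, n in self.steps):
            raise ValueError(f"ledger arithmetic violated: {self}")

    def frame(self) -> pd.DataFrame:
        rows = [(f, t, n) for f, t, n in self.steps]
        df = pd.DataFrame(rows, columns=["filter", "threshold", "n_removed"])
        return df

    def summary(self) -> str:
        lines = [f"SNPs in: {self.n_input:,}"]
        for f, t, n in self.steps:
            lines.append(f"  removed {n:>10,}  {f} (threshold {t:g})")
        lines.append(f"SNPs retained: {self.n_retained:,}")
        return "\n".join(lines)

    @classmethod
    def replay(cls, n_input: int, removals: Sequence[tuple[str, float, int]]) -> "QCLedger":
        """Rebuild a ledger from published per-filter counts and validate it."""
        ledger = cls(n_input=int(n_input))
        for name, thr, n in removals:
            ledger.add(name, thr, n)
        ledger.validate()
        return ledger


@dataclass
class SnpQCRecord:
    """Per-SNP QC metrics; dosage_r2 present iff the marker is imputed."""

    snp_id: str
    chrom: str
    pos: int
    call_rate: float
    maf: float
    hwe_p: float
    imputed: bool = False
    dosage_r2: float | None = None
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.snp_id}: call_rate outside [0,1]")
        if self.maf > 0.5 + 1e-12 or self.maf < 0:
            raise ValueError(f"{self.snp_id}: maf must lie in [0, 0.5]")
        if not 0.0 <= self.hwe_p <= 1.0:
            raise ValueError(f"{self.snp_id}: hwe_p must be a probability")
        if self.imputed and self.dosage_r2 is None:
            raise ValueError(f"{self.snp_id}: imputed record lacks dosage_r2")


# ---------------------------------------------------------------------------
# per-SNP metrics
# ---------------------------------------------------------------------------

def call_rate(genotypes: np.ndarray) -> float:
    """Fraction of non-missing calls (missing coded -1 or NaN)."""
    g = np.asarray(genotypes, dtype=float)
    if g.size == 0:
        raise ValueError("empty genotype vector")
    present = np.sum(~_missing_mask(g))
    return float(present / g.size)


def _missing_mask(g: np.ndarray) -> np.ndarray:
    return np.isnan(g) | (g < 0)


def minor_allele_freq(genotypes: np.ndarray) -> float:
    """Folded allele frequency min(f, 1-f) over non-missing alleles."""
    g = np.asarray(genotypes, dtype=float)
    obs = g[~_missing_mask(g)]
    if obs.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy–Weinberg proportions.

    Expected genotype counts come from the estimated allele frequency
    p̂ = (2·n_aa + n_ab) / 2n.  Returns (chi2, p).  Monomorphic sites fit
    exactly (chi2 = 0, p = 1).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_from_genotypes(genotypes: np.ndarray) -> tuple[float, float]:
    """HWE test from a coded genotype vector (missing excluded)."""
    g = np.asarray(genotypes, dtype=float)
    obs = g[~_missing_mask(g)].astype(int)
    return hwe_test(int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2)))


def qc_records_from_matrix(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    imputed: np.ndarray | None = None,
    dosage_r2: np.ndarray | None = None,
) -> list[SnpQCRecord]:
    """Compute per-SNP QC metrics for an m x n coded genotype matrix."""
    records = []
    for i in range(genotypes.shape[0]):
        g = genotypes[i]
        cr = call_rate(g)
        if cr == 0.0:
            maf, hwe_p = 0.0, 1.0
        else:
            maf = minor_allele_freq(g)
            _, hwe_p = hwe_from_genotypes(g)
        imp = bool(imputed[i]) if imputed is not None else False
        r2 = float(dosage_r2[i]) if (imp and dosage_r2 is not None) else None
        records.append(
            SnpQCRecord(
                snp_id=str(snps["snp_id"].iat[i]),
                chrom=str(snps["chrom"].iat[i]),
                pos=int(snps["pos"].iat[i]),
                call_rate=cr, maf=maf, hwe_p=hwe_p,
                imputed=imp, dosage_r2=r2,
            )
        )
    return records


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _genotyped_filters(thr: QCThresholds) -> list[tuple[str, float, callable]]:
    return [
        ("call_rate", thr.call_rate, lambda r: (not r.imputed) and r.call_rate < thr.call_rate),
        ("maf", thr.maf, lambda r: (not r.imputed) and r.maf < thr.maf),
        ("hwe", thr.hwe_p, lambda r: (not r.imputed) and r.hwe_p < thr.hwe_p),
    ]


def _imputed_filters(thr: QCThresholds) -> list[tuple[str, float, callable]]:
    return [
        ("imputed_maf", thr.imputed_maf, lambda r: r.imputed and r.maf < thr.imputed_maf),
        ("imputed_dosage_r2", thr.dosage_r2,
         lambda r: r.imputed and r.dosage_r2 < thr.dosage_r2),
    ]


def filter_imputed(
    records: Iterable[SnpQCRecord], thresholds: QCThresholds | None = None
) -> tuple[list[SnpQCRecord], QCLedger]:
    """Imputed-marker filters only: MAF < 0.01 or dosage R² < 0.3 removed.

    Genotyped markers pass through untouched (their MAF rule is the separate
    5% panel filter).
    """
    thr = thresholds or QCThresholds()
    records = list(records)
    for r in records:
        if r.imputed and r.dosage_r2 is None:
            raise ValueError(f"{r.snp_id}: imputed record lacks dosage_r2")
    return _apply(records, _imputed_filters(thr))


def run_qc(
    records: Iterable[SnpQCRecord],
    thresholds: QCThresholds | None = None,
    include_imputed_filters: bool = True,
) -> tuple[list[SnpQCRecord], QCLedger]:
    """Sequential QC: call rate → MAF → HWE (then imputed-marker filters).

    Each SNP is tagged with the first filter it fails; the returned ledger
    satisfies n_input = n_retained + Σ n_removed by construction and is
    validated before return.
    """
    thr = thresholds or QCThresholds()
    records = list(records)
    filters = _genotyped_filters(thr)
    if include_imputed_filters and any(r.imputed for r in records):
        filters += _imputed_filters(thr)
    retained, ledger = _apply(records, filters)
    logger.info("QC: %s", ledger.summary().replace("\n", " | "))
    return retained, ledger


def _apply(records, filters):
    ledger = QCLedger(n_input=len(records))
    surviving = records
    for name, threshold, predicate in filters:
        failed = [r for r in surviving if predicate(r)]
        for r in failed:
            r.fail_reason = name
        surviving = [r for r in surviving if not predicate(r)]
        ledger.add(name, threshold, len(failed))
    ledger.validate()
    return surviving, ledger


# ---------------------------------------------------------------------------
# cross-platform deduplication
# ---------------------------------------------------------------------------

def _identity_key(rec: SnpQCRecord) -> tuple:
    # rsID when it looks like one, else positional identity
    if rec.snp_id.startswith("rs"):
        return ("rsid", rec.snp_id)
    return ("locus", rec.chrom, rec.pos)


def dedup_platforms(
    *platform_sets: Sequence[SnpQCRecord],
    genotype_lookup: dict | None = None,
) -> tuple[list[SnpQCRecord], int]:
    """Merge SNP record sets from multiple genotyping platforms.

    Identity is the shared rsID when both platforms carry one, else
    (chrom, pos).  The first platform listed takes precedence for duplicated
    SNPs.  When ``genotype_lookup`` maps snp_id -> genotype vector, genotype
    conflicts at duplicated SNPs are counted and logged (first platform still
    wins); returns (merged records, n_redundant).
    """
    seen: dict[tuple, SnpQCRecord] = {}
    n_redundant = 0
    n_conflicts = 0
    for platform in platform_sets:
        for rec in platform:
            key = _identity_key(rec)
            if key in seen:
                n_redundant += 1
                if genotype_lookup is not None:
                    a = genotype_lookup.get(seen[key].snp_id)
                    b = genotype_lookup.get(rec.snp_id)
                    if a is not None and b is not None and not np.array_equal(a, b):
                        n_conflicts += 1
            else:
                seen[key] = rec
    if n_conflicts:
        logger.warning(
            "dedup_platforms: %d duplicated SNPs had conflicting genotypes; "
            "first-precedence platform retained", n_conflicts,
        )
    return list(seen.values()), n_redundant
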