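"""Synthetic three-population pharmacogenomic cohort with planted effects.

Generates everything the downstream pipeline consumes — genotypes (with a
Balding–Nichols between-race allele-frequency drift), log2 expression with
planted eQTLs, per-sample drug-sensitivity AUC driven by planted SNP and
expression effects, and noisy triplicate viability curves on a 9-dose grid —
together with a truth registry so recovery of every planted SNP→expression→AUC
chain can be asserted exactly.

All randomness flows from a single master seed through named substreams
(genotype / expression / auc / viability), so each stage regenerates
independently and identical specs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "SpecValidationError",
    "InfeasibleAUCError",
    "generate_genotypes",
    "generate_expression",
    "generate_viability",
    "generate_cohort",
    "design_planted_chain",
    "write_vcf",
]

#: default 9-point dose grid in nmol/L used for the cytotoxicity assay
DEFAULT_DOSE_GRID = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)

#: fixed curve shape for the AUC -> viability-curve inversion: slope b,
#: lower asymptote c, upper asymptote d.  One free parameter (the
#: half-maximal dose e) keeps the AUC -> curve map invertible.
INVERSION_B = 1.5
INVERSION_C = 0.05
INVERSION_D = 1.0

_N_AUTOSOMES = 22
_SNP_SPACING_BP = 5_000


class SpecValidationError(ValueError):
    """A CohortSpec field is out of its valid range (names the field)."""


class InfeasibleAUCError(ValueError):
    """Requested AUC lies outside the attainable range of the fixed curve."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    Defaults mirror the study design the pipeline targets: a 278-sample
    cohort of three self-reported race groups (93 / 91 / 94), genotyped on a
    common-variant panel, expression-profiled on a log2 array scale, and
    phenotyped with a 9-dose viability assay integrated into an AUC.
    """

    n_per_race: tuple[int, int, int] = (93, 91, 94)
    m_snps: int = 2_000
    m_probes: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    #: (snp_index, probe_index, beta_expr): log2-expression shift per rare allele
    planted_eqtls: tuple[tuple[int, int, float], ...] = ()
    #: (probe_index, gamma_auc): AUC shift per log2-expression unit
    planted_expr_auc: tuple[tuple[int, float], ...] = ()
    #: (snp_index, delta_auc): direct AUC shift per rare allele
    planted_snp_auc: tuple[tuple[int, float], ...] = ()
    noise_sd_expr: float = 0.5
    noise_sd_auc: float = 40.0
    noise_sd_viability: float = 0.03
    missing_rate: float = 0.02
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    auc_mean: float = 180.0
    n_replicates: int = 3
    race_labels: tuple[str, str, str] = ("AA", "CA", "HCA")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_race) != 3 or any(n <= 0 for n in self.n_per_race):
            raise SpecValidationError("n_per_race: need 3 positive group sizes")
        for name in ("m_snps", "m_probes", "n_replicates"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name}: must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecValidationError("maf_range: must lie within (0, 0.5]")
        if not 0.0 <= self.fst < 1.0:
            raise SpecValidationError("fst: must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecValidationError("missing_rate: must lie in [0, 1)")
        for name in ("noise_sd_expr", "noise_sd_auc", "noise_sd_viability"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name}: must be >= 0")
        doses = np.asarray(self.dose_grid, dtype=float)
        if doses.size < 2 or doses[0] != 0.0 or np.any(np.diff(doses) <= 0):
            raise SpecValidationError(
                "dose_grid: must be strictly ascending and start at dose 0"
            )
        for j, k, _ in self.planted_eqtls:
            if not (0 <= j < self.m_snps and 0 <= k < self.m_probes):
                raise SpecValidationError("planted_eqtls: index out of bounds")
        for k, _ in self.planted_expr_auc:
            if not 0 <= k < self.m_probes:
                raise SpecValidationError("planted_expr_auc: probe index out of bounds")
        for j, _ in self.planted_snp_auc:
            if not 0 <= j < self.m_snps:
                raise SpecValidationError("planted_snp_auc: snp index out of bounds")

    # ---- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_race))

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for label, n in zip(self.race_labels, self.n_per_race):
            out.extend(f"{label}{i + 1:03d}" for i in range(n))
        return out

    @property
    def race_of_sample(self) -> np.ndarray:
        return np.repeat(np.asarray(self.race_labels, dtype=object), self.n_per_race)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream derived from the master seed."""
        streams = {"genotype": 1, "expression": 2, "auc": 3, "viability": 4, "sex": 5}
        return np.random.default_rng([int(self.seed), streams[stream]])


@dataclass
class SyntheticTruth:
    """Planted-effect registry plus the latent per-sample quantities.

    ``race_freqs`` holds the drifted per-race rare-allele frequencies (m_snps
    x 3) from which the generating Fst can be re-estimated; ``true_auc`` is
    the noise-bearing but curve-free AUC each viability plate encodes, and
    ``half_max_dose`` the per-sample logistic parameter e solving the
    inversion.
    """

    spec: CohortSpec
    ancestral_maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    race_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]
    genotypes_true: np.ndarray = field(default=None)  # type: ignore[assignment]
    expr_baseline: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_auc: np.ndarray = field(default=None)  # type: ignore[assignment]
    half_max_dose: np.ndarray = field(default=None)  # type: ignore[assignment]

    def registry_frame(self) -> pd.DataFrame:
        """Planted effects as a tidy table (kind, snp, probe, effect)."""
        rows = []
        for j, k, beta in self.spec.planted_eqtls:
            rows.append(("eqtl", f"snp_{j:05d}", f"probe_{k:04d}", beta))
        for k, gamma in self.spec.planted_expr_auc:
            rows.append(("expr_auc", "", f"probe_{k:04d}", gamma))
        for j, delta in self.spec.planted_snp_auc:
            rows.append(("snp_auc", f"snp_{j:05d}", "", delta))
        return pd.DataFrame(rows, columns=["kind", "snp_id", "probe_id", "effect"])

    def estimate_fst(self) -> float:
        """Moment re-estimate of the divergence parameter from race frequencies.

        Under the Beta drift model the across-race sample variance of the
        drifted frequency has expectation F·p(1−p) while the mean-frequency
        product p̄(1−p̄) has expectation p(1−p)·(1 − F/r) + ... ; the ratio
        v / (p̄(1−p̄) + v/r) is unbiased to first order for F with r races.
        """
        p = self.race_freqs
        r = p.shape[1]
        v = p.var(axis=1, ddof=1)
        pbar = p.mean(axis=1)
        denom = pbar * (1 - pbar) + v / r
        ok = denom > 0
        return float(np.mean(v[ok] / denom[ok]))


def _snp_positions(m_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign SNPs to autosomes in contiguous blocks with fixed spacing."""
    per_chrom = int(np.ceil(m_snps / _N_AUTOSOMES))
    chrom = 1 + (np.arange(m_snps) // per_chrom)
    pos = 1 + (np.arange(m_snps) % per_chrom) * _SNP_SPACING_BP
    return chrom.astype(int), pos.astype(int)


def snp_table(spec: CohortSpec) -> pd.DataFrame:
    """SNP id / chrom / pos map used consistently across artifacts."""
    chrom, pos = _snp_positions(spec.m_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{j:05d}" for j in range(spec.m_snps)],
            "chrom": chrom,
            "pos": pos,
        }
    )


def probe_table(spec: CohortSpec) -> pd.DataFrame:
    """Probe -> synthetic gene locus map (for cis/trans annotation).

    Probes are laid down on the autosomes interleaved with, but offset from,
    the SNP blocks; each synthetic gene spans 20 kb.
    """
    per_chrom = int(np.ceil(spec.m_probes / _N_AUTOSOMES))
    chrom = 1 + (np.arange(spec.m_probes) % _N_AUTOSOMES)
    start = 10_000_000 + (np.arange(spec.m_probes) // _N_AUTOSOMES) * 100_000
    return pd.DataFrame(
        {
            "probe_id": [f"probe_{k:04d}" for k in range(spec.m_probes)],
            "gene": [f"GENE{k:04d}" for k in range(spec.m_probes)],
            "chrom": chrom.astype(int),
            "start": start.astype(int),
            "end": (start + 20_000).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(
    spec: CohortSpec, truth: SyntheticTruth | None = None
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw the genotype matrix (m_snps x n_samples, -1 = missing).

    Per SNP an ancestral rare-allele frequency is drawn uniformly from
    ``maf_range``; each race's frequency is a Balding–Nichols Beta draw with
    parameters p(1−F)/F and (1−p)(1−F)/F (F = fst; F = 0 leaves frequencies
    undrifted).  Genotypes are two Hardy–Weinberg Bernoulli alleles coded as
    the rare-allele count, then masked missing completely at random.
    """
    rng = spec.rng("genotype")
    truth = truth or SyntheticTruth(spec=spec)
    m, n = spec.m_snps, spec.n_samples

    lo, hi = spec.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if spec.fst > 0:
        F = spec.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        race_freqs = rng.beta(a[:, None], b[:, None], size=(m, 3))
        # keep frequencies polymorphic so HWE draws stay well defined
        race_freqs = np.clip(race_freqs, 1e-6, 1 - 1e-6)
    else:
        race_freqs = np.repeat(p_anc[:, None], 3, axis=1)

    G = np.empty((m, n), dtype=np.int8)
    offset = 0
    for r, n_r in enumerate(spec.n_per_race):
        G[:, offset : offset + n_r] = rng.binomial(
            2, race_freqs[:, r][:, None], size=(m, n_r)
        ).astype(np.int8)
        offset += n_r

    truth.ancestral_maf = p_anc
    truth.race_freqs = race_freqs
    truth.genotypes_true = G.copy()

    if spec.missing_rate > 0:
        mask = rng.random(size=(m, n)) < spec.missing_rate
        G = np.where(mask, np.int8(-1), G)
    return G, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    spec: CohortSpec, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix (probes x samples) plus its linear companion.

    probe value = baseline + Σ beta·(rare-allele count) + N(0, noise_sd_expr);
    baselines are uniform on log2 [3.5, 11] so a realistic minority of probes
    sit below the linear-scale low-expression boundary of 50 (log2 ≈ 5.64).
    Planted eQTLs act through the *true* (pre-missingness) genotypes.
    """
    if truth.genotypes_true is None:
        raise SpecValidationError("generate_genotypes must run before expression")
    rng = spec.rng("expression")
    m, n = spec.m_probes, spec.n_samples

    baseline = rng.uniform(3.5, 11.0, size=m)
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd_expr, size=(m, n))
    for j, k, beta in spec.planted_eqtls:
        X[k] += beta * truth.genotypes_true[j].astype(float)

    truth.expr_baseline = baseline
    ids = [f"probe_{k:04d}" for k in range(m)]
    log2 = pd.DataFrame(X, index=pd.Index(ids, name="probe_id"),
                        columns=spec.sample_ids)
    return log2, np.exp2(log2)


# ---------------------------------------------------------------------------
# AUC truth and viability curves
# ---------------------------------------------------------------------------

def _log_logistic(x: np.ndarray, b: float, c: float, d: float, e: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, d, dtype=float)
    nz = x > 0
    out[nz] = c + (d - c) / (1.0 + (x[nz] / e) ** b)
    return out


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)


def _curve_auc(e: float, b: float, c: float, d: float, upper: float) -> float:
    """Gauss–Legendre integral of the log-logistic curve on [0, upper]."""
    x = 0.5 * upper * (_GL_NODES + 1.0)
    w = 0.5 * upper * _GL_WEIGHTS
    return float(np.sum(w * _log_logistic(x, b, c, d, e)))


def solve_half_max_dose(
    target_auc: float,
    upper: float,
    b: float = INVERSION_B,
    c: float = INVERSION_C,
    d: float = INVERSION_D,
) -> float:
    """Solve for e so the curve's [0, upper] integral equals ``target_auc``.

    The integral is strictly increasing in e from c·upper (e→0) to d·upper
    (e→∞); targets outside that open interval raise InfeasibleAUCError.
    """
    lo_auc, hi_auc = c * upper, d * upper
    if target_auc == hi_auc:
        return float("inf")  # e -> inf limit: flat curve at the upper asymptote
    if not lo_auc < target_auc < hi_auc:
        raise InfeasibleAUCError(
            f"AUC {target_auc:.4g} outside attainable open interval "
            f"({lo_auc:.4g}, {hi_auc:.4g}) for fixed (b={b}, c={c}, d={d})"
        )
    f = lambda log_e: _curve_auc(np.exp(log_e), b, c, d, upper) - target_auc
    lo, hi = np.log(1e-6), np.log(1e9 * upper)
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)))


def generate_true_auc(
    spec: CohortSpec, truth: SyntheticTruth, log2_expr: pd.DataFrame
) -> np.ndarray:
    """Latent per-sample AUC: mean + planted effects + Gaussian noise.

    Expression effects are centred on the probe baseline so planting an
    effect does not move the cohort mean; values are clipped 1 unit inside
    the attainable range of the fixed inversion curve (viability saturates).
    """
    rng = spec.rng("auc")
    upper = spec.dose_grid[-1]
    auc = np.full(spec.n_samples, spec.auc_mean, dtype=float)
    for k, gamma in spec.planted_expr_auc:
        auc += gamma * (log2_expr.iloc[k].to_numpy() - truth.expr_baseline[k])
    for j, delta in spec.planted_snp_auc:
        g = truth.genotypes_true[j].astype(float)
        auc += delta * (g - g.mean())
    auc += rng.normal(0.0, spec.noise_sd_auc, size=spec.n_samples)
    auc = np.clip(auc, INVERSION_C * upper + 1.0, INVERSION_D * upper - 1.0)
    truth.true_auc = auc
    return auc


def generate_viability(
    spec: CohortSpec, true_auc: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """Render per-sample AUC targets into a long-format triplicate plate.

    Each sample's AUC is inverted to a half-maximal dose e under the fixed
    (b, c, d) shape; viability = curve(dose) + N(0, noise_sd_viability),
    clipped below at 0 (MTS readings can exceed the untreated control, so no
    upper clip).  Columns: sample, dose_nM, replicate, viability.
    """
    rng = spec.rng("viability")
    true_auc = np.asarray(true_auc, dtype=float)
    if true_auc.shape != (spec.n_samples,):
        raise SpecValidationError("true_auc: one value per sample required")
    doses = np.asarray(spec.dose_grid, dtype=float)
    upper = doses[-1]

    es = np.array([solve_half_max_dose(a, upper) for a in true_auc])
    rows = []
    for s, (sample, e) in enumerate(zip(spec.sample_ids, es)):
        curve = _log_logistic(doses, INVERSION_B, INVERSION_C, INVERSION_D, e)
        for rep in range(1, spec.n_replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd_viability, size=doses.size)
            v = np.clip(curve + noise, 0.0, None)
            for dose, val in zip(doses, v):
                rows.append((sample, dose, rep, val))
    df = pd.DataFrame(rows, columns=["sample", "dose_nM", "replicate", "viability"])
    return df


# ---------------------------------------------------------------------------
# VCF + file emission
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path: str | Path,
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    sample_ids: Sequence[str],
    dosages: np.ndarray | None = None,
    dosage_r2: np.ndarray | None = None,
) -> None:
    """Write genotypes as VCF v4.2 (GT; optional DS + INFO IMPR2).

    Emission is plain text with fixed formatting so identical inputs yield
    byte-identical files.  The ALT allele is the rare allele; GT encodes its
    count.  Imputed sites (those with a finite ``dosage_r2``) carry
    ``IMPR2=<r2>`` and, when ``dosages`` is given, a DS value per sample.
    """
    path = Path(path)
    m, n = genotypes.shape
    has_ds = dosages is not None
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=IMPR2,Number=1,Type=Float,Description="Imputation dosage R-squared quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_ds:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">'
        )
    for c in range(1, _N_AUTOSOMES + 1):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    fmt = "GT:DS" if has_ds else "GT"
    for i in range(m):
        info = "."
        if dosage_r2 is not None and np.isfinite(dosage_r2[i]):
            info = f"IMPR2={dosage_r2[i]:.4f}"
        fields = [
            str(int(snps["chrom"].iat[i])),
            str(int(snps["pos"].iat[i])),
            str(snps["snp_id"].iat[i]),
            "A",
            "G",
            ".",
            "PASS",
            info,
            fmt,
        ]
        gts = genotypes[i]
        if has_ds:
            ds = dosages[i]
            fields.extend(
                f"{_GT_CODE[int(g)]}:{d:.3f}" for g, d in zip(gts, ds)
            )
        else:
            fields.extend(_GT_CODE[int(g)] for g in gts)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def design_planted_chain(
    seed: int,
    m_snps: int = 1_000,
    m_probes: int = 250,
    beta_expr: float = 1.0,
    gamma_auc: float = 40.0,
    min_maf: float = 0.2,
    baseline_range: tuple[float, float] = (6.5, 10.0),
    **overrides,
) -> CohortSpec:
    """Build a cohort spec with one strong SNP -> expression -> AUC chain.

    A recovery experiment plants its causal chain deliberately at a common
    variant and a well-expressed probe (as one would pick a credible positive
    control): the chain SNP is the first with ancestral rare-allele frequency
    >= ``min_maf`` (so it survives the 5% MAF filter with margin) and the
    chain probe the first whose log2 baseline lies in ``baseline_range`` (so
    it clears the linear-scale low-expression filter).  Genotype and
    expression substreams do not depend on the planted-effect registry, so
    the two-pass construction is exactly reproducible.
    """
    base = CohortSpec(m_snps=m_snps, m_probes=m_probes, seed=seed, **overrides)
    _, truth = generate_genotypes(base)
    generate_expression(base, truth)
    snp_j = int(np.flatnonzero(truth.ancestral_maf >= min_maf)[0])
    lo, hi = baseline_range
    ok = (truth.expr_baseline >= lo) & (truth.expr_baseline <= hi)
    probe_k = int(np.flatnonzero(ok)[0])
    return dataclasses.replace(
        base,
        planted_eqtls=((snp_j, probe_k, beta_expr),),
        planted_expr_auc=((probe_k, gamma_auc),),
    )


@dataclass
class CohortFiles:
    """Paths of everything generate_cohort wrote."""

    vcf: Path
    expression_log2: Path
    expression_linear: Path
    viability: Path
    covariates: Path
    probe_map: Path
    truth_registry: Path
    truth_auc: Path


def generate_cohort(
    spec: CohortSpec, outdir: str | Path
) -> tuple[SyntheticTruth, CohortFiles]:
    """Run all generator stages and write the full artifact set to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    G, truth = generate_genotypes(spec)
    log2, linear = generate_expression(spec, truth)
    auc = generate_true_auc(spec, truth, log2)
    viability = generate_viability(spec, auc)
    truth.half_max_dose = np.array(
        [solve_half_max_dose(a, spec.dose_grid[-1]) for a in auc]
    )

    files = CohortFiles(
        vcf=outdir / "genotypes.vcf",
        expression_log2=outdir / "expression_log2.tsv",
        expression_linear=outdir / "expression_linear.tsv",
        viability=outdir / "viability.tsv",
        covariates=outdir / "covariates.tsv",
        probe_map=outdir / "probe_map.tsv",
        truth_registry=outdir / "truth_registry.tsv",
        truth_auc=outdir / "truth_auc.tsv",
    )

    write_vcf(files.vcf, G, snp_table(spec), spec.sample_ids)
    log2.to_csv(files.expression_log2, sep="\t", float_format="%.6f")
    linear.to_csv(files.expression_linear, sep="\t", float_format="%.6f")
    viability.to_csv(files.viability, sep="\t", index=False, float_format="%.6f")

    sex = spec.rng("sex").integers(0, 2, size=spec.n_samples)
    pd.DataFrame(
        {"sample": spec.sample_ids, "sex": sex, "race": spec.race_of_sample}
    ).to_csv(files.covariates, sep="\t", index=False)
    probe_table(spec).to_csv(files.probe_map, sep="\t", index=False)
    truth.registry_frame().to_csv(files.truth_registry, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample": spec.sample_ids,
            "true_auc": auc,
            "b": INVERSION_B,
            "c": INVERSION_C,
            "d": INVERSION_D,
            "e": truth.half_max_dose,
        }
    ).to_csv(files.truth_auc, sep="\t", index=False, float_format="%.6f")

    return truth, files
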