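"""Covariate adjustment: rank-normal phenotype, stratification PCs, residuals.

The association engine correlates *adjusted* variables: the AUC phenotype is
Van der Waerden (rank inverse-normal) transformed, then every variable —
phenotype, log2 expression, and rare-allele-count genotype — is regressed on
sex, race indicators and "sub-race" population-stratification covariates (the
top-k principal components of LD-thinned genotypes computed within each race)
and replaced by its standardized residuals.  Residual rows have mean 0 and SD
1 (population convention), so downstream partial correlations are plain dot
products.

Within-race PCs are encoded race-blocked: a sample carries its own race's
scores and exact zeros in the other races' columns, which realises
"PCA within each race" inside a single pooled regression design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateTable",
    "AdjustedMatrix",
    "van_der_waerden",
    "ld_thin",
    "within_race_pca",
    "build_design",
    "residualize",
]


def van_der_waerden(values: np.ndarray) -> np.ndarray:
    """Rank inverse-normal transform: rank r of n maps to Φ⁻¹(r/(n+1)).

    Ties receive average ranks; the output depends on the input only through
    its ranks, so any strictly monotone transform of the input yields the
    identical output.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("van_der_waerden requires at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("van_der_waerden requires finite inputs")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (x.size + 1))


# ---------------------------------------------------------------------------
# LD thinning
# ---------------------------------------------------------------------------

def _impute_mean(G: np.ndarray) -> np.ndarray:
    """Float genotype matrix with per-SNP mean imputation of missing calls."""
    X = np.asarray(G, dtype=float)
    miss = np.isnan(X) | (X < 0)
    X = np.where(miss, np.nan, X)
    means = np.nanmean(X, axis=1)
    means = np.where(np.isfinite(means), means, 0.0)
    idx = np.where(miss)
    X[idx] = means[idx[0]]
    return X


def ld_thin(
    genotypes: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    window_snps: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained SNP indices (sorted).

    Within each sliding window of ``window_snps`` markers, any pair with
    squared genotype correlation > ``r2_max`` loses its lower-MAF member;
    the window advances by ``step``.  Positions must be sorted within each
    chromosome.  Missing genotypes are mean-imputed for the correlation.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    for c in np.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions unsorted within chromosome {c}")

    X = _impute_mean(genotypes)
    m = X.shape[0]
    freqs = X.mean(axis=1) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    sd = X.std(axis=1)
    keep = np.ones(m, dtype=bool)
    # zero-variance SNPs carry no LD information; retain them untouched
    order = np.lexsort((pos, chrom))

    for start in range(0, m, step):
        widx = order[start : start + window_snps]
        widx = widx[keep[widx] & (sd[widx] > 0)]
        if widx.size < 2:
            continue
        same_chrom = chrom[widx] == chrom[widx[0]]
        widx = widx[same_chrom]
        if widx.size < 2:
            continue
        Z = (X[widx] - X[widx].mean(axis=1, keepdims=True)) / sd[widx][:, None]
        R = (Z @ Z.T) / Z.shape[1]
        r2 = R**2
        for a in range(len(widx)):
            if not keep[widx[a]]:
                continue
            for b in range(a + 1, len(widx)):
                if not keep[widx[b]]:
                    continue
                if r2[a, b] > r2_max:
                    drop = widx[a] if maf[widx[a]] <= maf[widx[b]] else widx[b]
                    keep[drop] = False
                    if drop == widx[a]:
                        break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# within-race PCA
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Design inputs: sex indicator, race labels, race-blocked PC scores."""

    sample_ids: list[str]
    sex: np.ndarray
    race: np.ndarray
    pcs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.sex) != n or len(self.race) != n:
            raise ValueError("covariate columns must match sample count")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateTable":
        return cls(
            sample_ids=[str(s) for s in df["sample"]],
            sex=df["sex"].to_numpy(dtype=float),
            race=df["race"].to_numpy(dtype=object),
        )


def within_race_pca(
    genotypes: np.ndarray,
    race: np.ndarray,
    sample_ids: list[str],
    k: int = 5,
) -> pd.DataFrame:
    """Top-k genotype PCs per race, assembled into race-blocked columns.

    Per race: SNPs are standardized over that race's samples (zero-variance
    SNPs dropped, missing mean-imputed) and the top-k left singular vectors
    of the sample matrix become the scores.  A sample's columns for other
    races are exactly zero.  Column names: PC{i}_{race}.
    """
    race = np.asarray(race)
    n = len(sample_ids)
    cols = {}
    for r in pd.unique(race):
        sel = race == r
        n_r = int(sel.sum())
        if n_r <= k:
            raise ValueError(
                f"race {r!r} has {n_r} samples <= k={k}; use a smaller k"
            )
        X = _impute_mean(genotypes[:, sel])
        sd = X.std(axis=1)
        X = X[sd > 0]
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1)[:, None]
        # samples x snps orientation for the sample-space decomposition
        U, S, _ = np.linalg.svd(Z.T / np.sqrt(Z.shape[0]), full_matrices=False)
        scores = U[:, :k] * S[:k]
        for i in range(k):
            col = np.zeros(n)
            col[sel] = scores[:, i]
            cols[f"PC{i + 1}_{r}"] = col
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample"))


# ---------------------------------------------------------------------------
# design + residualization
# ---------------------------------------------------------------------------

def build_design(cov: CovariateTable) -> pd.DataFrame:
    """Pooled regression design: intercept + sex + race dummies + PC blocks.

    One race indicator is dropped against the intercept; raises naming the
    collinear columns if the assembled design is rank deficient.
    """
    n = len(cov.sample_ids)
    data = {"intercept": np.ones(n), "sex": np.asarray(cov.sex, dtype=float)}
    races = pd.unique(np.asarray(cov.race))
    for r in races[1:]:
        data[f"race_{r}"] = (np.asarray(cov.race) == r).astype(float)
    X = pd.DataFrame(data, index=pd.Index(cov.sample_ids, name="sample"))
    if cov.pcs is not None:
        X = pd.concat([X, cov.pcs], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify an offending column by greedy elimination
        cols = list(X.columns)
        culprits = []
        M = X.to_numpy()
        for j in range(M.shape[1]):
            others = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                culprits.append(cols[j])
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    return X


@dataclass
class AdjustedMatrix:
    """Standardized residual rows (mean 0, SD 1) for one variable family."""

    provenance: str  # auc | expression | genotype
    values: pd.DataFrame  # variables x samples
    n_covariates: int  # non-intercept design columns
    dropped: list[str] = field(default_factory=list)
    #: per-variable boolean mask of samples actually used (None = all)
    observed: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]


def residualize(
    variables: pd.DataFrame,
    design: pd.DataFrame,
    provenance: str,
    missing_mask: pd.DataFrame | None = None,
) -> AdjustedMatrix:
    """OLS-residualize each row of ``variables`` on ``design``, standardize.

    Rows with zero residual variance (e.g. a variable equal to a covariate
    column) are flagged and excluded with a logged reason.  When
    ``missing_mask`` marks unobserved entries (True = missing), each such row
    is residualized on its observed subsample only; missing entries are NaN
    in the output and the observed mask is carried on the result so the
    association engine can use pairwise-complete samples.
    """
    if list(variables.columns) != list(design.index):
        raise ValueError("sample ordering of variables and design must match")
    X = design.to_numpy(dtype=float)
    Y = variables.to_numpy(dtype=float)
    n_cov = design.shape[1] - int("intercept" in design.columns)

    Q, _ = np.linalg.qr(X)
    out = np.full_like(Y, np.nan, dtype=float)
    dropped: list[str] = []
    keep_rows = np.ones(Y.shape[0], dtype=bool)

    if missing_mask is None:
        complete_rows = np.ones(Y.shape[0], dtype=bool)
    else:
        mm = missing_mask.to_numpy(dtype=bool)
        complete_rows = ~mm.any(axis=1)

    # fast path: all-complete rows share one projection
    if complete_rows.any():
        Yc = Y[complete_rows]
        R = Yc - (Yc @ Q) @ Q.T
        out[complete_rows] = R

    if missing_mask is not None and (~complete_rows).any():
        for i in np.flatnonzero(~complete_rows):
            obs = ~mm[i]
            Xo = X[obs]
            Qo, _ = np.linalg.qr(Xo)
            yo = Y[i, obs]
            out[i, obs] = yo - Qo @ (Qo.T @ yo)

    # standardize to mean 0 / SD 1 over observed entries (population SD)
    for i in range(out.shape[0]):
        row = out[i]
        obs = np.isfinite(row)
        sd = row[obs].std()
        if sd <= 1e-12:
            keep_rows[i] = False
            dropped.append(str(variables.index[i]))
            continue
        out[i, obs] = (row[obs] - row[obs].mean()) / row[obs].std()

    if dropped:
        logger.info(
            "residualize[%s]: dropped %d zero-residual-variance rows (%s%s)",
            provenance, len(dropped), ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )

    values = pd.DataFrame(
        out[keep_rows], index=variables.index[keep_rows], columns=variables.columns
    )
    observed = None
    if missing_mask is not None:
        observed = ~missing_mask.loc[values.index]
    return AdjustedMatrix(
        provenance=provenance, values=values, n_covariates=n_cov,
        dropped=dropped, observed=observed,
    )
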