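"""Partial-correlation association engine with F-tests and Storey q-values.

Association between two covariate-adjusted variables (AUC phenotype,
expression probe, or SNP rare-allele count) is the Pearson correlation r of
their residual vectors — the partial correlation given sex, race and
stratification PCs.  It is tested with

    F = r^2 * df / (1 - r^2),   df = n - 2 - k,

on (1, df) degrees of freedom, k being the number of non-intercept covariate
columns charged; this equals the squared-t convention for a single regression
coefficient.  Multiple testing is handled per analysis family with Storey
q-values (fixed lambda; pi0 = 1 reduces exactly to Benjamini–Hochberg).

`PartialCorrelationScan` is the Model-style entry point: construct from two
adjusted matrices, `.fit()` computes all pairs vectorized (pairwise-complete
on genotype missingness) and returns an `AssociationResults` with the record
table, q-values and a summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import AdjustedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "PartialCorrelationScan",
    "AssociationResults",
    "partial_correlation",
    "storey_qvalues",
]

_TINY_P = np.nextafter(0.0, 1.0)  # smallest positive double; keeps -log10 finite


@dataclass
class AssociationRecord:
    """One pairwise partial-correlation test."""

    pair_type: str  # expr~auc | snp~auc | snp~expr
    id_a: str
    id_b: str
    r: float
    f_stat: float
    df_den: int
    p: float
    q: float = np.nan
    n_eff: int = 0


def _f_test(r: float, df_den: int) -> tuple[float, float]:
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        warnings.warn("degenerate fit: |r| = 1 gives p = 0", RuntimeWarning)
        return np.inf, 0.0
    f = r2 * df_den / (1.0 - r2)
    return f, float(stats.f.sf(f, 1, df_den))


def partial_correlation(
    a: np.ndarray, b: np.ndarray, n_covariates: int
) -> tuple[float, float, float]:
    """Partial correlation of two already-residualized vectors + F-test.

    Returns (r, F, p) with F on (1, n - 2 - k) degrees of freedom.  Both
    vectors must have been residualized on the same design with
    ``n_covariates`` non-intercept columns.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    n = a.size
    df = n - 2 - n_covariates
    if df < 1:
        raise ValueError(f"insufficient residual df: n={n}, k={n_covariates}")
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        raise ValueError("zero-variance vector in partial correlation")
    r = float(np.dot(a - a.mean(), b - b.mean()) / (n * sa * sb))
    r = float(np.clip(r, -1.0, 1.0))
    f, p = _f_test(r, df)
    return r, f, p


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(
    pvalues: np.ndarray, lam: float = 0.5, pi0_mode: str = "storey"
) -> np.ndarray:
    """Storey q-values at fixed lambda (no spline smoothing).

    pi0 is estimated as #{p > lambda} / (m (1 - lambda)), clamped to
    [1/m, 1]; the q-value of the i-th ordered p is the step-up minimum of
    pi0 * m * p_(j) / j over j >= i, capped at 1, returned in input order.
    ``pi0_mode='fixed-1'`` fixes pi0 = 1, which makes the output exactly the
    Benjamini–Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0_mode == "fixed-1":
        pi0 = 1.0
    elif pi0_mode == "storey":
        if not 0.0 < lam < 1.0:
            raise ValueError("lambda must lie in (0, 1)")
        pi0 = np.sum(p > lam) / (m * (1.0 - lam))
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    else:
        raise ValueError(f"unknown pi0_mode {pi0_mode!r}")

    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# all-pairs scan
# ---------------------------------------------------------------------------

class PartialCorrelationScan:
    """All-pairs partial-correlation scan between two adjusted matrices.

    Parameters
    ----------
    a, b : AdjustedMatrix
        Residualized variable families sharing the same sample ordering
        (hard error otherwise — no silent realignment).  Rows of ``a`` are
        paired with every row of ``b``.
    pair_type : str
        Family label (``snp~auc``, ``expr~auc``, ``snp~expr``) used for
        reporting and per-family q-values.
    lam, pi0_mode : Storey q-value settings.
    """

    def __init__(
        self,
        a: AdjustedMatrix,
        b: AdjustedMatrix,
        pair_type: str,
        lam: float = 0.5,
        pi0_mode: str = "storey",
    ):
        if a.sample_ids != b.sample_ids:
            raise ValueError(
                "sample-order mismatch between adjusted matrices; "
                "realign inputs explicitly before scanning"
            )
        if a.n_covariates != b.n_covariates:
            raise ValueError("both matrices must be adjusted on the same design")
        self.a, self.b = a, b
        self.pair_type = pair_type
        self.lam = lam
        self.pi0_mode = pi0_mode

    def fit(self) -> "AssociationResults":
        a, b = self.a, self.b
        n = len(a.sample_ids)
        k = a.n_covariates
        A = a.values.to_numpy(dtype=float)
        B = b.values.to_numpy(dtype=float)
        m_a, m_b = A.shape[0], B.shape[0]

        a_obs = a.observed.to_numpy(dtype=bool) if a.observed is not None else None
        b_obs = b.observed.to_numpy(dtype=bool) if b.observed is not None else None
        if b_obs is not None and not b_obs.all():
            raise ValueError(
                "second matrix may not carry missingness; put the sparse "
                "family (genotypes) first"
            )
        complete_a = (
            np.ones(m_a, dtype=bool) if a_obs is None else a_obs.all(axis=1)
        )

        # r matrix and per-row effective sample size, fully vectorized
        R = np.full((m_a, m_b), np.nan)
        n_eff = np.full(m_a, n, dtype=int)

        if complete_a.any():
            # residual rows are mean-0 SD-1, so r is a scaled dot product
            R[complete_a] = (A[complete_a] @ B.T) / n

        for ia in np.flatnonzero(~complete_a):
            # pairwise-complete: subset the partner matrix and recenter
            obs = a_obs[ia]
            ne = int(obs.sum())
            n_eff[ia] = ne
            if ne - 2 - k < 1:
                continue
            av = A[ia, obs] - A[ia, obs].mean()
            sa = av.std()
            Bo = B[:, obs] - B[:, obs].mean(axis=1, keepdims=True)
            sb = Bo.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                R[ia] = (Bo @ av) / (ne * sb * sa)

        R = np.clip(R, -1.0, 1.0)
        df = (n_eff - 2 - k)[:, None] * np.ones((1, m_b), dtype=int)
        valid = np.isfinite(R) & (df >= 1)
        if np.any(np.abs(R[valid]) >= 1.0):
            warnings.warn("degenerate fit: |r| = 1 gives p = 0", RuntimeWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = R**2 * df / (1.0 - R**2)
        P = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(valid, F, 0.0), 1, df))

        ids_a = np.repeat(np.asarray(a.values.index, dtype=object), m_b)
        ids_b = np.tile(np.asarray(b.values.index, dtype=object), m_a)
        flat_valid = valid.ravel()
        frame = pd.DataFrame(
            {
                "id_a": ids_a[flat_valid],
                "id_b": ids_b[flat_valid],
                "r": R.ravel()[flat_valid],
                "f_stat": F.ravel()[flat_valid],
                "df_den": df.ravel()[flat_valid],
                "p": P.ravel()[flat_valid],
                "n_eff": np.repeat(n_eff, m_b)[flat_valid],
            }
        )
        frame.sort_values(["id_a", "id_b"], inplace=True, kind="stable",
                          ignore_index=True)
        if len(frame):
            frame["q"] = storey_qvalues(
                frame["p"].to_numpy(), self.lam, self.pi0_mode
            )
            frame["p"] = frame["p"].clip(lower=_TINY_P)
        else:
            frame["q"] = []
        frame.insert(0, "pair_type", self.pair_type)
        logger.info(
            "scan[%s]: %d tests, %d with p < 1e-4",
            self.pair_type, len(frame), int((frame["p"] < 1e-4).sum()),
        )
        return AssociationResults(self, frame)


class AssociationResults:
    """Record table plus reporting helpers for one scan family."""

    def __init__(self, model: PartialCorrelationScan, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    def records(self) -> list[AssociationRecord]:
        return [
            AssociationRecord(
                pair_type=row.pair_type, id_a=row.id_a, id_b=row.id_b,
                r=row.r, f_stat=row.f_stat, df_den=int(row.df_den),
                p=row.p, q=row.q, n_eff=int(row.n_eff),
            )
            for row in self.frame.itertuples(index=False)
        ]

    def tier_counts(self, thresholds=(1e-3, 1e-4, 1e-5)) -> dict[float, int]:
        p = self.frame["p"].to_numpy()
        return {t: int((p < t).sum()) for t in thresholds}

    def summary(self) -> str:
        tiers = self.tier_counts()
        lines = [
            f"Partial-correlation scan: {self.model.pair_type}",
            f"tests                : {len(self.frame)}",
        ]
        for t, c in sorted(tiers.items(), reverse=True):
            lines.append(f"p < {t:g}            : {c}")
        if len(self.frame):
            lines.append(f"min p                : {self.frame['p'].min():.3g}")
            lines.append(f"min q                : {self.frame['q'].min():.3g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
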