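"""Log-logistic dose-response fitting and the AUC cytotoxicity phenotype.

The phenotype for association is the area under each cell line's fitted
viability-vs-dose curve between dose 0 and the top assay dose (320 nmol/L by
default): lower AUC means the line is more drug-sensitive.  The curve is the
four-parameter log-logistic

    f(x) = c + (d - c) / (1 + (x / e)^b),    f(0) = d by continuity,

with slope b, lower asymptote c, upper asymptote d and half-maximal dose e.
This parameterisation takes the dose-0 control point without log-transforming
dose.

`DoseResponseModel` follows the Model/Results idiom: construct from a long
viability table, call :meth:`fit`, and read estimates, diagnostics and the
AUC table off the returned :class:`DoseResponseResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseFit",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_curve",
    "compute_auc",
    "batch_phenotype",
    "InsufficientDataError",
]

#: parameter bounds keeping 9-point-grid fits identifiable:
#: c in [-0.1, 1.1], d in [0.5, 1.5], b in (0, 10], e in (0, 10 * max dose]
_BOUND_C = (-0.1, 1.1)
_BOUND_D = (0.5, 1.5)
_BOUND_B = (1e-6, 10.0)

_MIN_DISTINCT_DOSES = 5


class InsufficientDataError(ValueError):
    """Fewer than the minimum distinct doses (5, incl. dose 0) supplied."""


@dataclass
class DoseResponseFit:
    """Fitted curve and AUC phenotype for one cell line."""

    sample_id: str
    b: float
    c: float
    d: float
    e: float
    auc: float
    converged: bool
    rss: float
    n_points: int

    def predict(self, dose: np.ndarray | float) -> np.ndarray:
        """Evaluate the fitted curve; f(0) = d by continuity."""
        x = np.atleast_1d(np.asarray(dose, dtype=float))
        out = np.full_like(x, self.d)
        nz = x > 0
        out[nz] = self.c + (self.d - self.c) / (1.0 + (x[nz] / self.e) ** self.b)
        return out


def _loglogistic(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.full_like(x, d, dtype=float)
    nz = x > 0
    out[nz] = c + (d - c) / (1.0 + (x[nz] / e) ** b)
    return out if out.size > 1 else out[0]


def compute_auc(fit: DoseResponseFit, lower: float = 0.0, upper: float = 320.0) -> float:
    """Numerically integrate the fitted curve on [lower, upper] (rel tol 1e-9)."""
    if lower >= upper:
        raise ValueError(f"integration bounds require lower < upper, got [{lower}, {upper}]")
    if lower < 0:
        raise ValueError("doses are non-negative; lower bound must be >= 0")
    val, _ = quad(
        _loglogistic, lower, upper,
        args=(fit.b, fit.c, fit.d, fit.e),
        epsrel=1e-9, epsabs=1e-12, limit=200,
    )
    return float(val)


def _trapezoid_auc(doses: np.ndarray, means: np.ndarray, lower: float, upper: float) -> float:
    """Fallback phenotype: trapezoid over dose-wise mean viability.

    Integrates the piecewise-linear interpolant of the dose means clipped to
    [lower, upper]; flat extrapolation beyond the observed grid.
    """
    grid = np.unique(np.clip(np.append(doses, [lower, upper]), lower, upper))
    vals = np.interp(grid, doses, means)
    return float(np.trapezoid(vals, grid))


def fit_curve(
    viability: pd.DataFrame,
    sample_id: str = "",
    lower: float = 0.0,
    upper: float = 320.0,
) -> DoseResponseFit:
    """Least-squares log-logistic fit for one cell line's viability records.

    ``viability`` needs columns dose_nM and viability.  Initialisation: d =
    mean viability at dose 0, c = mean at the top dose, e = the dose whose
    mean viability is nearest (c+d)/2, b = 1; three perturbed restarts on
    failure.  Never raises on optimizer failure — returns converged=False
    with a trapezoid-of-dose-means fallback AUC instead.
    """
    doses = viability["dose_nM"].to_numpy(dtype=float)
    y = viability["viability"].to_numpy(dtype=float)
    if np.any(doses < 0):
        raise ValueError("negative doses are invalid")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("viability values must be finite and >= 0")
    distinct = np.unique(doses)
    if distinct.size < _MIN_DISTINCT_DOSES or 0.0 not in distinct:
        raise InsufficientDataError(
            f"need >= {_MIN_DISTINCT_DOSES} distinct doses including dose 0, "
            f"got {distinct.size}"
        )

    max_dose = float(distinct.max())
    dose_means = np.array([y[doses == dd].mean() for dd in distinct])
    d0 = float(np.clip(dose_means[0], *_BOUND_D))
    c0 = float(np.clip(dose_means[-1], *_BOUND_C))
    half = (c0 + d0) / 2.0
    inner = distinct[distinct > 0]
    inner_means = dose_means[distinct > 0]
    e0 = float(inner[np.argmin(np.abs(inner_means - half))])
    bound_e = (1e-6, 10.0 * max_dose)

    def resid(theta: np.ndarray) -> np.ndarray:
        return _loglogistic(doses, *theta) - y

    lo = np.array([_BOUND_B[0], _BOUND_C[0], _BOUND_D[0], bound_e[0]])
    hi = np.array([_BOUND_B[1], _BOUND_C[1], _BOUND_D[1], bound_e[1]])
    starts = [np.array([1.0, c0, d0, e0])]
    rng = np.random.default_rng(0)
    for _ in range(3):
        jitter = np.array(
            [np.exp(rng.normal(0, 0.5)), c0 + rng.normal(0, 0.1),
             d0 + rng.normal(0, 0.1), e0 * np.exp(rng.normal(0, 0.7))]
        )
        starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=2000)
        except Exception:  # pragma: no cover - scipy raises only on bad input
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None:
            break  # perturbed restarts are for optimizer failure only

    if best is None:
        auc = _trapezoid_auc(distinct, dose_means, lower, upper)
        return DoseResponseFit(sample_id, np.nan, np.nan, np.nan, np.nan,
                               auc, False, float(np.sum((y - y.mean()) ** 2)),
                               int(y.size))

    b, c, d, e = (float(v) for v in best.x)
    fit = DoseResponseFit(sample_id, b, c, d, e, np.nan, True,
                          float(2.0 * best.cost), int(y.size))
    fit.auc = compute_auc(fit, lower, upper)
    return fit


class DoseResponseModel:
    """Per-cell-line log-logistic dose-response model for a viability table.

    Parameters
    ----------
    data : DataFrame with columns sample, dose_nM, replicate, viability.
    lower, upper : integration bounds of the AUC phenotype in nmol/L.
    """

    def __init__(self, data: pd.DataFrame, lower: float = 0.0, upper: float = 320.0):
        required = {"sample", "dose_nM", "replicate", "viability"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"viability table missing columns: {sorted(missing)}")
        dup = data.duplicated(["sample", "dose_nM", "replicate"])
        if dup.any():
            offenders = data.loc[dup, ["sample", "dose_nM", "replicate"]]
            raise ValueError(
                "duplicate (sample, dose, replicate) triplets:\n"
                + offenders.to_string(index=False)
            )
        if lower >= upper:
            raise ValueError("lower must be < upper")
        self.data = data
        self.lower = float(lower)
        self.upper = float(upper)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "DoseResponseModel":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def fit(self) -> "DoseResponseResults":
        fits = []
        for sample, grp in self.data.groupby("sample", sort=True):
            fits.append(fit_curve(grp, str(sample), self.lower, self.upper))
        results = DoseResponseResults(self, fits)
        if fits:
            logger.info(
                "dose-response: %d samples, %.1f%% converged",
                len(fits), 100.0 * results.convergence_rate,
            )
        else:
            logger.warning("dose-response: empty viability table, no samples fit")
        return results


class DoseResponseResults:
    """Fitted curves, AUC phenotypes and convergence diagnostics."""

    def __init__(self, model: DoseResponseModel, fits: list[DoseResponseFit]):
        self.model = model
        self.fits = fits

    @property
    def convergence_rate(self) -> float:
        if not self.fits:
            return float("nan")
        return sum(f.converged for f in self.fits) / len(self.fits)

    @property
    def auc(self) -> pd.Series:
        return pd.Series({f.sample_id: f.auc for f in self.fits}, name="auc")

    def frame(self) -> pd.DataFrame:
        """AUC table: sample_id, auc, b, c, d, e, converged, rss, n_points."""
        return pd.DataFrame(
            [
                {
                    "sample_id": f.sample_id, "auc": f.auc, "b": f.b, "c": f.c,
                    "d": f.d, "e": f.e, "converged": f.converged, "rss": f.rss,
                    "n_points": f.n_points,
                }
                for f in self.fits
            ]
        )

    def summary(self) -> str:
        df = self.frame()
        lines = [
            "Dose-response AUC phenotype",
            "===========================",
            f"samples fitted     : {len(df)}",
        ]
        if len(df):
            lines += [
                f"converged          : {int(df.converged.sum())} "
                f"({100 * self.convergence_rate:.1f}%)",
                f"AUC integration    : [{self.model.lower:g}, {self.model.upper:g}] nmol/L",
                f"AUC mean (sd)      : {df.auc.mean():.2f} ({df.auc.std():.2f})",
                f"AUC range          : [{df.auc.min():.2f}, {df.auc.max():.2f}]",
            ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def batch_phenotype(
    viability: pd.DataFrame | str | Path,
    lower: float = 0.0,
    upper: float = 320.0,
) -> pd.DataFrame:
    """Convenience wrapper: viability table (or TSV path) -> AUC table."""
    if not isinstance(viability, pd.DataFrame):
        viability = pd.read_csv(viability, sep="\t")
    if viability.empty:
        logger.warning("batch_phenotype: empty viability input")
        return pd.DataFrame(
            columns=["sample_id", "auc", "b", "c", "d", "e", "converged", "rss", "n_points"]
        )
    return DoseResponseModel(viability, lower, upper).fit().frame()
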