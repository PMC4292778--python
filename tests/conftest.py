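"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from pgx_triangulate.cohort import (
    CohortSpec, generate_expression, generate_genotypes, generate_true_auc,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Compact cohort for fast unit tests (full 278 samples, few markers)."""
    return CohortSpec(
        m_snps=60,
        m_probes=30,
        planted_eqtls=((3, 2, 1.0),),
        planted_expr_auc=((2, 40.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(genotypes, truth, log2 expression, linear expression, true AUC)."""
    G, truth = generate_genotypes(small_spec)
    log2, linear = generate_expression(small_spec, truth)
    auc = generate_true_auc(small_spec, truth, log2)
    return G, truth, log2, linear, auc


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_viability(doses, params, n_rep=3, noise_sd=0.0, rng=None, sample="S1"):
    """Long-format viability table from exact log-logistic parameters."""
    b, c, d, e = params
    doses = np.asarray(doses, dtype=float)
    curve = np.where(doses > 0, c + (d - c) / (1 + (doses / e) ** b), d)
    rows = []
    for rep in range(1, n_rep + 1):
        v = curve.copy()
        if noise_sd > 0:
            v = np.clip(v + rng.normal(0, noise_sd, size=v.size), 0, None)
        rows += [(sample, dd, rep, vv) for dd, vv in zip(doses, v)]
    return pd.DataFrame(rows, columns=["sample", "dose_nM", "replicate", "viability"])
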