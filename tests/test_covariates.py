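"""Covariate engine: rank-normal transform, LD thinning, PCA, residuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pgx_triangulate.cohort import CohortSpec, generate_genotypes, snp_table
from pgx_triangulate.covariates import (
    CovariateTable, build_design, ld_thin, residualize, van_der_waerden,
    within_race_pca,
)


# ---------------------------------------------------------------------------
# Van der Waerden transform
# ---------------------------------------------------------------------------

def test_vdw_maps_ranks_to_normal_quantiles():
    """[5, 1, 9] has ranks (2, 1, 3) -> quantiles at (0.5, 0.25, 0.75)."""
    out = van_der_waerden(np.array([5.0, 1.0, 9.0]))
    expected = stats.norm.ppf([0.5, 0.25, 0.75])
    assert np.allclose(out, expected, atol=1e-3)
    assert out[0] == pytest.approx(0.0, abs=1e-12)
    assert out[2] == pytest.approx(0.6745, abs=1e-3)


def test_vdw_ties_get_average_ranks():
    """Tied pair among 3 values: average rank 1.5 maps to Phi^-1(1.5/4)."""
    out = van_der_waerden(np.array([3.0, 3.0, 7.0]))
    tied = stats.norm.ppf(1.5 / 4)
    assert out[0] == pytest.approx(tied, rel=1e-12)
    assert out[1] == pytest.approx(tied, rel=1e-12)
    assert out[2] == pytest.approx(stats.norm.ppf(3 / 4), rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60, unique=True))
def test_vdw_rank_invariance(values):
    """Any strictly monotone transform of the input gives identical output."""
    # round + dedupe so the transform below stays injective in float64
    x = np.unique(np.round(np.asarray(values), 3))
    if x.size < 3:
        return
    direct = van_der_waerden(x)
    monotone = van_der_waerden(np.arctan(x / 1e6) * 3 + 7)
    assert np.allclose(direct, monotone, atol=1e-12)


def test_vdw_output_close_to_standard_normal(rng):
    """KS distance to N(0,1) stays below 2/sqrt(n) on continuous input."""
    x = rng.gamma(2.0, 3.0, size=500)  # deliberately skewed input
    out = van_der_waerden(x)
    d = stats.kstest(out, "norm").statistic
    assert d <= 2 / np.sqrt(x.size)


def test_vdw_input_validation():
    with pytest.raises(ValueError):
        van_der_waerden(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        van_der_waerden(np.array([1.0, np.nan, 2.0]))


# ---------------------------------------------------------------------------
# LD thinning
# ---------------------------------------------------------------------------

def test_ld_thin_drops_one_of_perfect_pair(rng):
    g = rng.binomial(2, 0.4, size=(1, 100))
    G = np.vstack([g, g])  # r^2 = 1
    kept = ld_thin(G, np.ones(2), np.array([100, 200]))
    assert kept.size == 1


def test_ld_thin_keeps_independent_snps(rng):
    G = rng.binomial(2, 0.3, size=(30, 4000))  # r^2 ~ 1/n, far below 0.2
    kept = ld_thin(G, np.ones(30), np.arange(30) * 1000)
    assert kept.size == 30


def test_ld_thin_requires_sorted_positions(rng):
    G = rng.binomial(2, 0.3, size=(3, 50))
    with pytest.raises(ValueError, match="unsorted"):
        ld_thin(G, np.ones(3), np.array([300, 100, 200]))


def test_ld_thin_leaves_no_high_r2_pair(rng):
    """Brute-force pair recheck: no retained within-window pair above r2."""
    n, m = 120, 200
    base = rng.binomial(2, 0.3, size=(m, n)).astype(float)
    # plant correlated duplicates: every 10th SNP copies its neighbour
    for i in range(0, m - 1, 10):
        flip = rng.random(n) < 0.05
        base[i + 1] = np.where(flip, rng.binomial(2, 0.3, n), base[i])
    chrom, pos = np.ones(m), np.arange(m) * 500
    window, r2_max = 50, 0.2
    kept = ld_thin(base, chrom, pos, window_snps=window, r2_max=r2_max)
    Z = base[kept]
    Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
    R2 = ((Z @ Z.T) / n) ** 2
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            if abs(int(kept[a]) - int(kept[b])) < window:
                assert R2[a, b] <= r2_max + 1e-9


# ---------------------------------------------------------------------------
# within-race PCA
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pca_inputs():
    spec = CohortSpec(m_snps=500, m_probes=1, fst=0.05, missing_rate=0.0, seed=21)
    G, _ = generate_genotypes(spec)
    return spec, G


def test_pca_scores_orthogonal_and_variance_ordered(pca_inputs):
    spec, G = pca_inputs
    pcs = within_race_pca(G, spec.race_of_sample, spec.sample_ids, k=5)
    race = spec.race_of_sample
    for r in spec.race_labels:
        block = pcs.loc[race == r, [f"PC{i}_{r}" for i in range(1, 6)]].to_numpy()
        gram = block.T @ block
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        variances = np.diag(gram)
        assert np.all(np.diff(variances) <= 1e-9)  # non-increasing


def test_pca_race_blocking_is_exact_zero(pca_inputs):
    spec, G = pca_inputs
    pcs = within_race_pca(G, spec.race_of_sample, spec.sample_ids, k=3)
    race = spec.race_of_sample
    for r in spec.race_labels:
        other = pcs.loc[race != r, [f"PC{i}_{r}" for i in range(1, 4)]]
        assert (other.to_numpy() == 0.0).all()


def test_design_has_15_pc_columns_plus_sex_and_race(pca_inputs):
    """k=5 across 3 races: 15 PC columns + intercept + sex + 2 race dummies."""
    spec, G = pca_inputs
    cov = CovariateTable(
        sample_ids=spec.sample_ids,
        sex=np.tile([0.0, 1.0], spec.n_samples)[: spec.n_samples],
        race=spec.race_of_sample,
    )
    cov.pcs = within_race_pca(G, cov.race, spec.sample_ids, k=5)
    design = build_design(cov)
    assert sum(c.startswith("PC") for c in design.columns) == 15
    assert design.shape[1] == 1 + 1 + 2 + 15
    assert np.linalg.matrix_rank(design.to_numpy()) == design.shape[1]


def test_pca_k_too_large_for_race():
    spec = CohortSpec(n_per_race=(4, 50, 50), m_snps=50, m_probes=1, seed=3)
    G, _ = generate_genotypes(spec)
    with pytest.raises(ValueError, match="smaller k"):
        within_race_pca(G, spec.race_of_sample, spec.sample_ids, k=5)


def test_pc1_separates_hidden_subpopulations(rng):
    """Two sub-groups at Fst 0.05 inside one labelled race: PC1 finds them."""
    n, m = 90, 2000
    labels = np.array([0] * 45 + [1] * 45)
    F = 0.05
    p_anc = rng.uniform(0.1, 0.5, size=m)
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    p_sub = rng.beta(a[:, None], b[:, None], size=(m, 2))
    G = np.empty((m, n), dtype=np.int8)
    for s in range(n):
        G[:, s] = rng.binomial(2, p_sub[:, labels[s]])
    ids = [f"S{i}" for i in range(n)]
    pcs = within_race_pca(G, np.array(["X"] * n), ids, k=2)
    r = np.corrcoef(pcs["PC1_X"], labels)[0, 1]
    assert abs(r) > 0.8


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def _toy_design(n, rng):
    cov = CovariateTable(
        sample_ids=[f"S{i}" for i in range(n)],
        sex=rng.integers(0, 2, n).astype(float),
        race=np.array(["A"] * (n // 2) + ["B"] * (n - n // 2)),
    )
    return build_design(cov)


def test_residualize_flags_collinear_variable(rng):
    design = _toy_design(40, rng)
    vars_ = pd.DataFrame(
        [design["sex"].to_numpy()], index=["dup_sex"], columns=design.index
    )
    adj = residualize(vars_, design, "auc")
    assert adj.dropped == ["dup_sex"]
    assert adj.values.empty


def test_residualize_orthogonal_variable_passes_through(rng):
    n = 60
    design = _toy_design(n, rng)
    Q, _ = np.linalg.qr(design.to_numpy())
    v = rng.normal(size=n)
    v -= Q @ (Q.T @ v)  # exactly orthogonal to the design
    vars_ = pd.DataFrame([v], index=["v"], columns=design.index)
    adj = residualize(vars_, design, "auc")
    expected = (v - v.mean()) / v.std()
    assert np.allclose(adj.values.iloc[0].to_numpy(), expected, atol=1e-10)


def test_residualize_matches_pseudoinverse_oracle(rng):
    """50 x 278 fixture equals an independent pinv-based least squares."""
    n, m = 278, 50
    design = _toy_design(n, rng)
    X = design.to_numpy()
    Y = rng.normal(size=(m, n))
    vars_ = pd.DataFrame(Y, index=[f"v{i}" for i in range(m)],
                         columns=design.index)
    adj = residualize(vars_, design, "expression")
    beta = np.linalg.pinv(X) @ Y.T
    resid = Y - (X @ beta).T
    oracle = (resid - resid.mean(1, keepdims=True)) / resid.std(1, keepdims=True)
    assert np.allclose(adj.values.to_numpy(), oracle, atol=1e-8)


def test_residual_rows_standardized_and_orthogonal_to_design(rng):
    n = 100
    design = _toy_design(n, rng)
    Y = rng.normal(size=(20, n))
    adj = residualize(pd.DataFrame(Y, index=[f"v{i}" for i in range(20)],
                                   columns=design.index), design, "expression")
    V = adj.values.to_numpy()
    assert np.allclose(V.mean(axis=1), 0.0, atol=1e-8)
    assert np.allclose(V.std(axis=1), 1.0, atol=1e-8)
    X = design.to_numpy()
    cross = V @ X / n
    assert np.max(np.abs(cross)) < 1e-6


def test_residualize_pairwise_missing_uses_observed_subset(rng):
    n = 50
    design = _toy_design(n, rng)
    y = rng.normal(size=n)
    miss = np.zeros(n, dtype=bool)
    miss[[3, 17, 31]] = True
    vars_ = pd.DataFrame([y], index=["g"], columns=design.index)
    mask = pd.DataFrame([miss], index=["g"], columns=design.index)
    adj = residualize(vars_, design, "genotype", missing_mask=mask)
    row = adj.values.iloc[0].to_numpy()
    assert np.isnan(row[miss]).all()
    obs = ~miss
    Xo = design.to_numpy()[obs]
    yo = y[obs]
    resid = yo - Xo @ (np.linalg.pinv(Xo) @ yo)
    oracle = (resid - resid.mean()) / resid.std()
    assert np.allclose(row[obs], oracle, atol=1e-8)
    assert adj.observed.iloc[0].sum() == n - 3


def test_build_design_rejects_rank_deficiency(rng):
    n = 30
    cov = CovariateTable(
        sample_ids=[f"S{i}" for i in range(n)],
        sex=np.ones(n),  # constant sex column collides with the intercept
        race=np.array(["A"] * 15 + ["B"] * 15),
    )
    with pytest.raises(ValueError, match="collinear"):
        build_design(cov)
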