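"""Gene-environment screen: spline basis, nested LRTs, scan behavior."""

import numpy as np
import pandas as pd
import pytest

from scipy.interpolate import BSpline

from gwaskit import gxe
from gwaskit.gxe import GxEModelSpec, default_specs, gxe_scan, lrt_nested, spline_basis
from gwaskit._glm import fit_logistic

from conftest import make_gm


# ---------------------------------------------------------------------------
# spline basis

def _natural_spline_space(x, knots):
    """Independent natural-cubic-spline construction: full cubic B-spline
    basis on the knots, restricted to the subspace with zero second
    derivative at both boundary knots."""
    t = np.concatenate([[knots[0]] * 4, knots[1:-1], [knots[-1]] * 4])
    n_basis = len(t) - 4
    cols = []
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        cols.append(BSpline(t, c, 3)(x))
    B = np.column_stack(cols)
    # constraint matrix: second derivative at the two boundary knots is zero
    bounds = np.array([knots[0], knots[-1]], dtype=float)
    d2 = np.vstack([
        [BSpline(t, np.eye(n_basis)[i], 3).derivative(2)(b) for i in range(n_basis)]
        for b in bounds
    ])
    u, s, vh = np.linalg.svd(d2)
    ns = vh[np.sum(s > 1e-10):].T  # null space of the constraints
    return B @ ns  # columns span the natural splines (incl. constant)


def test_basis_full_rank_on_increasing_env():
    x = np.linspace(-2, 2, 100)
    b = spline_basis(x)
    assert b.shape == (100, 3)
    assert np.linalg.matrix_rank(np.column_stack([np.ones(100), b])) == 4


def test_basis_spans_natural_spline_space():
    """The truncated-power basis must span the same function space as an
    independently constructed B-spline natural basis on the same knots."""
    rng = np.random.default_rng(0)
    x = np.sort(rng.standard_normal(200))
    interior = np.quantile(x, [1 / 3, 2 / 3])
    knots = np.array([x.min(), *interior, x.max()])
    ours = np.column_stack([np.ones(len(x)), spline_basis(x)])
    ref = _natural_spline_space(x, knots)
    # project each reference column onto ours: residual must vanish
    proj = ours @ np.linalg.lstsq(ours, ref, rcond=None)[0]
    assert np.max(np.abs(proj - ref)) < 1e-8
    # and vice versa (equal 4-dimensional spaces)
    proj2 = ref @ np.linalg.lstsq(ref, ours, rcond=None)[0]
    assert np.max(np.abs(proj2 - ours)) < 1e-8


def test_basis_too_few_distinct_values_errors():
    with pytest.raises(ValueError):
        spline_basis(np.array([1.0, 1.0, 2.0, 2.0]))


def test_affine_env_transform_leaves_lrt_invariant():
    rng = np.random.default_rng(1)
    n = 400
    g = rng.integers(0, 3, n).astype(float)
    e = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * g * e - 0.5)))).astype(float)

    def stat(env, coding):
        ecols = gxe._env_columns(env, coding)
        one = np.ones((n, 1))
        X_main = np.column_stack([one, ecols, g])
        X_full = np.column_stack([X_main, g[:, None] * ecols])
        return lrt_nested(X_full, X_main, y)["statistic"]

    for coding in ("linear", "spline3"):
        s1 = stat(e, coding)
        s2 = stat(3.0 * e + 7.0, coding)
        assert s1 == pytest.approx(s2, abs=1e-5)


# ---------------------------------------------------------------------------
# nested LRT

def test_identical_models_zero_statistic():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(200), rng.standard_normal(200)])
    y = rng.integers(0, 2, 200).astype(float)
    res = lrt_nested(X, X, y)
    assert res["statistic"] == pytest.approx(0.0, abs=1e-8)
    assert res["p"] == 1.0


def test_non_nested_specs_error():
    X = np.ones((10, 2))
    with pytest.raises(ValueError):
        lrt_nested(X, X, np.zeros(10), full_cols=["a", "b"], null_cols=["c"])
    with pytest.raises(ValueError):
        lrt_nested(np.ones((10, 1)), np.ones((10, 2)), np.zeros(10))


def test_lrt_statistic_independent_of_start():
    rng = np.random.default_rng(3)
    n = 300
    X_full = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = (rng.random(n) < 0.4).astype(float)
    f1 = fit_logistic(X_full, y)
    f2 = fit_logistic(X_full, y, start=np.array([2.0, -1.0, 1.0]))
    assert f1.llf == pytest.approx(f2.llf, abs=1e-6)


def test_null_lrt_type_i_error_calibrated():
    """1-df interaction LRT on null data: empirical size near 0.05
    (400 replicates, 99% binomial band)."""
    rng = np.random.default_rng(4)
    n = 300
    hits = 0
    reps = 400
    for _ in range(reps):
        g = rng.integers(0, 3, n).astype(float)
        e = rng.standard_normal(n)
        y = (rng.random(n) < 0.33).astype(float)
        one = np.ones((n, 1))
        X_main = np.column_stack([one, e, g])
        X_full = np.column_stack([X_main, g * e])
        if lrt_nested(X_full, X_main, y)["p"] < 0.05:
            hits += 1
    assert 0.05 * reps - 2.58 * np.sqrt(reps * 0.05 * 0.95) <= hits \
        <= 0.05 * reps + 2.58 * np.sqrt(reps * 0.05 * 0.95)


# ---------------------------------------------------------------------------
# the four-model scan

def _pheno(n, rng):
    return pd.DataFrame({
        "alcohol": rng.standard_normal(n),
        "age": rng.normal(60, 5, n),
        "smoke": rng.integers(0, 2, n).astype(float),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "pc3": rng.standard_normal(n),
    })


def test_spec_df_accounting():
    assert GxEModelSpec("e", "linear", "interaction_only").df == 1
    assert GxEModelSpec("e", "linear", "joint").df == 2
    assert GxEModelSpec("e", "spline3", "interaction_only").df == 3
    assert GxEModelSpec("e", "spline3", "joint").df == 4
    with pytest.raises(ValueError):
        GxEModelSpec("e", "quadratic", "joint")


def test_joint_statistic_dominates_interaction_only():
    rng = np.random.default_rng(5)
    n = 500
    g = rng.integers(0, 3, n).astype(float)
    e = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * g + 0.4 * g * e - 0.7)))).astype(float)
    one = np.ones((n, 1))
    ecol = e[:, None]
    X_base = np.column_stack([one, ecol])
    X_main = np.column_stack([X_base, g])
    X_full = np.column_stack([X_main, g[:, None] * ecol])
    s_joint = lrt_nested(X_full, X_base, y)["statistic"]
    s_int = lrt_nested(X_full, X_main, y)["statistic"]
    assert s_joint >= s_int


def test_pure_interaction_snp_flagged_without_main_effect(small_study):
    """A simulated pure-interaction SNP should light up the interaction
    models while its marginal main-effect p stays unremarkable."""
    cfg, study = small_study
    c = study.cohorts["cohort_f"]
    target = study.truth["gxe_snps"]
    sub = c.genotypes.subset_snps(target)
    specs = default_specs("alcohol", covariates=("age", "smoke"))
    tab = gxe_scan(sub, c.phenotypes["status"].to_numpy(), c.phenotypes, specs)
    best_int = tab[[f"p_model{i}" for i in (1, 3)]].min(axis=1)
    assert (best_int < 0.05).any()
    assert (tab["main_effect_p"] > 0.001).all()


def test_zero_effect_scan_no_flags():
    rng = np.random.default_rng(6)
    n = 300
    gm = make_gm(rng.integers(0, 3, size=(n, 30)).astype(np.int8))
    pheno = _pheno(n, rng)
    y = rng.integers(0, 2, n)
    specs = default_specs("alcohol")
    tab = gxe_scan(gm, y, pheno, specs)
    assert not tab["significant_any"].any()
    assert set(tab.columns) >= {"p_model1", "p_model2", "p_model3", "p_model4", "main_effect_p"}


def test_invalid_spec_rejected_before_scan():
    rng = np.random.default_rng(7)
    gm = make_gm(rng.integers(0, 3, size=(20, 2)).astype(np.int8))
    pheno = _pheno(20, rng)
    specs = {1: GxEModelSpec("nonexistent_env", "linear", "joint")}
    with pytest.raises(ValueError, match="nonexistent_env"):
        gxe_scan(gm, np.zeros(20), pheno, specs)
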