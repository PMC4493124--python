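"""ANOVA variance components, RR-BLUP solvers, GEBV prediction, accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibmgs import (
    PlotPhenotypes,
    VarianceEstimates,
    accuracy,
    estimate_variance_anova,
    fit_rrblup,
    predict_gebv,
)


def _plots(values_by_line):
    rows = [
        (line, f"r{k + 1}", v)
        for line, vals in values_by_line.items()
        for k, v in enumerate(vals)
    ]
    return PlotPhenotypes(pd.DataFrame(rows, columns=["line", "replicate", "value"]))


def test_anova_zero_within_variance():
    var = estimate_variance_anova(_plots({"a": [5, 5], "b": [9, 9], "c": [1, 1]}))
    assert var.Ve == 0.0
    assert var.h2 == 1.0


def test_anova_hand_table():
    """3 lines x 2 reps (10,12 | 20,22 | 30,32): textbook one-way arithmetic."""
    var = estimate_variance_anova(
        _plots({"a": [10, 12], "b": [20, 22], "c": [30, 32]}))
    assert var.Ve == pytest.approx(2.0)  # MS_within
    assert var.Vg == pytest.approx((200.0 - 2.0) / 2.0)  # (MS_between - MSW)/r
    assert var.h2 == pytest.approx(99.0 / (99.0 + 1.0))
    assert var.n_reps == pytest.approx(2.0)


def test_anova_matches_statsmodels_oracle():
    statsmodels = pytest.importorskip("statsmodels.api")
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(13)
    lines = [f"l{i}" for i in range(12)]
    data = {l: list(10 * rng.standard_normal(3) + 5 * i) for i, l in enumerate(lines)}
    plots = _plots(data)
    var = estimate_variance_anova(plots)

    fit = ols("value ~ C(line)", data=plots.table).fit()
    tab = anova_lm(fit)
    ms_between = tab.loc["C(line)", "mean_sq"]
    ms_within = tab.loc["Residual", "mean_sq"]
    assert var.Ve == pytest.approx(ms_within, rel=1e-10)
    assert var.Vg == pytest.approx(max(0.0, (ms_between - ms_within) / 3.0), rel=1e-10)


def test_anova_single_replicate_rejected():
    with pytest.raises(ValueError, match="supply h"):
        estimate_variance_anova(_plots({"a": [1], "b": [2], "c": [3]}))


def test_anova_truncates_negative_vg():
    rng = np.random.default_rng(14)
    # pure noise with huge within-line spread: MS_between < MS_within happens
    vgs = []
    for _ in range(20):
        data = {f"l{i}": list(rng.standard_normal(4)) for i in range(5)}
        vgs.append(estimate_variance_anova(_plots(data)).Vg)
    assert min(vgs) == 0.0  # truncation engaged at least once
    assert all(v >= 0 for v in vgs)


# --- RR-BLUP ----------------------------------------------------------------


def _mme_oracle(X, y, lam):
    """Direct dense solve of the mixed-model equations with unpenalized mu."""
    n_p, n_m = X.shape
    lhs = np.zeros((1 + n_m, 1 + n_m))
    lhs[0, 0] = n_p
    lhs[0, 1:] = X.sum(axis=0)
    lhs[1:, 0] = X.sum(axis=0)
    lhs[1:, 1:] = X.T @ X + lam * np.eye(n_m)
    rhs = np.concatenate([[y.sum()], X.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


def test_fit_matches_dense_mme_oracle():
    """4 lines x 2 markers, lambda = 2: independent 3x3 system solve."""
    X = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=float)
    y = np.array([1.0, 2.0, 2.5, 4.0])
    mu_o, g_o = _mme_oracle(X, y, 2.0)
    for solver in ("primal", "dual"):
        fit = fit_rrblup(X, y, lam=2.0, solver=solver)
        assert fit.mu == pytest.approx(mu_o, rel=1e-10)
        assert np.allclose(fit.g, g_o, rtol=1e-10)


def test_infinite_shrinkage_limit():
    rng = np.random.default_rng(15)
    X = 2.0 * rng.integers(0, 2, size=(20, 30))
    y = rng.standard_normal(20)
    fit = fit_rrblup(X, y, lam=1e12)
    assert np.max(np.abs(fit.g)) < 1e-6 * np.std(y)
    assert fit.mu == pytest.approx(y.mean(), abs=1e-6)


def test_constant_y_gives_zero_effects():
    X = np.array([[0, 2, 0], [2, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
    fit = fit_rrblup(X, np.full(4, 3.25), lam=1.5)
    assert np.all(fit.g == 0.0)
    assert fit.mu == 3.25


def test_lambda_validation():
    X = np.array([[0.0, 2.0], [2.0, 0.0]])
    y = np.array([1.0, 2.0])
    with pytest.raises(ValueError, match="lambda"):
        fit_rrblup(X, y, lam=0.0)
    with pytest.raises(ValueError, match="lambda"):
        fit_rrblup(X, y, lam=-1.0)
    var = VarianceEstimates(Vg=0.0, Ve=1.0, h2=0.5, n_reps=2)
    with pytest.raises(ValueError, match="Vg"):
        fit_rrblup(X, y, var=var)


@pytest.mark.parametrize("n_p,n_m,seed", [(10, 5, 0), (15, 40, 1), (60, 200, 2)])
def test_primal_dual_agreement(n_p, n_m, seed):
    rng = np.random.default_rng(seed)
    X = 2.0 * rng.integers(0, 2, size=(n_p, n_m))
    y = rng.standard_normal(n_p)
    fa = fit_rrblup(X, y, lam=3.7, solver="primal")
    fb = fit_rrblup(X, y, lam=3.7, solver="dual")
    scale = max(1.0, np.max(np.abs(fa.g)))
    assert np.max(np.abs(fa.g - fb.g)) / scale < 1e-8
    assert fa.mu == pytest.approx(fb.mu, abs=1e-8)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_shrinkage_monotonicity(seed):
    rng = np.random.default_rng(seed)
    X = 2.0 * rng.integers(0, 2, size=(12, 20))
    y = rng.standard_normal(12)
    norms = [
        np.linalg.norm(fit_rrblup(X, y, lam=lam).g)
        for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_gblup_equivalence():
    """Marker-effect predictions equal the genomic-relationship formulation."""
    rng = np.random.default_rng(16)
    X = 2.0 * rng.integers(0, 2, size=(30, 300))
    y = X[:, :10] @ rng.standard_normal(10) + rng.standard_normal(30)
    X_new = 2.0 * rng.integers(0, 2, size=(8, 300))
    lam = 12.0
    fit = fit_rrblup(X, y, lam=lam)
    pred = predict_gebv(fit, X_new)

    mean = X.mean(axis=0)
    Xc, yc = X - mean, y - y.mean()
    K = Xc @ Xc.T + lam * np.eye(30)
    pred_gblup = y.mean() + (X_new - mean) @ Xc.T @ np.linalg.solve(K, yc)
    assert np.max(np.abs(pred - pred_gblup)) < 1e-8


def test_predict_reproduces_fitted_values_full_rank():
    rng = np.random.default_rng(17)
    X = 2.0 * rng.integers(0, 2, size=(40, 6))
    y = rng.standard_normal(40)
    fit = fit_rrblup(X, y, lam=1e-8)
    # lambda -> 0 with N_P > N_M: ridge fit approaches OLS fitted values
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(40), X]), y, rcond=None)
    assert np.allclose(predict_gebv(fit, X),
                       np.column_stack([np.ones(40), X]) @ beta, atol=1e-5)


def test_predict_hand_toy_and_zero_line():
    from ibmgs.rrblup import RRBlupFit

    fit = RRBlupFit(mu=1.0, g=np.array([0.5, -0.25]), lam=1.0,
                    marker_ids=("m1", "m2"), training_ids=(), solver="primal")
    pred = predict_gebv(fit, np.array([[2.0, 2.0], [0.0, 0.0]]))
    assert pred[0] == pytest.approx(1.5)
    assert pred[1] == pytest.approx(1.0)  # all-zero genotype -> intercept


def test_predict_marker_mismatch(toy_genotypes):
    fit = fit_rrblup(toy_genotypes, np.array([1.0, 2.0, 3.0, 4.0]), lam=1.0)
    other = toy_genotypes.subset_markers(["a", "b"])
    with pytest.raises(ValueError, match="marker set mismatch"):
        predict_gebv(fit, other)


# --- accuracy ---------------------------------------------------------------


def test_accuracy_formula_values():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    res = accuracy(obs, obs, h2=0.64)
    assert res.r_MP == pytest.approx(1.0)
    assert res.r_MG == pytest.approx(1.0 / 0.8)
    res2 = accuracy(obs, obs[::-1], h2=1.0)
    assert res2.r_MG == res2.r_MP  # h2 = 1 -> identity


def test_accuracy_zero_variance_warns_nan():
    with pytest.warns(UserWarning, match="zero variance"):
        res = accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], h2=0.8)
    assert np.isnan(res.r_MP) and np.isnan(res.r_MG)


def test_accuracy_input_validation():
    with pytest.raises(ValueError, match="3 paired"):
        accuracy([1.0, 2.0], [1.0, 2.0], h2=0.5)
    with pytest.raises(ValueError, match="h2"):
        accuracy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], h2=0.0)
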