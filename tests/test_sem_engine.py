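import numpy as np
import pandas as pd
import pytest

from raclmap import (Constraint, HierarchicalFactorModel, ModelSpec,
                     build_anatomical_spec, fml_discrepancy, implied_moments)
from raclmap.sem.engine import ParamTable, _Objective, fit_ml_raw, smart_start


def _toy_spec(mean=False):
    """Two correlated first-order factors, no second order."""
    return ModelSpec(
        indicators=("x1", "x2", "x3", "x4"),
        first_order={"F1": {"x1": 1.0, "x2": "free"},
                     "F2": {"x3": 1.0, "x4": "free"}},
        second_order={},
        mean_structure=mean,
        name="toy")


def test_implied_moments_hand_computed():
    spec = _toy_spec()
    theta = {"lam1[x2~F1]": 0.8, "lam1[x4~F2]": 1.2,
             "psi[F1]": 2.0, "psi[F2]": 1.0,
             "theta[x1]": 0.5, "theta[x2]": 0.5,
             "theta[x3]": 0.4, "theta[x4]": 0.4}
    sigma, mu = implied_moments(spec, theta)
    lam = np.array([[1.0, 0.0], [0.8, 0.0], [0.0, 1.0], [0.0, 1.2]])
    # psi holds the full factor covariance; off-diagonals default to 0 only
    # if the model has no free factor covariance -- check ParamTable
    names = ParamTable(spec).names
    assert mu is None
    # hand-built: Sigma = Lam Psi Lam' + Theta with Psi=diag(2,1) and free
    # F1-F2 covariance at its packed value (0 here since not in theta)
    psi = np.array([[2.0, 0.0], [0.0, 1.0]])
    expected = lam @ psi @ lam.T + np.diag([0.5, 0.5, 0.4, 0.4])
    assert np.allclose(sigma, expected)
    assert any(n.startswith("psi[") for n in names)


def test_fml_zero_iff_exact_fit():
    spec = _toy_spec()
    theta = {"lam1[x2~F1]": 0.8, "lam1[x4~F2]": 1.2,
             "psi[F1]": 2.0, "psi[F2]": 1.0,
             "theta[x1]": 0.5, "theta[x2]": 0.5,
             "theta[x3]": 0.4, "theta[x4]": 0.4}
    sigma, _ = implied_moments(spec, theta)
    assert fml_discrepancy(sigma, None, sigma, None) == pytest.approx(0.0, abs=1e-12)
    other = sigma + np.diag([0.1, 0, 0, 0])
    assert fml_discrepancy(sigma, None, other, None) > 0


def test_fml_mean_term():
    S = np.eye(3)
    xbar = np.array([1.0, 2.0, 3.0])
    mu = xbar + np.array([0.5, 0.0, 0.0])
    base = fml_discrepancy(S, None, S, None)
    with_mean = fml_discrepancy(S, xbar, S, mu)
    assert with_mean - base == pytest.approx(0.25)    # d' Sigma^-1 d


def test_analytic_gradient_matches_finite_differences():
    spec = build_anatomical_spec(mean_structure=True)
    rng = np.random.default_rng(3)
    # a synthetic PD moment target near the model manifold
    table = ParamTable(spec)
    from raclmap import default_population, simulate_bp_table
    ds = simulate_bp_table(default_population("anatomical", n_subjects=80,
                                              seed=3))
    w = ds.wide()
    S = w.cov().to_numpy()
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    xbar = w.mean().to_numpy() / d
    obj = _Objective(table, S, xbar)
    raw0 = table.pack(smart_start(table, S, xbar))
    raw0 += 0.05 * rng.standard_normal(raw0.size)
    f0, g = obj(raw0)
    eps = 1e-6
    idx = rng.choice(raw0.size, size=12, replace=False)
    for i in idx:
        e = np.zeros_like(raw0)
        e[i] = eps
        fp, _ = obj(raw0 + e)
        fm, _ = obj(raw0 - e)
        fd = (fp - fm) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=5e-4, abs=1e-7)


def test_just_identified_recovery():
    # a one-factor, three-indicator model is just-identified: the fitted
    # moments must reproduce S exactly and the loadings the closed form
    spec = ModelSpec(indicators=("a", "b", "c"),
                     first_order={"F": {"a": 1.0, "b": "free", "c": "free"}},
                     second_order={}, name="jid")
    lam = np.array([1.0, 0.7, 1.3])
    psi = 2.0
    theta = np.array([0.3, 0.4, 0.5])
    S = psi * np.outer(lam, lam) + np.diag(theta)
    table, raw, fmin, info = fit_ml_raw(spec, S, None, 100, n_restarts=1,
                                        rng=np.random.default_rng(0))
    assert fmin == pytest.approx(0.0, abs=1e-9)
    est = table.values(raw)
    assert est["lam1[b~F]"] == pytest.approx(0.7, abs=1e-5)
    assert est["lam1[c~F]"] == pytest.approx(1.3, abs=1e-5)
    assert est["psi[F]"] == pytest.approx(2.0, rel=1e-4)


def test_rescaling_invariance(anatomical_wide):
    spec = build_anatomical_spec(mean_structure=True)
    res = HierarchicalFactorModel(spec, data=anatomical_wide).fit(
        n_restarts=0, compute_se=False)
    scaled = anatomical_wide * 10.0
    res10 = HierarchicalFactorModel(spec, data=scaled).fit(
        n_restarts=0, compute_se=False)
    assert res10.chi_square == pytest.approx(res.chi_square, abs=1e-3)
    assert res10.cfi == pytest.approx(res.cfi, abs=1e-5)
    # latent means scale linearly with the data
    m = res.latent_means()["mean"]
    m10 = res10.latent_means()["mean"]
    assert np.allclose(m10, 10.0 * m, rtol=1e-3)


def test_equality_constraint_shares_one_parameter(anatomical_wide):
    spec = build_anatomical_spec().standardized_second_order()
    eq = spec.constrain(Constraint(
        "equal", ("phi[Striatum,Limbic]", "phi[Striatum,Neocortex]")))
    res = HierarchicalFactorModel(eq, data=anatomical_wide).fit(
        n_restarts=0, compute_se=False)
    corr = res.factor_correlations(2)
    assert corr.loc["Striatum", "Limbic"] == pytest.approx(
        corr.loc["Striatum", "Neocortex"], abs=1e-10)
    assert res.df == 76


def test_marker_and_standardized_modes_agree(anatomical_wide):
    marker = build_anatomical_spec()
    std = marker.standardized_second_order()
    r1 = HierarchicalFactorModel(marker, data=anatomical_wide).fit(
        n_restarts=0, compute_se=False)
    r2 = HierarchicalFactorModel(std, data=anatomical_wide).fit(
        n_restarts=0, compute_se=False)
    assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-3)
    c1, c2 = r1.factor_correlations(2), r2.factor_correlations(2)
    assert np.allclose(c1.to_numpy(), c2.loc[c1.index, c1.columns].to_numpy(),
                       atol=1e-4)


def test_indicator_order_invariance(anatomical_wide):
    spec = build_anatomical_spec()
    shuffled = anatomical_wide[list(anatomical_wide.columns)[::-1]]
    r1 = HierarchicalFactorModel(spec, data=anatomical_wide).fit(
        n_restarts=0, compute_se=False)
    r2 = HierarchicalFactorModel(spec, data=shuffled).fit(
        n_restarts=0, compute_se=False)
    assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-4)


def test_non_pd_sample_matrix_raises():
    spec = _toy_spec()
    S = np.ones((4, 4))      # rank 1
    with pytest.raises(np.linalg.LinAlgError):
        fit_ml_raw(spec, S, None, 50, n_restarts=0)


def test_heywood_flagged():
    # force a residual variance to (near) zero: indicator equal to marker
    rng = np.random.default_rng(1)
    f = rng.standard_normal(300)
    data = pd.DataFrame({
        "x1": f + 0.01 * rng.standard_normal(300),
        "x2": f + 0.01 * rng.standard_normal(300),
        "x3": 0.8 * f + rng.standard_normal(300),
        "x4": 0.6 * f + rng.standard_normal(300)})
    spec = ModelSpec(indicators=("x1", "x2", "x3", "x4"),
                     first_order={"F": {"x1": 1.0, "x2": "free",
                                        "x3": "free", "x4": "free"}},
                     second_order={}, name="hey")
    res = HierarchicalFactorModel(spec, data=data).fit(n_restarts=0,
                                                       compute_se=False)
    assert res.info["converged"]
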