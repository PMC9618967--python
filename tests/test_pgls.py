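"""PGLS engine: GLS algebra, lambda profiling, AICc machinery, diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import phylormax as pm
from phylormax.models import spec_by_name
from phylormax.pgls import (
    DegenerateDataError,
    PhyloGLS,
    adjusted_r2,
    aicc,
    akaike_weights,
    compare_models,
    gls_profile_loglik,
    multi_tree_sensitivity,
    vif,
)
from phylormax.trees import lambda_transform, phylo_covariance


# ---------------------------------------------------------------- GLS core


def test_identity_covariance_reduces_to_ols(rng):
    n, k = 50, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    y = X @ [1.0, -0.5, 0.25] + rng.normal(size=n)
    beta, se, sigma2, ll = gls_profile_loglik(X, y, np.eye(n))
    # independent OLS oracle via lstsq
    b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ b_ols) ** 2).sum())
    se_ols = np.sqrt(rss / n * np.diag(np.linalg.inv(X.T @ X)))
    assert np.allclose(beta, b_ols, atol=1e-10)
    assert np.allclose(se, se_ols, atol=1e-10)
    # and against statsmodels coefficients
    import statsmodels.api as sm

    assert np.allclose(beta, sm.OLS(y, X).fit().params, atol=1e-10)


def test_loglik_is_mvn_density_at_estimates(rng):
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    A = rng.normal(size=(n, n))
    C = A @ A.T / n + np.eye(n)
    y = rng.normal(size=n)
    beta, _, sigma2, ll = gls_profile_loglik(X, y, C)
    direct = multivariate_normal.logpdf(y, mean=X @ beta, cov=sigma2 * C)
    assert ll == pytest.approx(direct, abs=1e-8)


def test_noiseless_response_is_degenerate(rng):
    n = 20
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    with pytest.raises(DegenerateDataError):
        gls_profile_loglik(X, X @ [1.0, 2.0], np.eye(n))


def test_lambda_zero_fit_equals_ols_on_tree_data(small_tree, small_dataset):
    fit = PhyloGLS.from_formula(
        "logrmax~logM+1/kBT+depth", small_dataset, small_tree
    ).fit(lam=0.0)
    dm = fit.model.design
    # unit-depth tree: C_0 = I, so plain OLS must match to 1e-8
    b_ols, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
    rss = float(((dm.y - dm.X @ b_ols) ** 2).sum())
    se_ols = np.sqrt(rss / dm.n * np.diag(np.linalg.inv(dm.X.T @ dm.X)))
    assert np.allclose(fit.params.to_numpy(), b_ols, atol=1e-8)
    assert np.allclose(fit.bse.to_numpy(), se_ols, atol=1e-8)


# ------------------------------------------------------------- lambda hat


def test_profile_maximum_beats_grid(small_tree, small_dataset):
    model = PhyloGLS.from_formula(
        "logrmax~logM+1/kBT+depth", small_dataset, small_tree
    )
    fit = model.fit()
    grid = np.linspace(0, 1, 101)
    assert all(fit.llf >= model.loglik_at(g) - 1e-6 for g in grid)
    assert 0.0 <= fit.lambda_ <= 1.0
    lo, hi = fit.lambda_ci
    assert 0.0 <= lo <= fit.lambda_ <= hi <= 1.0


@pytest.mark.parametrize("true_lambda,side", [(0.0, "low"), (1.0, "high")])
def test_lambda_recovered_at_endpoints(true_lambda, side):
    """lambda-hat lands near the generating value for independent (0) and
    Brownian (1) residuals; 40 replicates at n=150."""
    tree = pm.simulate_tree(150, seed=99)
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        cfg = pm.SimulationConfig(
            n_species=150, seed=1000 + rep, true_lambda=true_lambda,
            sigma2=0.3,
        )
        tab = pm.simulate_pgls_dataset(tree, cfg)
        fit = PhyloGLS.from_formula(cfg.model, tab, tree).fit()
        if side == "low" and fit.lambda_ < 0.1:
            hits += 1
        if side == "high" and fit.lambda_ > 0.9:
            hits += 1
    assert hits >= 0.9 * n_rep


# ------------------------------------------------------------------ AICc


@pytest.mark.parametrize(
    "ll,k,n,expected,abs_tol",
    [
        (-37.0, 5, 63, 85.0526, 1e-3),
        (-36.9, 6, 63, 87.3, 0.05),
        (-100.0, 4, 10**7, 208.0, 1e-4),  # correction vanishes at large n
    ],
)
def test_aicc_values(ll, k, n, expected, abs_tol):
    assert aicc(ll, k, n) == pytest.approx(expected, abs=abs_tol)


def test_aicc_small_sample_guard():
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


def test_akaike_weights_two_equal_models():
    assert np.allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])


def test_akaike_weights_normalized(rng):
    for _ in range(20):
        w = akaike_weights(rng.uniform(50, 150, size=rng.integers(1, 12)))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)


# ------------------------------------------------------------------- VIF


def test_vif_orthogonal_columns():
    n = 64
    t = np.arange(n)
    X = np.column_stack(
        [np.ones(n), np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)]
    )
    out = vif(X, ["intercept", "a", "b"])
    assert np.allclose(out.to_numpy(), 1.0, atol=1e-10)


def test_vif_closed_form_at_r_064(rng):
    """Two predictors with empirical correlation exactly 0.64 give
    VIF = 1/(1-0.64^2) ~= 1.69 < 2."""
    n = 200
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    # orthonormalize empirically, then mix to the target correlation
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean()
    z2 -= z1 * (z1 @ z2) / (z1 @ z1)
    z2 /= z2.std()
    r = 0.64
    x2 = r * z1 + np.sqrt(1 - r**2) * z2
    out = vif(np.column_stack([np.ones(n), z1, x2]), ["intercept", "x1", "x2"])
    expected = 1.0 / (1.0 - r**2)
    assert out["x1"] == pytest.approx(expected, abs=1e-6)
    assert out["x2"] == pytest.approx(expected, abs=1e-6)
    assert (out < 2).all()


def test_vif_duplicated_column_is_infinite(rng):
    x = rng.normal(size=50)
    out = vif(np.column_stack([np.ones(50), x, x]), ["intercept", "a", "b"])
    assert np.isinf(out["a"]) and np.isinf(out["b"])


# --------------------------------------------------------------- R-squared


def test_adjusted_r2_null_model_is_nonpositive(small_tree, small_dataset):
    null = PhyloGLS.from_formula("logrmax~logM", small_dataset, small_tree)
    # intercept-only design built by stripping the mass column
    dm = null.design
    dm.X = dm.X[:, :1]
    dm.columns = ["intercept"]
    fit0 = PhyloGLS(dm, C=null.C).fit()
    assert fit0.rsquared == pytest.approx(0.0, abs=1e-10)
    assert fit0.rsquared_adj <= 0.0 + 1e-10


def test_near_noiseless_r2_approaches_one(rng):
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [0.5, -1.0] + 1e-6 * rng.normal(size=n)
    table = pd.DataFrame(
        {
            "species": [f"s{i}" for i in range(n)],
            "log_mass": X[:, 1],
            "median_temp": rng.uniform(5, 25, n),
            "median_depth": rng.uniform(10, 100, n),
            "rmax": np.exp(y),
        }
    )
    dm = pm.build_design_matrix(spec_by_name("logrmax~logM"), table)
    fit = PhyloGLS(dm, C=np.eye(n)).fit(lam=0.0)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-9)


def test_adjusted_r2_guards_mismatched_null(small_tree, small_dataset):
    fit = PhyloGLS.from_formula("logrmax~logM", small_dataset,
                                small_tree).fit()
    with pytest.raises(ValueError):
        adjusted_r2(fit, fit)  # not an intercept-only null


# ------------------------------------------------------------- comparison


def test_identical_specs_share_the_weight(small_tree, small_dataset):
    spec = spec_by_name("logrmax~logM")
    comp = compare_models([spec, spec], small_dataset, small_tree)
    t = comp.table
    assert np.allclose(t["aicc"].iloc[0], t["aicc"].iloc[1])
    assert np.allclose(t["weight"], [0.5, 0.5])
    assert t["delta_aicc"].min() == 0.0


def test_comparison_table_shape_and_invariants(small_tree, small_dataset):
    comp = compare_models(pm.enumerate_models(), small_dataset, small_tree)
    t = comp.table
    assert len(t) == 10
    assert t["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    assert t["delta_aicc"].min() == 0.0
    assert list(t["k"]) == [2, 3, 3, 4, 5, 4, 4, 5, 5, 6]


def test_failed_member_keeps_partial_table(small_tree, small_dataset):
    broken = small_dataset.copy()
    broken["depth_m"] = 100.0  # constant depth: scaling impossible
    comp = compare_models(
        [spec_by_name("logrmax~logM"), spec_by_name("logrmax~logM+depth")],
        broken,
        small_tree,
    )
    t = comp.table.set_index("model")
    assert np.isfinite(t.loc["logrmax~logM", "aicc"])
    assert np.isnan(t.loc["logrmax~logM+depth", "aicc"])
    assert t.loc["logrmax~logM+depth", "error"] != ""


def test_uninformative_parameter_flagging(small_tree, small_dataset):
    """small_dataset's truth is the additive model, so adding either
    interaction to it should buy < 2 AICc."""
    comp = compare_models(pm.enumerate_models(), small_dataset, small_tree)
    flagged = {
        (u["base"], u["extended"]) for u in comp.uninformative
    }
    assert (
        "logrmax~logM+1/kBT+depth",
        "logrmax~logM+1/kBT*depth",
    ) in flagged


# ------------------------------------------------------------ sensitivity


def _jitter_tree(tree, seed):
    rng = np.random.default_rng(seed)
    t = tree.clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= rng.uniform(0.95, 1.05)
    return t


def test_duplicated_tree_gives_identical_columns(small_tree, small_dataset):
    specs = pm.enumerate_models()[:4]
    mat = multi_tree_sensitivity([small_tree] * 3, specs, small_dataset)
    assert mat.shape == (4, 3)
    assert np.allclose(mat["1"], mat["2"]) and np.allclose(mat["1"], mat["3"])
    for col in mat:
        assert (mat[col] == 0).sum() == 1


def test_jittered_trees_agree_on_best_model():
    tree = pm.simulate_tree(120, seed=21)
    cfg = pm.SimulationConfig(n_species=120, seed=21, sigma2=0.15)
    tab = pm.simulate_pgls_dataset(tree, cfg)
    trees = [_jitter_tree(tree, s) for s in range(5)]
    mat = multi_tree_sensitivity(trees, pm.enumerate_models(), tab)
    best = mat.idxmin(axis=0)
    assert best.nunique() == 1


def test_tip_mismatch_names_offending_tree(small_tree, small_dataset):
    other = pm.simulate_tree(10, seed=5)
    with pytest.raises(ValueError, match="2"):
        multi_tree_sensitivity(
            [small_tree, other], pm.enumerate_models()[:2], small_dataset
        )


# -------------------------------------------------------------- prediction


def test_prediction_at_training_rows_equals_fitted(small_tree, small_dataset):
    fit = PhyloGLS.from_formula(
        "logrmax~logM*1/kBT+depth", small_dataset, small_tree
    ).fit()
    pred = fit.predict(small_dataset)
    assert np.allclose(pred, fit.fittedvalues, atol=1e-10)


def test_zero_slopes_give_constant_curve(small_tree, small_dataset):
    fit = PhyloGLS.from_formula(
        "logrmax~logM+1/kBT+depth", small_dataset, small_tree
    ).fit()
    flat = dataclasses.replace(
        fit, params=pd.Series([2.5, 0.0, 0.0, 0.0], index=fit.params.index)
    )
    curve = flat.predict_rmax_curve(np.geomspace(1e2, 1e6, 7), 6.0, 10.0)
    assert np.allclose(curve["log_rmax_pred"], 2.5)


def test_no_mass_depth_interaction_means_parallel_curves(
    small_tree, small_dataset
):
    fit = PhyloGLS.from_formula(
        "logrmax~logM*1/kBT+depth", small_dataset, small_tree
    ).fit()
    grid = np.geomspace(1e2, 1e6, 9)
    shallow = fit.predict_rmax_curve(grid, 6.0, 10.0)["log_rmax_pred"]
    deep = fit.predict_rmax_curve(grid, 6.0, 1000.0)["log_rmax_pred"]
    gaps = (shallow - deep).to_numpy()
    assert np.allclose(gaps, gaps[0], atol=1e-10)


def test_prediction_domain_checks(small_tree, small_dataset):
    fit = PhyloGLS.from_formula(
        "logrmax~logM", small_dataset, small_tree
    ).fit()
    with pytest.raises(ValueError):
        fit.predict_rmax_curve([-1.0, 10.0], 6.0, 10.0)
    with pytest.raises(ValueError):
        fit.predict_rmax_curve([10.0], -300.0, 10.0)


def test_summary_mentions_key_quantities(small_tree, small_dataset):
    fit = PhyloGLS.from_formula(
        "logrmax~logM", small_dataset, small_tree
    ).fit()
    text = fit.summary()
    assert "Pagel's lambda" in text and "AICc" in text and "log_mass" in text


def test_plot_rmax_curves_returns_axes(small_tree, small_dataset):
    import matplotlib

    matplotlib.use("Agg")
    fit = PhyloGLS.from_formula(
        "logrmax~logM*1/kBT+depth", small_dataset, small_tree
    ).fit()
    ax = fit.plot_rmax_curves()
    assert len(ax) == 2
    assert len(ax[0].lines) == 3 and len(ax[1].lines) == 3
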