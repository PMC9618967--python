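"""Phylogenetic generalized least squares with maximum-likelihood Pagel's lambda.

The regression model is

    y = X beta + eps,   eps ~ N(0, sigma^2 * C_lambda),

where ``C_lambda`` is the Brownian-motion phylogenetic covariance of the tree
with its off-diagonal entries multiplied by Pagel's lambda. For fixed lambda
the GLS estimates are available in closed form, so lambda is estimated by
maximizing the profile log-likelihood over [0, 1]; its 95% confidence
interval comes from the 1.92 log-likelihood-unit drop. Everything is ML (not
REML): candidate models differ in their fixed effects, and AICc comparison
across such models requires ML likelihoods.

The public surface follows the model/results convention: :class:`PhyloGLS`
is built from a trait table and a tree (``from_formula``), ``fit()`` returns
a :class:`PhyloGLSResults` carrying coefficients, standard errors, lambda
with its CI, log-likelihood, AICc and (adjusted) R^2, plus ``summary()``,
``predict()`` and diagnostics. Multi-model AICc comparison, Akaike weights,
variance-inflation factors and multi-tree sensitivity build on those objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import brentq, minimize_scalar

from .models import (
    DesignMatrix,
    ModelSpec,
    build_design_matrix,
    enumerate_models,
    inverse_temperature,
)
from .trees import lambda_transform, phylo_covariance

__all__ = [
    "SingularityError",
    "DegenerateDataError",
    "gls_profile_loglik",
    "PhyloGLS",
    "PhyloGLSResults",
    "aicc",
    "akaike_weights",
    "adjusted_r2",
    "compare_models",
    "ModelComparison",
    "vif",
    "multi_tree_sensitivity",
]

#: AICc improvement below which an added parameter is deemed uninformative
UNINFORMATIVE_DELTA = 2.0


class SingularityError(np.linalg.LinAlgError):
    """Covariance or design matrix is numerically singular."""


class DegenerateDataError(ValueError):
    """Residual variance is exactly zero (noiseless response)."""


def _chol(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise SingularityError(
            f"covariance matrix not positive definite (cond={cond:.3g})"
        ) from exc


def gls_profile_loglik(
    X: np.ndarray, y: np.ndarray, C_lambda: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Closed-form GLS estimates and ML log-likelihood for fixed covariance.

    Returns ``(beta, se, sigma2_ml, loglik)`` where::

        beta   = (X' C^-1 X)^-1 X' C^-1 y
        sigma2 = (y - X beta)' C^-1 (y - X beta) / n          (ML)
        loglik = -n/2 log(2 pi sigma2) - 1/2 log|C| - n/2
        se     = sqrt(diag(sigma2 (X' C^-1 X)^-1))

    Solved through a Cholesky factorization of ``C_lambda`` (never an
    explicit inverse); raises :class:`SingularityError` with a condition
    number if the factorization fails, and :class:`DegenerateDataError` if
    the residual variance vanishes.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    L = _chol(np.asarray(C_lambda, float))
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise SingularityError(
            f"design matrix numerically singular (cond={np.linalg.cond(XtX):.3g})"
        )
    cf = cho_factor(XtX)
    beta = cho_solve(cf, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    scale = max(1.0, float(yw @ yw))
    if rss <= 1e-20 * scale:
        raise DegenerateDataError(
            "residual variance is zero: response lies exactly in the column "
            "space of the design"
        )
    sigma2 = rss / n
    logdet_C = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet_C - 0.5 * n
    cov_beta = sigma2 * cho_solve(cf, np.eye(k))
    se = np.sqrt(np.diag(cov_beta))
    return beta, se, sigma2, float(loglik)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)``; ``k`` counts the regression
    coefficients only (the convention under which the comparison tables are
    computed), with the alternative of adding the variance parameters exposed
    via the ``k_convention`` switch on :func:`compare_models`.
    """
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k+1 (got n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: normalized ``exp(-delta/2)`` over a model set."""
    a = np.asarray(aicc_values, float)
    if a.size < 1 or not np.all(np.isfinite(a)):
        raise ValueError("aicc values must be a non-empty finite array")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def vif(design: DesignMatrix | np.ndarray, columns: list[str] | None = None):
    """Variance-inflation factors for the non-intercept design columns.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from the ordinary
    (non-phylogenetic) regression of column j on the remaining non-intercept
    columns — the standard collinearity diagnostic. Perfectly collinear
    columns report ``inf``.
    """
    if isinstance(design, DesignMatrix):
        X = design.X
        columns = design.columns
    else:
        X = np.asarray(design, float)
        if columns is None:
            columns = [f"x{j}" for j in range(X.shape[1])]
    keep = [j for j, c in enumerate(columns) if c != "intercept"]
    out = {}
    for j in keep:
        others = [i for i in keep if i != j]
        xj = X[:, j]
        A = np.column_stack([np.ones(len(xj))] + [X[:, i] for i in others])
        coef, *_ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ coef
        tss = float(((xj - xj.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        out[columns[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


class PhyloGLS:
    """Phylogenetic GLS model for one candidate structure.

    Parameters
    ----------
    design
        Design matrix with response (see ``models.build_design_matrix``).
    tree
        Rooted tree with branch lengths whose tips cover ``design.species``;
        alternatively pass a precomputed covariance via ``C``.
    C
        Brownian covariance matrix aligned with ``design.species`` (used by
        simulations that bypass tree construction).
    """

    def __init__(
        self,
        design: DesignMatrix,
        tree: dendropy.Tree | None = None,
        C: np.ndarray | None = None,
    ):
        if (tree is None) == (C is None):
            raise ValueError("provide exactly one of tree or C")
        if design.y is None:
            raise ValueError("design has no response (rmax column missing)")
        self.design = design
        self.tree = tree
        if C is None:
            C, _ = phylo_covariance(tree, design.species)
        C = np.asarray(C, float)
        if C.shape != (design.n, design.n):
            raise ValueError(
                f"covariance shape {C.shape} does not match n={design.n}"
            )
        self.C = C

    @classmethod
    def from_formula(
        cls,
        spec: ModelSpec | str,
        data: pd.DataFrame,
        tree: dendropy.Tree,
        *,
        scale: bool = True,
    ) -> "PhyloGLS":
        """Build from a formula label (Table-style string) or ModelSpec."""
        if isinstance(spec, str):
            from .models import spec_by_name

            spec = spec_by_name(spec)
        design = build_design_matrix(spec, data, scale=scale)
        return cls(design, tree=tree)

    # -- likelihood machinery -------------------------------------------------

    def loglik_at(self, lam: float) -> float:
        """Profile log-likelihood at a fixed lambda."""
        _, _, _, ll = gls_profile_loglik(
            self.design.X, self.design.y, lambda_transform(self.C, lam)
        )
        return ll

    def fit(self, lam: float | None = None, *, xatol: float = 1e-8
            ) -> "PhyloGLSResults":
        """Fit by ML; lambda is profiled over [0, 1] unless given.

        Bounded scalar optimization with both endpoints evaluated explicitly;
        the profile-likelihood 95% CI for lambda is the set where the profile
        is within 1.92 units of its maximum.
        """
        if lam is not None:
            lambda_hat = float(lam)
            ll_hat = self.loglik_at(lambda_hat)
        else:
            res = minimize_scalar(
                lambda l: -self.loglik_at(l),
                bounds=(0.0, 1.0),
                method="bounded",
                options={"xatol": xatol},
            )
            if not res.success:  # pragma: no cover - bounded Brent rarely fails
                raise RuntimeError(f"lambda optimization failed: {res.message}")
            candidates = [(self.loglik_at(0.0), 0.0),
                          (self.loglik_at(1.0), 1.0),
                          (-res.fun, float(res.x))]
            ll_hat, lambda_hat = max(candidates, key=lambda t: t[0])
        C_hat = lambda_transform(self.C, lambda_hat)
        beta, se, sigma2, ll = gls_profile_loglik(
            self.design.X, self.design.y, C_hat
        )
        ci = (None, None) if lam is not None else self._lambda_ci(
            lambda_hat, ll_hat
        )
        return PhyloGLSResults(
            model=self,
            params=pd.Series(beta, index=self.design.columns),
            bse=pd.Series(se, index=self.design.columns),
            lambda_=lambda_hat,
            lambda_ci=ci,
            sigma2=sigma2,
            llf=ll,
        )

    def _lambda_ci(self, lambda_hat: float, ll_hat: float,
                   drop: float = 1.92) -> tuple[float, float]:
        """Profile-likelihood interval: lambda with loglik >= max - drop."""
        target = ll_hat - drop

        def g(l: float) -> float:
            return self.loglik_at(l) - target

        lo = 0.0
        if lambda_hat > 1e-9 and g(0.0) < 0:
            lo = brentq(g, 0.0, lambda_hat, xtol=1e-6)
        hi = 1.0
        if lambda_hat < 1 - 1e-9 and g(1.0) < 0:
            hi = brentq(g, lambda_hat, 1.0, xtol=1e-6)
        return float(lo), float(hi)


@dataclass
class PhyloGLSResults:
    """Fitted PGLS model: estimates, uncertainties and diagnostics."""

    model: PhyloGLS
    params: pd.Series
    bse: pd.Series
    lambda_: float
    lambda_ci: tuple
    sigma2: float
    llf: float

    # -- basic accessors ------------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return self.model.design.spec

    @property
    def nobs(self) -> int:
        return self.model.design.n

    @property
    def k(self) -> int:
        """Number of regression coefficients (intercept included)."""
        return len(self.params)

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.nobs)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.design.X @ self.params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self.model.design.y - self.fittedvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-theory CIs, ``estimate +/- 1.96 se`` at the default level."""
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- goodness of fit ------------------------------------------------------

    def _gls_rss(self, X: np.ndarray) -> float:
        """GLS residual sum of squares of y on X, whitened by this fit's
        lambda-transformed covariance."""
        C_hat = lambda_transform(self.model.C, self.lambda_)
        L = _chol(C_hat)
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, self.model.design.y, lower=True)
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ coef
        return float(r @ r)

    @property
    def rsquared(self) -> float:
        """1 - RSS(model)/RSS(intercept-only), both under this fit's C_lambda."""
        rss = self._gls_rss(self.model.design.X)
        rss0 = self._gls_rss(np.ones((self.nobs, 1)))
        return 1.0 - rss / rss0

    @property
    def rsquared_adj(self) -> float:
        n, k = self.nobs, self.k
        return 1.0 - (1.0 - self.rsquared) * (n - 1) / (n - k)

    # -- prediction -----------------------------------------------------------

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted log r_max at new covariate values.

        ``data`` needs ``mass`` (g) or ``log_mass``, ``median_temp`` (deg C)
        or ``invtemp``, and ``median_depth`` (m) or ``depth`` as the spec
        requires; the training centering constants are applied.
        """
        data = data.copy()
        if "species" not in data.columns:
            data["species"] = [f"pred_{i}" for i in range(len(data))]
        dm = build_design_matrix(
            self.spec, data, transform=self.model.design.transform
        )
        return dm.X @ self.params.to_numpy()

    def predict_rmax_curve(
        self,
        mass_grid,
        fixed_temp: float,
        fixed_depth: float,
    ) -> pd.DataFrame:
        """Predicted log r_max over a body-mass grid at fixed temperature
        and depth (the prediction-curve layout of the analysis figures)."""
        mass_grid = np.asarray(mass_grid, float)
        if np.any(mass_grid <= 0):
            raise ValueError("mass grid must be positive (grams)")
        inverse_temperature(fixed_temp)  # domain check
        frame = pd.DataFrame(
            {
                "mass": mass_grid,
                "median_temp": fixed_temp,
                "median_depth": fixed_depth,
            }
        )
        return pd.DataFrame(
            {
                "mass_g": mass_grid,
                "log_rmax_pred": self.predict(frame),
                "temp_c": fixed_temp,
                "depth_m": fixed_depth,
            }
        )

    def plot_rmax_curves(
        self,
        mass_grid=None,
        depths=(10.0, 500.0, 1000.0),
        temps=(6.0, 10.0, 20.0),
        fixed_temp: float = 6.0,
        fixed_depth: float = 10.0,
        ax=None,
    ):
        """Two-panel prediction plot: log r_max against body mass across
        depths at a fixed temperature, and across temperatures at a fixed
        depth. Returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if mass_grid is None:
            mass_grid = np.geomspace(1e2, 1e6, 100)
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for depth in depths:
            c = self.predict_rmax_curve(mass_grid, fixed_temp, depth)
            ax[0].plot(c["mass_g"], c["log_rmax_pred"], label=f"{depth:g} m")
        for temp in temps:
            c = self.predict_rmax_curve(mass_grid, temp, fixed_depth)
            ax[1].plot(c["mass_g"], c["log_rmax_pred"], label=f"{temp:g} °C")
        for a, title in zip(ax, (f"at {fixed_temp:g} °C", f"at {fixed_depth:g} m")):
            a.set_xscale("log")
            a.set_xlabel("maximum body mass (g)")
            a.set_title(title)
            a.legend(frameon=False)
        ax[0].set_ylabel(r"predicted $\log\,r_{max}$")
        return ax

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Phylogenetic GLS (ML), model: {self.spec.name}",
            f"n = {self.nobs}, k = {self.k}, logLik = {self.llf:.3f}, "
            f"AICc = {self.aicc:.2f}",
            f"Pagel's lambda = {self.lambda_:.3f}"
            + (
                f" (95% CI {self.lambda_ci[0]:.2f}, {self.lambda_ci[1]:.2f})"
                if self.lambda_ci[0] is not None
                else ""
            ),
            f"sigma^2 (ML) = {self.sigma2:.4f}, "
            f"adj. R^2 = {self.rsquared_adj:.3f}",
            "",
            f"{'term':<22}{'coef':>10}{'se':>10}{'ci95_lo':>10}{'ci95_hi':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}"
                f"{ci.loc[name, 'lower']:>10.3f}{ci.loc[name, 'upper']:>10.3f}"
            )
        return "\n".join(lines)


def adjusted_r2(fit: PhyloGLSResults, null_fit: PhyloGLSResults) -> float:
    """Adjusted R^2 of ``fit`` against an intercept-only null on the same data.

    Both residual sums of squares are whitened by ``fit``'s own
    lambda-transformed covariance so the comparison is internally consistent.
    """
    if null_fit.nobs != fit.nobs or null_fit.k != 1:
        raise ValueError("null_fit must be the intercept-only model on the "
                         "same data")
    if not np.array_equal(null_fit.model.design.y, fit.model.design.y):
        raise ValueError("fit and null_fit responses differ")
    return fit.rsquared_adj


@dataclass
class ModelComparison:
    """AICc comparison across candidate models on one dataset and tree."""

    table: pd.DataFrame
    fits: dict
    uninformative: list

    @property
    def best_name(self) -> str:
        return self.table.loc[self.table["delta_aicc"].idxmin(), "model"]

    @property
    def best_fit(self) -> PhyloGLSResults:
        return self.fits[self.best_name]

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format coefficients with 95% CIs and lambda for every model."""
        rows = []
        for name, fit in self.fits.items():
            if fit is None:
                continue
            ci = fit.conf_int()
            for term in fit.params.index:
                rows.append(
                    {
                        "model": name,
                        "term": term,
                        "estimate": fit.params[term],
                        "se": fit.bse[term],
                        "ci95_lower": ci.loc[term, "lower"],
                        "ci95_upper": ci.loc[term, "upper"],
                        "lambda": fit.lambda_,
                        "lambda_ci_lower": fit.lambda_ci[0],
                        "lambda_ci_upper": fit.lambda_ci[1],
                    }
                )
        return pd.DataFrame(rows)


def _is_nested(sub: ModelSpec, sup: ModelSpec) -> bool:
    return (
        set(sub.column_names()) < set(sup.column_names())
    )


def compare_models(
    specs: list,
    table: pd.DataFrame,
    tree: dendropy.Tree,
    *,
    scale: bool = True,
    k_convention: str = "coefficients",
) -> ModelComparison:
    """Fit every candidate model and assemble the AICc comparison table.

    Columns: model, k, neg_loglik, aicc, adj_r2, delta_aicc, weight, lambda.
    Nested model pairs differing by one term with an AICc improvement below
    2 are flagged: the added parameter is considered uninformative. A model
    whose fit fails is kept as a row of NaNs with the error message rather
    than aborting the batch.

    ``k_convention``: ``"coefficients"`` (default; matches the comparison
    tables) counts regression coefficients only; ``"coefficients+variance"``
    additionally counts lambda and sigma^2.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    if k_convention not in ("coefficients", "coefficients+variance"):
        raise ValueError(f"unknown k_convention {k_convention!r}")
    fit_list: list[PhyloGLSResults | None] = []
    error_list: list[str] = []
    for spec in specs:
        try:
            fit_list.append(
                PhyloGLS.from_formula(spec, table, tree, scale=scale).fit()
            )
            error_list.append("")
        except Exception as exc:  # keep the batch alive, mark the row
            fit_list.append(None)
            error_list.append(f"{type(exc).__name__}: {exc}")

    rows = []
    for spec, fit, err in zip(specs, fit_list, error_list):
        if fit is None:
            rows.append(
                {"model": spec.name, "k": spec.k, "neg_loglik": np.nan,
                 "aicc": np.nan, "adj_r2": np.nan, "lambda": np.nan,
                 "error": err}
            )
            continue
        k_eff = fit.k if k_convention == "coefficients" else fit.k + 2
        rows.append(
            {
                "model": spec.name,
                "k": fit.k,
                "neg_loglik": -fit.llf,
                "aicc": aicc(fit.llf, k_eff, fit.nobs),
                "adj_r2": fit.rsquared_adj,
                "lambda": fit.lambda_,
                "error": "",
            }
        )
    df = pd.DataFrame(rows)
    ok = df["aicc"].notna()
    df["delta_aicc"] = df["aicc"] - df.loc[ok, "aicc"].min()
    df["weight"] = np.nan
    df.loc[ok, "weight"] = akaike_weights(df.loc[ok, "aicc"].to_numpy())

    uninformative = []
    by_name = {s.name: s for s in specs}
    for a in specs:
        for b in specs:
            if a.name == b.name or not _is_nested(by_name[a.name], b):
                continue
            if b.k - a.k != 1:
                continue
            ra = df.loc[df["model"] == a.name, "aicc"].iloc[0]
            rb = df.loc[df["model"] == b.name, "aicc"].iloc[0]
            if np.isnan(ra) or np.isnan(rb):
                continue
            added = (set(b.column_names()) - set(a.column_names())).pop()
            if ra - rb < UNINFORMATIVE_DELTA:
                uninformative.append(
                    {"base": a.name, "extended": b.name, "added_term": added,
                     "aicc_improvement": ra - rb}
                )
    fits = {s.name: f for s, f in zip(specs, fit_list)}
    return ModelComparison(table=df, fits=fits, uninformative=uninformative)


def multi_tree_sensitivity(
    trees: list,
    specs: list,
    table: pd.DataFrame,
    *,
    scale: bool = True,
) -> pd.DataFrame:
    """Delta-AICc of every candidate model under each tree.

    Rows are models, columns trees (1-based labels); each column contains
    that tree's Delta AICc per model, so each column has exactly one zero.
    All trees must carry the full species set of ``table``.
    """
    from .trees import tip_labels

    species = set(table["species"].astype(str))
    bad = [
        i + 1
        for i, t in enumerate(trees)
        if not species <= set(tip_labels(t))
    ]
    if bad:
        raise ValueError(f"trees missing required tips (1-based): {bad}")
    cols = {}
    for i, tree in enumerate(trees, start=1):
        comp = compare_models(specs, table, tree, scale=scale)
        cols[str(i)] = comp.table.set_index("model")["delta_aicc"]
    out = pd.DataFrame(cols)
    out.index.name = "model"
    return out
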