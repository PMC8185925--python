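"""Random-intercept mixed models: REML linear fits with Satterthwaite
degrees of freedom, and Laplace-approximated logistic fits.

The linear model is

    y = X beta + Z u + eps,   u_g ~ N(0, sigma_u^2),  eps ~ N(0, sigma_e^2)

with one scalar random intercept per group (patient).  Variance components
are estimated by restricted maximum likelihood on the profiled deviance in
a log variance-ratio parameterization; fixed-effect t statistics receive
Satterthwaite effective degrees of freedom computed from the delta-method
variance of the coefficient variance under the inverse REML information of
(sigma_u^2, sigma_e^2).

The logistic model integrates the random intercept by a Laplace
approximation around the per-group posterior mode and maximizes the
marginal likelihood over (beta, log sigma_u^2); fixed-effect inference is
Wald (z) from the observed information.

A batched path (`lmm_scan`) fits M models that share the grouping
structure but differ in one design column or in the response — the shape
of a metabolome-wide scan — in vectorized linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "fit_lmm",
    "fit_logistic_mm",
    "BatchLMMResult",
    "lmm_scan",
]

# profiled-deviance convergence: golden-section on log(theta) down to this
# interval width, giving deviance agreement well below 1e-8
_GOLDEN_ITERS = 60
_LOG_THETA_LO = -12.0
_LOG_THETA_HI = 8.0
# below this variance ratio the random intercept is treated as at the
# boundary (theta = 0) and the fit collapses to OLS with n - p df
_BOUNDARY_THETA = 1e-6


@dataclass
class MixedModelSpec:
    """Declarative description of a single mixed-model fit.

    Parameters
    ----------
    response : str
        Column holding the response (numeric for gaussian, 0/1 for
        binomial).
    fixed_effects : sequence of str
        Columns entering as fixed-effect covariates, in order.
    grouping : str
        Column holding the random-intercept grouping factor (patient ID).
    family : {"gaussian", "binomial"}
    intercept : bool
        Include a fixed intercept term (default True).
    """

    response: str
    fixed_effects: Sequence[str]
    grouping: str
    family: Literal["gaussian", "binomial"] = "gaussian"
    intercept: bool = True


@dataclass
class MixedModelFit:
    """Result of a single mixed-model fit, keyed by term name."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    statistics: dict[str, float]
    p_values: dict[str, float]
    dfs: dict[str, float] | None
    variance_components: tuple[float, float]
    converged: bool
    log_likelihood: float
    fallback: str | None = None
    trace: list[float] = field(default_factory=list)


@dataclass
class BatchLMMResult:
    """Arrays from a batched linear mixed scan (one row per model)."""

    beta: np.ndarray          # (M, p)
    se: np.ndarray            # (M, p)
    tstat: np.ndarray         # (M, p)
    df: np.ndarray            # (M, p) Satterthwaite df
    p_value: np.ndarray       # (M, p)
    sigma_u2: np.ndarray      # (M,)
    sigma_e2: np.ndarray      # (M,)
    boundary: np.ndarray      # (M,) bool, random-intercept variance at 0
    log_likelihood: np.ndarray  # (M,) REML criterion at the optimum
    trace: np.ndarray         # (M, iters) incumbent REML value per iteration


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched solve that returns NaN rows for singular members."""
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.full(b.shape, np.nan)
        sign, _ = np.linalg.slogdet(A)
        ok = np.isfinite(sign) & (sign != 0)
        if ok.any():
            out[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        return out


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    if (codes < 0).any():
        raise ValueError("grouping column contains missing values")
    return codes.astype(np.intp), len(uniques)


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy QR
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        bad = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(f"singular fixed-effect design; collinear terms: {bad}")


# ---------------------------------------------------------------------------
# batched REML machinery
# ---------------------------------------------------------------------------

class _BatchCore:
    """Sufficient statistics for M random-intercept LMMs sharing groups.

    Everything the profiled REML criterion needs at any variance ratio
    theta is expressible through XtX, Xty, yty and per-group sums, all
    computed once.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 n_groups: int):
        M, n, p = X.shape
        self.M, self.n, self.p = M, n, p
        self.codes = codes
        self.G = n_groups
        self.group_sizes = np.bincount(codes, minlength=n_groups).astype(float)
        self.XtX = np.einsum("mip,miq->mpq", X, X, optimize=True)
        self.Xty = np.einsum("mip,mi->mp", X, Y, optimize=True)
        self.yty = np.einsum("mi,mi->m", Y, Y)
        # per-group sums: (M, G, p) and (M, G)
        GX = np.zeros((M, n_groups, p))
        GY = np.zeros((M, n_groups))
        for g in range(n_groups):
            mask = codes == g
            GX[:, g, :] = X[:, mask, :].sum(axis=1)
            GY[:, g] = Y[:, mask].sum(axis=1)
        self.GX = GX
        self.GY = GY

    def _core_quantities(self, theta: np.ndarray):
        """A(theta), b(theta), c(theta), logdet V0 for vector theta (M,)."""
        ng = self.group_sizes  # (G,)
        scale = theta[:, None] / (1.0 + theta[:, None] * ng[None, :])  # (M,G)
        A = self.XtX - np.einsum("mg,mgp,mgq->mpq", scale, self.GX, self.GX,
                                 optimize=True)
        b = self.Xty - np.einsum("mg,mgp,mg->mp", scale, self.GX, self.GY,
                                 optimize=True)
        c = self.yty - np.einsum("mg,mg,mg->m", scale, self.GY, self.GY)
        logdetV0 = np.log1p(theta[:, None] * ng[None, :]).sum(axis=1)
        return A, b, c, logdetV0

    def profiled_reml(self, theta: np.ndarray):
        """Profiled REML log-criterion (up to constant), beta, sigma_e2."""
        n, p = self.n, self.p
        A, b, c, logdetV0 = self._core_quantities(theta)
        beta = _solve_batch(A, b)
        q = c - np.einsum("mp,mp->m", beta, b)
        q = np.maximum(q, 1e-300)
        sigma_e2 = q / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * np.log(sigma_e2) + logdetV0 + logdetA)
        ll = np.where(sign > 0, ll, -np.inf)
        return ll, beta, sigma_e2, A

    def reml_and_var(self, sigma_u2: np.ndarray, sigma_e2: np.ndarray):
        """Unprofiled REML log-likelihood and Var(beta_j) at a variance pair.

        Returns (ll, var_beta) with var_beta of shape (M, p) — the
        diagonal of sigma_e2 * A(theta)^{-1}.
        """
        n, p = self.n, self.p
        theta = sigma_u2 / sigma_e2
        A, b, c, logdetV0 = self._core_quantities(theta)
        beta = _solve_batch(A, b)
        q = c - np.einsum("mp,mp->m", beta, b)
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * np.log(sigma_e2) + logdetV0 + logdetA
                     + q / sigma_e2)
        Ainv = np.linalg.pinv(A)
        var_beta = sigma_e2[:, None] * np.einsum("...ii->...i", Ainv)
        return ll, var_beta


def _satterthwaite_df(core: _BatchCore, sigma_u2: np.ndarray,
                      sigma_e2: np.ndarray, boundary: np.ndarray
                      ) -> np.ndarray:
    """Delta-method effective df per coefficient, (M, p).

    df_j = 2 Var_j^2 / (g_j' W g_j) with g_j the gradient of
    Var(beta_j) in (sigma_u^2, sigma_e^2) and W the inverse observed REML
    information, both by central finite differences.
    """
    M, p, n = core.M, core.p, core.n
    df = np.full((M, p), float(n - p))
    active = ~boundary
    if not active.any():
        return df
    su2 = sigma_u2[active]
    se2 = sigma_e2[active]
    h1 = np.maximum(1e-7, 1e-4 * su2)
    h2 = np.maximum(1e-7, 1e-4 * se2)

    sub = _SubCore(core, active)

    def f(a, b):
        return sub.reml_and_var(a, b)

    ll_cc, var_cc = f(su2, se2)
    ll_pc, var_pc = f(su2 + h1, se2)
    ll_mc, var_mc = f(np.maximum(su2 - h1, 1e-12), se2)
    ll_cp, var_cp = f(su2, se2 + h2)
    ll_cm, var_cm = f(su2, se2 - h2)
    ll_pp, _ = f(su2 + h1, se2 + h2)
    ll_mm, _ = f(np.maximum(su2 - h1, 1e-12), se2 - h2)
    ll_pm, _ = f(su2 + h1, se2 - h2)
    ll_mp, _ = f(np.maximum(su2 - h1, 1e-12), se2 + h2)

    d1 = np.maximum(su2 - np.maximum(su2 - h1, 1e-12), 1e-12)  # actual minus step
    # Hessian of the REML log-likelihood
    H11 = (ll_pc - 2 * ll_cc + ll_mc) / (h1 * d1)
    H22 = (ll_cp - 2 * ll_cc + ll_cm) / (h2 * h2)
    H12 = (ll_pp - ll_pm - ll_mp + ll_mm) / ((h1 + d1) * (2 * h2))
    # inverse information W = (-H)^{-1}
    a11, a22, a12 = -H11, -H22, -H12
    det = a11 * a22 - a12 * a12
    w11 = a22 / det
    w22 = a11 / det
    w12 = -a12 / det
    g1 = (var_pc - var_mc) / (h1 + d1)[:, None]
    g2 = (var_cp - var_cm) / (2 * h2)[:, None]
    quad = (g1 * g1 * w11[:, None] + 2 * g1 * g2 * w12[:, None]
            + g2 * g2 * w22[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = 2.0 * var_cc**2 / quad
    nu = np.where(np.isfinite(nu) & (quad > 0), nu, float(n - p))
    nu = np.clip(nu, 1.0, float(n - p))
    df[active] = nu
    return df


class _SubCore:
    """View of a _BatchCore restricted to a boolean row mask."""

    def __init__(self, core: _BatchCore, mask: np.ndarray):
        self.n, self.p = core.n, core.p
        self.group_sizes = core.group_sizes
        self.XtX = core.XtX[mask]
        self.Xty = core.Xty[mask]
        self.yty = core.yty[mask]
        self.GX = core.GX[mask]
        self.GY = core.GY[mask]

    _core_quantities = _BatchCore._core_quantities
    reml_and_var = _BatchCore.reml_and_var


def lmm_scan(Y: np.ndarray, X: np.ndarray, groups,
             max_iter: int = _GOLDEN_ITERS) -> BatchLMMResult:
    """Fit M random-intercept LMMs sharing a grouping structure.

    Parameters
    ----------
    Y : array (M, n) or (n,)
        Responses; a 1-D array is shared across all models.
    X : array (M, n, p) or (n, p)
        Fixed-effect designs (including any intercept column); a 2-D
        array is shared across all models.
    groups : array (n,)
        Random-intercept labels (patient IDs), any hashable dtype.

    Returns
    -------
    BatchLMMResult
        REML estimates, Satterthwaite df and two-sided t p-values.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and Y.ndim == 1:
        X = X[None]
        Y = Y[None]
    elif X.ndim == 2:
        X = np.broadcast_to(X[None], (Y.shape[0],) + X.shape).copy()
    elif Y.ndim == 1:
        Y = np.broadcast_to(Y[None], (X.shape[0], Y.shape[0])).copy()
    M, n, p = X.shape
    if Y.shape != (M, n):
        raise ValueError("Y and X shapes are inconsistent")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed effects ({p})")
    codes, G = _group_codes(groups)
    core = _BatchCore(Y, X, codes, G)

    # golden-section maximization of the profiled REML criterion in
    # u = log(theta); incumbent value recorded per iteration
    lo = np.full(M, _LOG_THETA_LO)
    hi = np.full(M, _LOG_THETA_HI)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = core.profiled_reml(np.exp(x1))[0]
    f2 = core.profiled_reml(np.exp(x2))[0]
    best = np.maximum(f1, f2)
    trace = [best.copy()]
    for _ in range(max_iter):
        left = f1 >= f2  # maximum bracketed in [lo, x2]
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        x1_new = hi - invphi * (hi - lo)
        x2_new = lo + invphi * (hi - lo)
        # one interior point is inherited, the other is fresh
        fresh = np.where(left, x1_new, x2_new)
        f_fresh = core.profiled_reml(np.exp(fresh))[0]
        f1, f2 = (np.where(left, f_fresh, f2), np.where(left, f1, f_fresh))
        x1, x2 = x1_new, x2_new
        best = np.maximum(best, f_fresh)
        trace.append(best.copy())
    u_hat = (lo + hi) / 2.0
    theta_hat = np.exp(u_hat)

    # compare with the theta -> 0 boundary (OLS)
    ll_hat, beta_hat, se2_hat, A_hat = core.profiled_reml(theta_hat)
    ll_0, beta_0, se2_0, A_0 = core.profiled_reml(np.full(M, 0.0))
    boundary = (ll_0 >= ll_hat - 1e-10) | (theta_hat < _BOUNDARY_THETA)
    theta_hat = np.where(boundary, 0.0, theta_hat)
    beta = np.where(boundary[:, None], beta_0, beta_hat)
    sigma_e2 = np.where(boundary, se2_0, se2_hat)
    A = np.where(boundary[:, None, None], A_0, A_hat)
    sigma_u2 = theta_hat * sigma_e2
    ll = np.where(boundary, ll_0, ll_hat)
    best = np.maximum(best, ll_0)
    trace.append(best.copy())

    Ainv = np.linalg.pinv(A)
    var_beta = sigma_e2[:, None] * np.einsum("...ii->...i", Ainv)
    se = np.sqrt(np.maximum(var_beta, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    df = _satterthwaite_df(core, sigma_u2, sigma_e2, boundary)
    p_value = 2.0 * stats.t.sf(np.abs(tstat), df)
    return BatchLMMResult(beta=beta, se=se, tstat=tstat, df=df,
                          p_value=p_value, sigma_u2=sigma_u2,
                          sigma_e2=sigma_e2, boundary=boundary,
                          log_likelihood=ll,
                          trace=np.column_stack(trace))


def _build_design(data: pd.DataFrame, spec: MixedModelSpec
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = list(spec.fixed_effects)
    used = [spec.response, *cols, spec.grouping]
    missing = [c for c in used if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[used]
    if sub[[spec.response, *cols]].isna().any().any():
        raise ValueError("missing values in model columns; take complete cases upstream")
    y = sub[spec.response].to_numpy(dtype=float)
    parts = [sub[c].to_numpy(dtype=float) for c in cols]
    names = list(cols)
    if spec.intercept:
        parts = [np.ones(len(sub))] + parts
        names = ["(Intercept)"] + names
    X = np.column_stack(parts) if parts else np.ones((len(sub), 1))
    return y, X, sub[spec.grouping].to_numpy(), names


def fit_lmm(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """REML linear mixed model with a random intercept per group.

    Fixed-effect p-values use t statistics with Satterthwaite degrees of
    freedom.  When the random-intercept variance is estimated at the
    boundary (zero) the fit equals ordinary least squares with n - p
    residual df.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm is for gaussian responses; use fit_logistic_mm")
    y, X, groups, names = _build_design(data, spec)
    if not np.issubdtype(np.asarray(y).dtype, np.number) or not np.all(np.isfinite(y)):
        raise ValueError("response must be finite numeric")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; model is degenerate")
    _check_design(X, names)
    res = lmm_scan(y, X, groups)
    k = 0
    return MixedModelFit(
        coefficients=dict(zip(names, res.beta[k])),
        standard_errors=dict(zip(names, res.se[k])),
        statistics=dict(zip(names, res.tstat[k])),
        p_values=dict(zip(names, res.p_value[k])),
        dfs=dict(zip(names, res.df[k])),
        variance_components=(float(res.sigma_u2[k]), float(res.sigma_e2[k])),
        converged=True,
        log_likelihood=float(res.log_likelihood[k]),
        fallback="ols_boundary" if res.boundary[k] else None,
        trace=list(res.trace[k]),
    )


# ---------------------------------------------------------------------------
# logistic mixed model (Laplace)
# ---------------------------------------------------------------------------

def _laplace_nll_factory(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                         G: int):
    """Negative Laplace marginal log-likelihood of (beta, log sigma_u^2).

    Returns (value, gradient); the gradient is exact for the Laplace
    objective, combining the envelope theorem at the per-group posterior
    mode with implicit differentiation of the mode and of the curvature
    inside the log-determinant correction.
    """
    state = {"u": np.zeros(G)}

    def nll_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        beta = params[:-1]
        s = float(np.clip(params[-1], -30.0, 30.0))
        su2 = np.exp(s)
        eta0 = X @ beta
        u = state["u"].copy()
        # per-group Newton for the posterior mode, vectorized over groups
        for _ in range(100):
            eta = eta0 + u[codes]
            mu = special.expit(eta)
            grad_u = np.bincount(codes, weights=y - mu, minlength=G) - u / su2
            w = mu * (1.0 - mu)
            S = np.bincount(codes, weights=w, minlength=G)
            step = grad_u / (S + 1.0 / su2)
            u = u + step
            if np.max(np.abs(step)) < 1e-11:
                break
        state["u"] = u
        eta = eta0 + u[codes]
        # log p(y | u) computed stably
        llk = -(np.logaddexp(0.0, -eta)[y > 0.5].sum()
                + np.logaddexp(0.0, eta)[y < 0.5].sum())
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        S = np.bincount(codes, weights=w, minlength=G)
        H = S + 1.0 / su2              # -d2f/du2 per group
        ll = llk - (u * u).sum() / (2.0 * su2) - 0.5 * np.log1p(su2 * S).sum()

        # gradient -------------------------------------------------------
        # dw/deta summed per group, and weighted design sums
        wp = w * (1.0 - 2.0 * mu)      # d(mu(1-mu))/deta
        Swp = np.bincount(codes, weights=wp, minlength=G)
        wX = X * w[:, None]
        SwX = np.zeros((G, X.shape[1]))
        wpX = X * wp[:, None]
        SwpX = np.zeros((G, X.shape[1]))
        for j in range(X.shape[1]):
            SwX[:, j] = np.bincount(codes, weights=wX[:, j], minlength=G)
            SwpX[:, j] = np.bincount(codes, weights=wpX[:, j], minlength=G)
        # implicit derivatives of the group mode
        du_dbeta = -SwX / H[:, None]               # (G, p)
        du_ds = (u / su2) / H                       # (G,)
        # direct part (envelope): df/dbeta, df/ds at fixed u
        g_beta = X.T @ (y - mu)
        g_s = (u * u).sum() / (2.0 * su2)
        # log-det correction T = 0.5 sum log(1 + su2 * S)
        coef = 0.5 * su2 / (1.0 + su2 * S)          # (G,)
        dT_dbeta = (coef[:, None] * (SwpX + Swp[:, None] * du_dbeta)).sum(axis=0)
        dT_ds = (0.5 * su2 * S / (1.0 + su2 * S)).sum() \
            + (coef * Swp * du_ds).sum()
        grad = np.concatenate([-(g_beta - dT_dbeta), [-(g_s - dT_ds)]])
        return -ll, grad

    return nll_grad, state


def fit_logistic_mm(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """Random-intercept logistic regression via Laplace approximation.

    The marginal likelihood is maximized over fixed effects and
    log(sigma_u^2); p-values are Wald z from the observed information.
    Perfect separation is reported through ``converged=False`` rather
    than silently returned coefficients.
    """
    y, X, groups, names = _build_design(data, spec)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("binomial response must be coded 0/1")
    if len(uniq) < 2:
        raise ValueError("response has a single class; logistic model undefined")
    _check_design(X, names)
    codes, G = _group_codes(groups)
    nll_grad, state = _laplace_nll_factory(y, X, codes, G)

    p = X.shape[1]
    # start from a ridge-stabilized plain logistic fit
    beta0 = np.zeros(p)
    for _ in range(25):
        mu = special.expit(X @ beta0)
        w = np.maximum(mu * (1 - mu), 1e-6)
        H = X.T @ (X * w[:, None]) + 1e-8 * np.eye(p)
        g = X.T @ (y - mu) - 1e-8 * beta0
        step = np.linalg.solve(H, g)
        beta0 = beta0 + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta0 = X @ beta0
    ll_boundary = -(np.logaddexp(0.0, -eta0)[y > 0.5].sum()
                    + np.logaddexp(0.0, eta0)[y < 0.5].sum())
    if G == len(y):
        # one Bernoulli observation per group: the intercept variance is
        # not meaningfully identifiable and the Laplace approximation is
        # unreliable, so the variance is fixed at the boundary and the
        # fit is exactly plain logistic regression
        at_boundary = True
        converged_opt = True
    else:
        x0 = np.concatenate([np.clip(beta0, -10, 10), [np.log(0.25)]])
        bounds = [(-40.0, 40.0)] * p + [(-12.0, 8.0)]
        res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-13,
                                         "gtol": 1e-9})
        params = res.x
        # at sigma_u^2 = 0 the Laplace objective is the EXACT likelihood;
        # a sub-1e-3 "gain" at small positive variance is approximation
        # error, so the boundary (plain logistic) fit is preferred there
        at_boundary = (-res.fun) - ll_boundary < 1e-3
        converged_opt = bool(res.success)
    if at_boundary:
        params = np.concatenate([beta0, [-30.0]])
        state["u"][:] = 0.0
    beta = params[:-1]
    su2 = 0.0 if at_boundary else float(np.exp(params[-1]))

    # observed information from central differences of the exact gradient
    # (plain logistic information X'WX at the variance boundary)
    if at_boundary:
        mu = special.expit(X @ beta)
        H_beta = X.T @ (X * (mu * (1.0 - mu))[:, None])
        f0 = -ll_boundary
    else:
        h = 1e-6 * np.maximum(1.0, np.abs(params))
        k = p + 1
        H = np.zeros((k, k))
        f0, _ = nll_grad(params)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            _, gp = nll_grad(params + ei)
            _, gm = nll_grad(params - ei)
            H[i] = (gp - gm) / (2 * h[i])
        H_beta = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H_beta)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    separated = bool(np.max(np.abs(beta)) > 15.0 or not np.all(np.isfinite(se))
                     or np.any(se > 100.0))
    converged = converged_opt and not separated
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MixedModelFit(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        statistics=dict(zip(names, z)),
        p_values=dict(zip(names, pvals)),
        dfs=None,
        variance_components=(su2, float("nan")),
        converged=converged,
        log_likelihood=float(-f0),
        fallback="separation" if separated else None,
    )
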