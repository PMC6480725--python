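"""Linear logistic test models by marginal maximum likelihood.

The LLTM restricts Rasch item difficulty to a linear combination of
cognitive-operator weights, delta_i = sum_j q_ij eta_j.  It is fitted here as
a generalised linear mixed model: logit P(x_vi = 1) = theta_v + c + sum_j
q_ij b_j with theta_v ~ Normal(0, sigma_theta^2) a person random effect.  The
fixed effects (c, b_j) are on the *easiness* scale; the implied difficulty of
an item is delta_i = -(c + sum_j q_ij b_j).  The LLTM-plus-error adds a
per-item residual eps_i ~ Normal(0, sigma_eps^2) so the operator
decomposition need not be exact.

The person-only marginal likelihood is integrated by Gauss-Hermite
quadrature; the crossed person x item model uses the Laplace approximation
around the joint random-effect mode, solved with a Schur complement on the
(small) item block so each evaluation costs O(n k + k^3).

A Rasch model fitted with per-item indicator covariates (``saturated
properties``) is the unrestricted reference for AIC/BIC comparison.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .qmatrix import ItemPropertyMatrix, QMatrix
from .rasch import ResponseMatrix

__all__ = [
    "LLTMFit",
    "ModelComparison",
    "fit_lltm",
    "fit_lltm_error",
    "fit_rasch_mml",
    "saturated_properties",
    "predict_difficulties",
    "bootstrap_item_se",
    "compare_models",
]


@dataclasses.dataclass
class LLTMFit:
    """Marginal-likelihood fit of an LLTM (or its error extension)."""

    eta: pd.Series                 # operator fixed effects, easiness scale
    intercept: float
    person_var: float
    item_resid_var: float          # 0 for the plain LLTM
    marg_loglik: float
    n_params: int
    fitted_difficulties: pd.Series  # per item, difficulty scale
    se_eta: pd.Series
    item_residuals: pd.Series | None = None   # shrunken eps_i (error model)
    person_theta: pd.Series | None = None     # EAP / posterior-mode abilities
    model: str = "lltm"
    n_obs: int = 0
    convergence: dict = dataclasses.field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return -2.0 * self.marg_loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_params

    def bic(self, n_obs: int | None = None) -> float:
        n = self.n_obs if n_obs is None else n_obs
        return self.deviance + self.n_params * np.log(n)


@dataclasses.dataclass
class ModelComparison:
    table: pd.DataFrame            # per model: loglik, n_params, AIC, BIC
    lr_tests: pd.DataFrame         # nested pairs: statistic, df, p


def _design(responses: ResponseMatrix, properties: ItemPropertyMatrix):
    ids = list(properties.item_ids)
    if set(ids) != set(responses.item_ids) or len(ids) != len(responses.item_ids):
        raise ValueError("property matrix items do not match response items")
    X = responses.scores[ids].to_numpy(dtype=float)
    M = ~np.isnan(X)
    Xf = np.where(M, X, 0.0)
    Q = properties.covariates.astype(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(ids)), Q])) < Q.shape[1] + 1:
        raise ValueError(
            "item property matrix (with intercept) is rank deficient; "
            f"columns: {list(properties.operator_names)}")
    return Xf, M, Q, ids


def _softplus(x):
    return np.logaddexp(0.0, x)


# --------------------------------------------------------------------------
# Person-only marginal likelihood (Gauss-Hermite)
# --------------------------------------------------------------------------

class _GHModel:
    def __init__(self, Xf, M, Q, n_nodes=61):
        self.Xf, self.M, self.Q = Xf, M, Q
        nodes, weights = special.roots_hermitenorm(n_nodes)
        self.nodes, self.logw = nodes, np.log(weights / np.sqrt(2.0 * np.pi))
        self.si = Xf.sum(axis=0)           # item totals
        self.rv = Xf.sum(axis=1)           # person raw scores

    def unpack(self, params):
        c, b, logsd = params[0], params[1:-1], params[-1]
        return c, b, np.exp(logsd)

    def loglik_grad(self, params):
        c, b, sd = self.unpack(params)
        easi = c + self.Q @ b                      # per-item easiness
        theta = sd * self.nodes                    # quadrature abscissae
        L = theta[:, None] + easi[None, :]         # nodes x items
        sp = _softplus(L)
        # person x node log-likelihood
        A = self.rv[:, None] * theta[None, :] + (self.Xf @ easi)[:, None] \
            - self.M @ sp.T
        A += self.logw[None, :]
        m = A.max(axis=1, keepdims=True)
        W = np.exp(A - m)
        s = W.sum(axis=1)
        ll = float((m[:, 0] + np.log(s)).sum())
        W /= s[:, None]                            # posterior node weights
        P = 1.0 / (1.0 + np.exp(-L))               # nodes x items
        # d ll / d easiness_i = s_i - sum_v sum_q W_vq m_vi P_qi
        exp_correct = self.M * (W @ P)             # persons x items
        g_easi = self.si - exp_correct.sum(axis=0)
        g_c = g_easi.sum()
        g_b = self.Q.T @ g_easi
        # d ll / d log sd: theta_q = sd * z_q, dL/dlogsd = theta_q
        resid = self.rv[:, None] - (self.M @ P.T)  # persons x nodes: sum_i (x - p)
        g_logsd = float(((W * resid) @ theta).sum())
        return ll, np.concatenate([[g_c], g_b, [g_logsd]])

    def posterior_theta(self, params):
        c, b, sd = self.unpack(params)
        easi = c + self.Q @ b
        theta = sd * self.nodes
        L = theta[:, None] + easi[None, :]
        sp = _softplus(L)
        A = self.rv[:, None] * theta[None, :] + (self.Xf @ easi)[:, None] \
            - self.M @ sp.T + self.logw[None, :]
        A -= A.max(axis=1, keepdims=True)
        W = np.exp(A)
        W /= W.sum(axis=1, keepdims=True)
        return W @ theta                            # EAP estimates


def _fit_gh(Xf, M, Q, n_nodes, start=None, max_iter=500):
    model = _GHModel(Xf, M, Q, n_nodes=n_nodes)
    p0 = np.zeros(Q.shape[1] + 2) if start is None else np.asarray(start, float)
    if start is None:
        p0[-1] = 0.0  # log sd = 0

    def nll(p):
        ll, g = model.loglik_grad(p)
        return -ll, -g

    res = optimize.minimize(nll, p0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-12,
                                     "gtol": 1e-7})
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        raise RuntimeError(f"LLTM marginal fit did not converge: {res.message}")
    return model, res


def fit_lltm(
    responses: ResponseMatrix,
    properties: ItemPropertyMatrix,
    n_quad: int = 61,
    se: bool = True,
) -> LLTMFit:
    """Fit the LLTM with a Normal(0, sigma^2) person random effect.

    Fixed-effect SEs come from the inverse observed information (numerically
    differenced analytic gradient).  Person abilities are EAP estimates.
    """
    Xf, M, Q, ids = _design(responses, properties)
    model, res = _fit_gh(Xf, M, Q, n_quad)
    params = res.x
    c, b, sd = model.unpack(params)
    names = list(properties.operator_names)
    easi = c + Q @ b
    se_all = np.full(len(params), np.nan)
    if se:
        H = _numdiff_hessian(lambda p: model.loglik_grad(p)[1], params)
        with np.errstate(invalid="ignore"):
            se_all = np.sqrt(np.diag(np.linalg.inv(-H)))
    theta = model.posterior_theta(params)
    return LLTMFit(
        eta=pd.Series(b, index=names, name="eta"),
        intercept=float(c),
        person_var=float(sd ** 2),
        item_resid_var=0.0,
        marg_loglik=-float(res.fun),
        n_params=len(params),
        fitted_difficulties=pd.Series(-easi, index=ids, name="delta_hat"),
        se_eta=pd.Series(se_all[1:-1], index=names, name="se"),
        person_theta=pd.Series(theta, index=responses.person_ids, name="theta"),
        model="lltm",
        n_obs=int(M.sum()),
        convergence={"converged": True, "iterations": int(res.nit)},
    )


def _numdiff_hessian(grad_fn, params, h=1e-5):
    p = np.asarray(params, float)
    H = np.zeros((p.size, p.size))
    for j in range(p.size):
        step = np.zeros_like(p)
        step[j] = h
        H[:, j] = (grad_fn(p + step) - grad_fn(p - step)) / (2 * h)
    return 0.5 * (H + H.T)


def saturated_properties(item_ids: Sequence[str]) -> ItemPropertyMatrix:
    """Per-item indicator covariates (first item as reference).

    Together with the intercept this spans every item's easiness, so the
    marginal fit is the unrestricted Rasch model under marginal likelihood.
    """
    ids = list(item_ids)
    k = len(ids)
    cov = np.zeros((k, k - 1))
    cov[1:, :] = np.eye(k - 1)
    return ItemPropertyMatrix(
        item_ids=tuple(ids), model_ids=tuple(range(k)),
        operator_names=tuple(f"ind_{i}" for i in ids[1:]), covariates=cov)


def fit_rasch_mml(responses: ResponseMatrix, n_quad: int = 61) -> LLTMFit:
    """Rasch model under marginal likelihood (saturated LLTM)."""
    fit = fit_lltm(responses, saturated_properties(responses.item_ids),
                   n_quad=n_quad, se=False)
    fit.model = "rasch_mml"
    return fit


# --------------------------------------------------------------------------
# Crossed random effects (LLTM plus error) via Laplace
# --------------------------------------------------------------------------

class _LaplaceModel:
    def __init__(self, Xf, M, Q):
        self.Xf, self.M, self.Q = Xf, M, Q
        self.n, self.k = Xf.shape
        self._warm = np.zeros(self.n + self.k)

    def _joint_parts(self, u, easi, var_t, var_e):
        n, k = self.n, self.k
        theta, e = u[:n], u[n:]
        L = theta[:, None] + (easi + e)[None, :]
        ll = float((self.Xf * L).sum() - (self.M * _softplus(L)).sum())
        prior = -0.5 * (theta @ theta) / var_t - 0.5 * n * np.log(2 * np.pi * var_t) \
                - 0.5 * (e @ e) / var_e - 0.5 * k * np.log(2 * np.pi * var_e)
        return ll + prior, L

    def _mode(self, easi, var_t, var_e, tol=1e-9, max_newton=60):
        n, k = self.n, self.k
        u = self._warm.copy()
        f_prev = None
        for _ in range(max_newton):
            theta, e = u[:n], u[n:]
            L = theta[:, None] + (easi + e)[None, :]
            P = np.where(self.M, 1.0 / (1.0 + np.exp(-L)), 0.0)
            R = self.Xf - P
            g = np.concatenate([R.sum(axis=1) - theta / var_t,
                                R.sum(axis=0) - e / var_e])
            W = P * (1.0 - P)
            Dp = W.sum(axis=1) + 1.0 / var_t
            Di = W.sum(axis=0) + 1.0 / var_e
            # solve [[diag(Dp), W], [W.T, diag(Di)]] du = g via Schur on items
            S = np.diag(Di) - (W.T / Dp) @ W
            rhs_i = g[n:] - W.T @ (g[:n] / Dp)
            du_i = np.linalg.solve(S, rhs_i)
            du_p = (g[:n] - W @ du_i) / Dp
            step = np.concatenate([du_p, du_i])
            # damped Newton
            t = 1.0
            f0, _ = self._joint_parts(u, easi, var_t, var_e)
            for _ in range(30):
                u_new = u + t * step
                f1, _ = self._joint_parts(u_new, easi, var_t, var_e)
                if f1 >= f0 - 1e-12:
                    break
                t *= 0.5
            u = u_new
            if np.max(np.abs(t * step)) < tol or (
                    f_prev is not None and abs(f1 - f_prev) < 1e-12):
                break
            f_prev = f1
        self._warm = u
        return u

    def laplace_loglik(self, params):
        m = self.Q.shape[1]
        c, b = params[0], params[1:1 + m]
        var_t, var_e = np.exp(2 * params[-2]), np.exp(2 * params[-1])
        easi = c + self.Q @ b
        u = self._mode(easi, var_t, var_e)
        f, L = self._joint_parts(u, easi, var_t, var_e)
        P = np.where(self.M, 1.0 / (1.0 + np.exp(-L)), 0.0)
        W = P * (1.0 - P)
        Dp = W.sum(axis=1) + 1.0 / var_t
        Di = W.sum(axis=0) + 1.0 / var_e
        S = np.diag(Di) - (W.T / Dp) @ W
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf, u
        logdet_H = float(np.log(Dp).sum() + logdet_S)
        ll = f + 0.5 * (self.n + self.k) * np.log(2 * np.pi) - 0.5 * logdet_H
        return ll, u


def fit_lltm_error(
    responses: ResponseMatrix,
    properties: ItemPropertyMatrix,
    max_iter: int = 300,
    se: bool = True,
) -> LLTMFit:
    """Fit the LLTM plus a per-item residual (crossed random effects).

    The marginal likelihood over the joint (person, item) random-effect
    vector is approximated by Laplace's method at the penalised-likelihood
    mode.  Reported per-item difficulties are the shrunken predictions
    -(c + q_i b + eps_hat_i); ``item_resid_var`` is the residual variance the
    operators leave unexplained.
    """
    Xf, M, Q, ids = _design(responses, properties)
    profiles = [tuple(row) for row in Q]
    if len(set(profiles)) == len(profiles):
        warnings.warn("one item per operator profile everywhere; "
                      "item residual variance is weakly identified")
    model = _LaplaceModel(Xf, M, Q)
    m = Q.shape[1]
    # warm start at the plain-LLTM solution with a moderate residual variance
    gh_model, gh_res = _fit_gh(Xf, M, Q, n_nodes=61)
    ll_boundary = -float(gh_res.fun)   # exact person-only likelihood at var_e = 0
    p0 = np.concatenate([gh_res.x[:-1], [gh_res.x[-1]], [np.log(0.5)]])

    def nll(p):
        ll, _ = model.laplace_loglik(p)
        return -ll

    res = optimize.minimize(
        nll, p0, method="L-BFGS-B", jac=None,
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6,
                 "eps": 1e-5})
    params = res.x
    ll, u = model.laplace_loglik(params)
    names = list(properties.operator_names)
    if ll_boundary >= ll:
        # the residual variance hits its zero boundary, where the crossed
        # model coincides with the plain LLTM and the person-only integral
        # is exact; report that fit rather than the interior Laplace one
        base = fit_lltm(responses, properties, se=se)
        return dataclasses.replace(
            base, model="lltm_error", n_params=m + 3, item_resid_var=0.0,
            item_residuals=pd.Series(np.zeros(len(ids)), index=ids, name="eps_hat"),
            convergence={"converged": True, "boundary": True,
                         "iterations": int(res.nit)})
    c, b = params[0], params[1:1 + m]
    var_t, var_e = float(np.exp(2 * params[-2])), float(np.exp(2 * params[-1]))
    e_hat = u[model.n:]
    theta_hat = u[:model.n]
    easi = c + Q @ b
    se_all = np.full(len(params), np.nan)
    if se:
        H = _numdiff_hessian(
            lambda p: optimize.approx_fprime(p, nll, 1e-5), params, h=1e-4) * -1.0
        with np.errstate(invalid="ignore"):
            se_all = np.sqrt(np.diag(np.linalg.inv(-H)))
    return LLTMFit(
        eta=pd.Series(b, index=names, name="eta"),
        intercept=float(c),
        person_var=var_t,
        item_resid_var=var_e,
        marg_loglik=float(ll),
        n_params=m + 3,
        fitted_difficulties=pd.Series(-(easi + e_hat), index=ids, name="delta_hat"),
        se_eta=pd.Series(se_all[1:1 + m], index=names, name="se"),
        item_residuals=pd.Series(e_hat, index=ids, name="eps_hat"),
        person_theta=pd.Series(theta_hat, index=responses.person_ids, name="theta"),
        model="lltm_error",
        n_obs=int(M.sum()),
        convergence={"converged": bool(res.success), "iterations": int(res.nit)},
    )


# --------------------------------------------------------------------------
# Prediction, bootstrap, comparison
# --------------------------------------------------------------------------

def predict_difficulties(fit, q: QMatrix) -> pd.Series:
    """Predicted difficulty per item model: delta = -(c + sum_j q_j b_j).

    ``fit`` may be an :class:`LLTMFit` or a mapping with keys ``intercept``
    and ``eta`` (a mapping operator -> easiness coefficient), so published
    coefficient tables can be fed in directly.
    """
    if isinstance(fit, LLTMFit):
        intercept, eta = fit.intercept, fit.eta
    else:
        intercept, eta = fit["intercept"], pd.Series(fit["eta"])
    names = list(q.operator_names)
    if list(eta.index) != names:
        if set(eta.index) >= set(names):
            eta = eta[names]
        else:
            raise ValueError(
                f"operator mismatch: fit has {list(eta.index)}, Q-matrix has {names}")
    pred = -(intercept + q.weights.astype(float) @ eta.to_numpy())
    return pd.Series(pred, index=q.model_ids, name="predicted_difficulty")


def bootstrap_item_se(
    fit: LLTMFit,
    responses: ResponseMatrix,
    properties: ItemPropertyMatrix,
    n_iter: int = 1000,
    seed: int = 0,
    n_quad: int = 31,
) -> dict:
    """Parametric bootstrap SEs for operator effects and item difficulties.

    Responses are simulated from the fitted model on the observed design
    (same persons, same missingness), the model is refitted, and the standard
    deviations of the replicate estimates are reported.  Failed refits are
    dropped; more than 20% failures is an error.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    Xf, M, Q, ids = _design(responses, properties)
    rng = np.random.default_rng(seed)
    easi = fit.intercept + Q @ fit.eta.to_numpy()
    sd_t = np.sqrt(fit.person_var)
    sd_e = np.sqrt(fit.item_resid_var)
    n, k = M.shape
    etas, deltas, failures = [], [], 0
    for _ in range(n_iter):
        theta = rng.normal(0.0, sd_t, n)
        e = rng.normal(0.0, sd_e, k) if sd_e > 0 else np.zeros(k)
        P = 1.0 / (1.0 + np.exp(-(theta[:, None] + (easi + e)[None, :])))
        sim = np.where(M, (rng.random((n, k)) < P).astype(float), np.nan)
        rep = ResponseMatrix.from_array(sim, person_ids=responses.person_ids,
                                        item_ids=ids)
        try:
            if fit.model == "lltm_error":
                rfit = fit_lltm_error(rep, properties, se=False)
            else:
                rfit = fit_lltm(rep, properties, n_quad=n_quad, se=False)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        etas.append(np.concatenate([[rfit.intercept], rfit.eta.to_numpy()]))
        deltas.append(rfit.fitted_difficulties.to_numpy())
    if failures > 0.2 * n_iter:
        raise RuntimeError(f"{failures}/{n_iter} bootstrap refits failed")
    etas, deltas = np.array(etas), np.array(deltas)
    names = ["intercept"] + list(fit.eta.index)
    return {
        "n_success": len(etas),
        "n_failed": failures,
        "se_eta": pd.Series(etas.std(axis=0, ddof=1), index=names),
        "se_item": pd.Series(deltas.std(axis=0, ddof=1), index=ids),
    }


def compare_models(
    fits: Sequence[LLTMFit],
    n_obs: int | None = None,
    nested_pairs: Sequence[tuple[int, int]] = (),
) -> ModelComparison:
    """AIC/BIC table and likelihood-ratio tests for declared nested pairs.

    ``n_obs`` defaults to the number of observed responses shared by the
    fits; pairs are (restricted_index, general_index) into ``fits``.
    """
    obs = {f.n_obs for f in fits}
    if len(obs) != 1:
        raise ValueError("fits are not based on the same observed responses")
    n = n_obs if n_obs is not None else obs.pop()
    rows = []
    for f in fits:
        rows.append({"model": f.model, "loglik": f.marg_loglik,
                     "n_params": f.n_params, "AIC": f.aic, "BIC": f.bic(n)})
    table = pd.DataFrame(rows).set_index("model")
    lr_rows = []
    for (i0, i1) in nested_pairs:
        f0, f1 = fits[i0], fits[i1]
        if f1.n_params <= f0.n_params:
            raise ValueError("nested pair must be (restricted, general)")
        stat = max(0.0, 2.0 * (f1.marg_loglik - f0.marg_loglik))
        df = f1.n_params - f0.n_params
        lr_rows.append({"restricted": f0.model, "general": f1.model,
                        "statistic": stat, "df": df,
                        "p": float(stats.chi2.sf(stat, df))})
    return ModelComparison(table=table, lr_tests=pd.DataFrame(lr_rows))
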