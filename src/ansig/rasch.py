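"""Rasch calibration by conditional maximum likelihood (CML).

The Rasch model gives P(x_vi = 1 | theta_v, delta_i) =
exp(theta_v - delta_i) / (1 + exp(theta_v - delta_i)).  Conditioning on each
person's raw score removes the person parameters, leaving a likelihood in the
item difficulties alone, evaluated through elementary symmetric functions
(ESFs) of the item easiness values eps_i = exp(-delta_i).  ESFs are computed
with the summation (difference-free) polynomial recurrence, which is stable
for test lengths around 50; first and second derivatives use forward-backward
prefix/suffix products, never deflation.

Missing-by-design data are handled by grouping persons on their administered
item subset and conditioning within each subset, which performs anchored
concurrent calibration of overlapping forms on one logit metric.  The metric
is identified by a sum-zero constraint over the estimated items (optionally
re-centred on an anchor subset).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ResponseMatrix",
    "RaschFit",
    "PersonEstimates",
    "TestInfo",
    "fit_rasch_cml",
    "estimate_persons",
    "andersen_lr_test",
    "wald_item_tests",
    "test_information",
    "person_separation_reliability",
]


@dataclasses.dataclass
class ResponseMatrix:
    """Dichotomous person x item scores with a missing-by-design mask.

    ``scores`` is a persons-by-items DataFrame of 0/1 entries with NaN where
    the item was not administered (the design mask is simply non-missingness).
    """

    scores: pd.DataFrame

    def __post_init__(self):
        arr = self.scores.to_numpy(dtype=float)
        vals = arr[~np.isnan(arr)]
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0))]))
            raise ValueError(f"scores must be 0, 1 or missing; found {bad}")

    @classmethod
    def from_array(cls, arr, person_ids=None, item_ids=None) -> "ResponseMatrix":
        arr = np.asarray(arr, dtype=float)
        n, k = arr.shape
        return cls(pd.DataFrame(
            arr,
            index=person_ids if person_ids is not None else [f"p{v+1}" for v in range(n)],
            columns=item_ids if item_ids is not None else [f"i{j+1}" for j in range(k)]))

    @property
    def person_ids(self) -> list:
        return list(self.scores.index)

    @property
    def item_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def design_mask(self) -> pd.DataFrame:
        return self.scores.notna()

    @property
    def n_observed(self) -> int:
        return int(self.scores.notna().to_numpy().sum())

    def subset_persons(self, keep) -> "ResponseMatrix":
        return ResponseMatrix(self.scores.loc[keep])


@dataclasses.dataclass
class RaschFit:
    difficulties: pd.Series          # delta_i, sum-zero over estimated items
    se: pd.Series
    cond_loglik: float
    excluded_items: list
    convergence: dict
    center: str = "items"

    @property
    def item_ids(self) -> list:
        return list(self.difficulties.index)


@dataclasses.dataclass
class PersonEstimates:
    theta: pd.Series
    se: pd.Series
    excluded_persons: list           # perfect/zero raw scores (no ML estimate)


@dataclasses.dataclass
class TestInfo:
    theta_grid: np.ndarray
    info: np.ndarray
    max_info: float
    argmax_theta: float


# --------------------------------------------------------------------------
# Elementary symmetric functions
# --------------------------------------------------------------------------

def _esf(eps: np.ndarray) -> np.ndarray:
    """gamma_r for r = 0..k via the summation recurrence."""
    g = np.zeros(len(eps) + 1)
    g[0] = 1.0
    for j, e in enumerate(eps):
        g[1:j + 2] += e * g[0:j + 1].copy()
    return g


def _esf_first_derivs(eps: np.ndarray):
    """gamma and the length-k polys gamma^(i) (all items except i)."""
    k = len(eps)
    prefix = [np.array([1.0])]
    for e in eps[:-1]:
        p = prefix[-1]
        q = np.zeros(len(p) + 1)
        q[:-1] += p
        q[1:] += e * p
        prefix.append(q)
    suffix = [np.array([1.0])]
    for e in eps[::-1][:-1]:
        p = suffix[-1]
        q = np.zeros(len(p) + 1)
        q[:-1] += p
        q[1:] += e * p
        suffix.append(q)
    suffix = suffix[::-1]
    gamma_i = np.zeros((k, k))
    for i in range(k):
        gamma_i[i] = np.convolve(prefix[i], suffix[i])
    full = np.zeros(k + 1)
    full[:k] = gamma_i[0]
    full[1:] += eps[0] * gamma_i[0]
    return full, gamma_i


def _conditional_item_probs(eps: np.ndarray):
    """pi[r, i] = E[x_i | raw score r] for r = 0..k, plus gamma."""
    k = len(eps)
    gamma, gamma_i = _esf_first_derivs(eps)
    pi = np.zeros((k + 1, k))
    for r in range(1, k + 1):
        pi[r] = eps * gamma_i[:, r - 1] / gamma[r]
    return pi, gamma, gamma_i


def _conditional_score_cov(eps: np.ndarray, score_counts: np.ndarray) -> np.ndarray:
    """Sum over raw scores of n_r * Cov(x | r): the CML information matrix."""
    k = len(eps)
    pi, gamma, _ = _conditional_item_probs(eps)
    H = np.zeros((k, k))
    for i in range(k):
        reduced = np.delete(eps, i)
        _, g_red_j = _esf_first_derivs(reduced)  # (k-1, k-1)
        # gamma^(ij)_r for j != i
        pij = np.zeros((k + 1, k))
        other = [j for j in range(k) if j != i]
        for jj, j in enumerate(other):
            for r in range(2, k + 1):
                if r - 2 < g_red_j.shape[1]:
                    pij[r, j] = eps[i] * eps[j] * g_red_j[jj, r - 2] / gamma[r]
        for r in range(k + 1):
            n_r = score_counts[r]
            if n_r == 0:
                continue
            row = pij[r] - pi[r, i] * pi[r]
            row[i] = pi[r, i] * (1.0 - pi[r, i])
            H[i] += n_r * row
    return H


# --------------------------------------------------------------------------
# CML fitting
# --------------------------------------------------------------------------

def _prepare_groups(responses: ResponseMatrix, item_ids: list):
    """Group non-extreme persons by administered item subset.

    Returns a list of (item_index_array, item_totals, score_counts) per
    subset, with item indices into ``item_ids``.
    """
    sub = responses.scores[item_ids]
    arr = sub.to_numpy(dtype=float)
    mask = ~np.isnan(arr)
    groups = {}
    for v in range(arr.shape[0]):
        key = mask[v].tobytes()
        groups.setdefault(key, []).append(v)
    out = []
    for key, rows in groups.items():
        m = np.frombuffer(key, dtype=bool)
        idx = np.where(m)[0]
        if idx.size == 0:
            continue
        x = arr[np.ix_(rows, idx)]
        raw = x.sum(axis=1)
        keep = (raw > 0) & (raw < idx.size)  # extreme persons carry no information
        x = x[keep]
        if x.shape[0] == 0:
            continue
        totals = x.sum(axis=0)
        counts = np.bincount(x.sum(axis=1).astype(int), minlength=idx.size + 1)
        out.append((idx, totals, counts))
    return out


def _neg_cll_and_grad(delta_full: np.ndarray, groups):
    nll = 0.0
    grad = np.zeros_like(delta_full)
    for idx, totals, counts in groups:
        d = delta_full[idx]
        eps = np.exp(-d)
        pi, gamma, _ = _conditional_item_probs(eps)
        r_idx = np.nonzero(counts)[0]
        nll += totals @ d + counts[r_idx] @ np.log(gamma[r_idx])
        grad[idx] += totals - counts[r_idx] @ pi[r_idx]
    return nll, grad


def fit_rasch_cml(
    responses: ResponseMatrix,
    anchors: Sequence | None = None,
    center: str = "items",
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> RaschFit:
    """Estimate item difficulties by conditional maximum likelihood.

    Items without score variance among administered responses are excluded
    with a warning.  The solution is identified by a sum-zero constraint over
    the estimated items; with ``center="anchors"`` the reported difficulties
    are re-centred so the ``anchors`` subset has mean zero (the common-metric
    convention for anchored multi-form designs).
    """
    arr = responses.scores.to_numpy(dtype=float)
    item_ids = responses.item_ids
    estimable, excluded = [], []
    for j, iid in enumerate(item_ids):
        col = arr[:, j]
        col = col[~np.isnan(col)]
        if col.size and 0 < col.sum() < col.size:
            estimable.append(iid)
        else:
            excluded.append(iid)
    if excluded:
        warnings.warn(f"excluding items without score variance: {excluded}")
    if len(estimable) < 2:
        raise ValueError("need at least 2 estimable items")
    groups = _prepare_groups(responses, estimable)
    if not groups:
        raise ValueError("no informative response patterns")
    k = len(estimable)

    def pack(free):
        return np.append(free, -free.sum())

    def objective(free):
        nll, grad_full = _neg_cll_and_grad(pack(free), groups)
        return nll, grad_full[:-1] - grad_full[-1]

    res = optimize.minimize(
        objective, np.zeros(k - 1), jac=True, method="L-BFGS-B",
        options={"gtol": gtol, "maxiter": max_iter, "ftol": 1e-13})
    gnorm = float(np.max(np.abs(res.jac))) if np.size(res.jac) else 0.0
    if not res.success and gnorm > 1e-4:
        raise RuntimeError(
            f"CML did not converge: {res.message} (max |gradient| = {gnorm:.2e})")
    delta = pack(res.x)

    # observed (= expected, here) information and SEs under the sum-zero map
    H = np.zeros((k, k))
    for idx, _totals, counts in groups:
        eps = np.exp(-delta[idx])
        H[np.ix_(idx, idx)] += _conditional_score_cov(eps, counts)
    J = np.vstack([np.eye(k - 1), -np.ones(k - 1)])  # free -> full
    H_free = J.T @ H @ J
    cov_free = np.linalg.inv(H_free)
    cov_full = J @ cov_free @ J.T
    se = np.sqrt(np.diag(cov_full))

    if center == "anchors":
        if not anchors:
            raise ValueError("center='anchors' requires an anchor item list")
        a_idx = [estimable.index(a) for a in anchors if a in estimable]
        if not a_idx:
            raise ValueError("no anchor item is estimable")
        delta = delta - delta[a_idx].mean()
    elif center != "items":
        raise ValueError("center must be 'items' or 'anchors'")

    return RaschFit(
        difficulties=pd.Series(delta, index=estimable, name="delta"),
        se=pd.Series(se, index=estimable, name="se"),
        cond_loglik=-float(res.fun),
        excluded_items=excluded,
        convergence={"converged": True, "iterations": int(res.nit),
                     "grad_norm": gnorm},
        center=center,
    )


# --------------------------------------------------------------------------
# Person estimation
# --------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def estimate_persons(fit: RaschFit, responses: ResponseMatrix) -> PersonEstimates:
    """Person-wise ML ability estimates with difficulties held fixed.

    Perfect and zero raw scores have no finite ML estimate and are flagged in
    ``excluded_persons``.  SE is the reciprocal square-root of the test
    information at the estimate.
    """
    delta = fit.difficulties
    theta, se, excluded = {}, {}, []
    for pid, row in responses.scores.iterrows():
        admin = [i for i in delta.index if pd.notna(row.get(i))]
        if not admin:
            excluded.append(pid)
            continue
        d = delta[admin].to_numpy()
        r = float(sum(row[i] for i in admin))
        if r == 0 or r == len(admin):
            excluded.append(pid)
            continue

        def score_eq(t, d=d, r=r):
            return _logistic(t - d).sum() - r

        t_hat = optimize.brentq(score_eq, -12.0, 12.0)
        p = _logistic(t_hat - d)
        info = float((p * (1 - p)).sum())
        theta[pid] = t_hat
        se[pid] = 1.0 / np.sqrt(info)
    return PersonEstimates(
        theta=pd.Series(theta, name="theta"),
        se=pd.Series(se, name="se"),
        excluded_persons=excluded)


# --------------------------------------------------------------------------
# Model tests
# --------------------------------------------------------------------------

def _split_persons(responses: ResponseMatrix, split):
    """Mean/median raw-score split, or explicit person-id groups."""
    if not isinstance(split, str):
        groups = [pd.Index(g) for g in split]
        if len(groups) < 2 or any(len(g) == 0 for g in groups):
            raise ValueError("explicit split needs >= 2 non-empty groups")
        return groups
    arr = responses.scores.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prop = np.nanmean(arr, axis=1)
    cut = np.nanmean(prop) if split == "mean" else np.nanmedian(prop)
    low = responses.scores.index[prop <= cut]
    high = responses.scores.index[prop > cut]
    if len(low) == 0 or len(high) == 0:
        raise ValueError(f"{split}-split produced an empty subgroup")
    return [low, high]


def _common_estimable(responses: ResponseMatrix, groups_idx) -> list:
    common = None
    for keep in groups_idx:
        arr = responses.scores.loc[keep]
        ok = []
        for iid in arr.columns:
            col = arr[iid].dropna()
            if col.size and 0 < col.sum() < col.size:
                ok.append(iid)
        common = set(ok) if common is None else common & set(ok)
    return [i for i in responses.item_ids if i in common]


def andersen_lr_test(responses: ResponseMatrix, split="mean") -> dict:
    """Andersen's likelihood-ratio test of item homogeneity.

    Persons are split on their raw-score proportion (mean split by default);
    the statistic is 2 * (sum of subgroup conditional log-likelihoods minus
    the pooled one), with df = (G - 1)(k - 1) for k jointly estimable items.
    """
    groups_idx = _split_persons(responses, split)
    common = _common_estimable(responses, groups_idx)
    if len(common) < 2:
        raise ValueError("fewer than 2 items estimable in every subgroup")
    sub_resp = ResponseMatrix(responses.scores[common])
    total = fit_rasch_cml(sub_resp)
    ll_groups = []
    for g, keep in enumerate(groups_idx):
        try:
            ll_groups.append(fit_rasch_cml(sub_resp.subset_persons(keep)).cond_loglik)
        except (ValueError, RuntimeError) as err:
            raise ValueError(f"subgroup {g} not estimable: {err}") from err
    stat = 2.0 * (sum(ll_groups) - total.cond_loglik)
    k = len(common)
    df = (len(groups_idx) - 1) * (k - 1)
    from scipy import stats
    return {"statistic": float(max(stat, 0.0)), "df": int(df),
            "p": float(stats.chi2.sf(max(stat, 0.0), df)),
            "split": split if isinstance(split, str) else "explicit",
            "n_items": k}


def wald_item_tests(
    responses: ResponseMatrix, split="mean", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-item Wald comparison of difficulties between two subsamples.

    Both subsample solutions are identified by sum-zero over the shared
    estimable items; z_i = (d1_i - d2_i) / sqrt(se1_i^2 + se2_i^2).  The
    returned frame flags items with p < alpha.
    """
    groups_idx = _split_persons(responses, split)
    common = _common_estimable(responses, groups_idx)
    if len(common) < 2:
        raise ValueError("fewer than 2 items estimable in every subgroup")
    sub_resp = ResponseMatrix(responses.scores[common])
    fits = [fit_rasch_cml(sub_resp.subset_persons(keep)) for keep in groups_idx]
    d1, d2 = fits[0].difficulties, fits[1].difficulties
    s1, s2 = fits[0].se, fits[1].se
    from scipy import stats
    z = (d1 - d2) / np.sqrt(s1 ** 2 + s2 ** 2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"delta_1": d1, "delta_2": d2, "z": z, "p": p,
                         "flagged": p < alpha})


# --------------------------------------------------------------------------
# Information and reliability
# --------------------------------------------------------------------------

def test_information(
    difficulties: Sequence[float], theta_grid: np.ndarray | None = None
) -> TestInfo:
    """Fisher test information sum_i p_i(theta)(1 - p_i(theta)) on a grid."""
    d = np.asarray(list(difficulties), dtype=float)
    if d.size == 0:
        raise ValueError("empty item set")
    if theta_grid is None:
        theta_grid = np.arange(-6.0, 6.0 + 1e-9, 0.01)
    p = _logistic(theta_grid[:, None] - d[None, :])
    info = (p * (1.0 - p)).sum(axis=1)
    i_max = int(np.argmax(info))
    return TestInfo(theta_grid=theta_grid, info=info,
                    max_info=float(info[i_max]),
                    argmax_theta=float(theta_grid[i_max]))


def person_separation_reliability(persons: PersonEstimates) -> float:
    """(observed theta variance - mean squared SE) / observed theta variance."""
    theta = persons.theta.dropna().to_numpy()
    if theta.size < 2:
        raise ValueError("need at least 2 estimated persons")
    var = float(np.var(theta, ddof=1))
    if var <= 0:
        warnings.warn("zero ability variance; reliability set to 0")
        return 0.0
    mse = float((persons.se.to_numpy() ** 2).mean())
    return max(0.0, (var - mse) / var)
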