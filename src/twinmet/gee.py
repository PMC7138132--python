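"""Linear GEE with exchangeable working correlation and sandwich errors.

Marginal linear model for clustered (family) data.  The working covariance
within a cluster of size :math:`k` is exchangeable,
:math:`R = (1-\\alpha) I + \\alpha J`, whose inverse is
:math:`a I + b J` with :math:`a = 1/(1-\\alpha)` and
:math:`b = -\\alpha / ((1-\\alpha)(1 + (k-1)\\alpha))`.  Because the inverse
is affine in two cluster-level matrices that do not depend on
:math:`\\alpha`, the estimating equations can be assembled once per dataset
and solved simultaneously for many outcome columns, each with its own
estimated :math:`\\alpha` — which is what makes replicate-heavy calibration
studies of the discovery phase cheap.

Standard errors are the usual robust (sandwich) estimator
:math:`B^{-1} M B^{-1}` summed over clusters; the scale parameter cancels.
With singleton clusters the estimator reduces exactly to OLS with HC0
heteroscedasticity-robust errors.  Wald p-values use the standard-normal
reference.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fit_exchangeable_gee", "gee_association", "gee_many"]


def _cluster_layout(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    sizes = np.diff(np.r_[starts, len(sorted_groups)])
    return order, starts, sizes


def fit_exchangeable_gee(X: np.ndarray, Y: np.ndarray, groups,
                         max_iter: int = 100, tol: float = 1e-12) -> dict:
    """Fit the exchangeable linear GEE for one or many outcome columns.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column).
    Y : (n,) or (n, K) outcomes; no missing values (handle upstream).
    groups : (n,) cluster labels.

    Returns
    -------
    dict with ``beta`` (p, K), ``se`` (p, K), ``alpha`` (K,), ``n_iter``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    K = Y.shape[1]
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains missing values")
    if not np.isfinite(Y).all():
        raise ValueError("outcomes contain missing values; drop them upstream")
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("at least 2 clusters are required")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix (collinear or constant columns)")

    order, starts, sizes = _cluster_layout(groups)
    Xs, Ys = X[order], Y[order]
    size_values = np.unique(sizes)
    kmax = int(size_values.max())

    # alpha-independent sufficient statistics per cluster-size class
    sx = np.add.reduceat(Xs, starts, axis=0)                 # (ncl, p)
    sy = np.add.reduceat(Ys, starts, axis=0)                 # (ncl, K)
    XtX_c = np.add.reduceat(Xs[:, :, None] * Xs[:, None, :], starts, axis=0)
    XtY_c = np.add.reduceat(Xs[:, :, None] * Ys[:, None, :], starts, axis=0)
    S, T, U, W = {}, {}, {}, {}
    for k in size_values:
        m = sizes == k
        S[k] = XtX_c[m].sum(axis=0)
        T[k] = np.einsum("cp,cq->pq", sx[m], sx[m])
        U[k] = XtY_c[m].sum(axis=0)
        W[k] = np.einsum("cp,ck->pk", sx[m], sy[m])
    pairs_total = int((sizes * (sizes - 1) // 2).sum())

    alpha = np.zeros(K)
    beta = np.zeros((p, K))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        A = np.zeros((K, p, p))
        rhs = np.zeros((K, p))
        for k in size_values:
            a = 1.0 / (1.0 - alpha)
            b = -alpha / ((1.0 - alpha) * (1.0 + (k - 1) * alpha))
            A += a[:, None, None] * S[k] + b[:, None, None] * T[k]
            rhs += (a[:, None] * U[k].T) + (b[:, None] * W[k].T)
        new_beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T  # (p, K)
        E = Ys - Xs @ new_beta                                      # (n, K)
        if pairs_total > 0:
            scale = (E ** 2).sum(axis=0) / max(n - p, 1)
            se_sum = np.add.reduceat(E, starts, axis=0)             # (ncl, K)
            sq_sum = np.add.reduceat(E ** 2, starts, axis=0)
            cross = 0.5 * (se_sum ** 2 - sq_sum).sum(axis=0)
            denom = max(pairs_total - p, 1) * scale
            new_alpha = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
            lo = -0.99 / (kmax - 1) if kmax > 1 else 0.0
            new_alpha = np.clip(new_alpha, lo, 0.99)
        else:
            new_alpha = np.zeros(K)
        delta = np.max(np.abs(new_beta - beta))
        beta, alpha = new_beta, new_alpha
        if delta < tol and n_iter > 1:
            break

    # sandwich covariance
    E = Ys - Xs @ beta
    Xte_c = np.add.reduceat(Xs[:, :, None] * E[:, None, :], starts, axis=0)  # (ncl,p,K)
    se_sum = np.add.reduceat(E, starts, axis=0)                              # (ncl,K)
    a_c = 1.0 / (1.0 - alpha)[None, :]                                       # (1,K)
    kc = sizes[:, None].astype(float)
    b_c = -alpha[None, :] / ((1.0 - alpha[None, :])
                             * (1.0 + (kc - 1.0) * alpha[None, :]))          # (ncl,K)
    g = a_c[:, None, :] * Xte_c + b_c[:, None, :] * (sx[:, :, None] * se_sum[:, None, :])
    M = np.einsum("cpk,cqk->kpq", g, g)
    A = np.zeros((K, p, p))
    for k in size_values:
        a = 1.0 / (1.0 - alpha)
        b = -alpha / ((1.0 - alpha) * (1.0 + (k - 1) * alpha))
        A += a[:, None, None] * S[k] + b[:, None, None] * T[k]
    Ainv = np.linalg.inv(A)
    cov = Ainv @ M @ Ainv
    se = np.sqrt(np.maximum(np.einsum("kpp->kp", cov), 0.0)).T  # (p, K)
    return {"beta": beta, "se": se, "alpha": alpha, "n_iter": n_iter}


def _build_design(status: np.ndarray, covariates: Optional[pd.DataFrame]) -> np.ndarray:
    cols = [np.ones_like(status, dtype=float), status.astype(float)]
    names = ["intercept", "status"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def gee_association(outcome, status, covariates: Optional[pd.DataFrame],
                    clusters) -> dict:
    """Association of one outcome with a binary status, family-clustered.

    Missing outcomes are dropped (complete-case) with ``n`` recorded;
    missing covariates or a constant status raise.  Returns a record dict
    with ``beta``, ``se``, ``p``, ``n`` and the working correlation
    ``alpha`` for the status coefficient.
    """
    y = np.asarray(outcome, float)
    s = np.asarray(status, float)
    g = np.asarray(clusters)
    ok = np.isfinite(y)
    y, s, g = y[ok], s[ok], g[ok]
    cov = covariates.iloc[np.flatnonzero(ok)] if covariates is not None else None
    if cov is not None and cov.isna().any().any():
        raise ValueError("covariates contain missing values")
    if len(np.unique(s)) < 2:
        raise ValueError("status is constant; the design is singular")
    X, _names = _build_design(s, cov)
    res = fit_exchangeable_gee(X, y, g)
    beta = float(res["beta"][1, 0])
    se = float(res["se"][1, 0])
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {"beta": beta, "se": se, "p": max(p, np.nextafter(0, 1)),
            "n": int(len(y)), "alpha": float(res["alpha"][0])}


def gee_many(outcomes: pd.DataFrame, status, covariates: Optional[pd.DataFrame],
             clusters) -> pd.DataFrame:
    """Run :func:`gee_association` for every outcome column, batched.

    Columns without missing values share one vectorized fit; columns with
    missing cells are fitted individually on their complete cases.
    """
    s = np.asarray(status, float)
    g = np.asarray(clusters)
    if outcomes.shape[1] == 0:
        return pd.DataFrame(columns=["beta", "se", "p", "n", "alpha"],
                            index=pd.Index([], name="id"))
    if len(np.unique(s)) < 2:
        raise ValueError("status is constant; the design is singular")
    if covariates is not None and covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    X, _ = _build_design(s, covariates)
    Y = outcomes.to_numpy(float)
    complete = np.isfinite(Y).all(axis=0)
    records = {}
    if complete.any():
        res = fit_exchangeable_gee(X, Y[:, complete], g)
        for j, name in enumerate(outcomes.columns[complete]):
            beta, se = float(res["beta"][1, j]), float(res["se"][1, j])
            z = beta / se if se > 0 else np.inf * np.sign(beta)
            records[name] = {
                "beta": beta, "se": se,
                "p": max(float(2.0 * stats.norm.sf(abs(z))), np.nextafter(0, 1)),
                "n": int(Y.shape[0]), "alpha": float(res["alpha"][j]),
            }
    for name in outcomes.columns[~complete]:
        records[name] = gee_association(outcomes[name], s, covariates, g)
    df = pd.DataFrame.from_dict(records, orient="index")
    df = df.reindex(outcomes.columns)
    df.index.name = "id"
    return df
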