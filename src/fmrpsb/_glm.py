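"""Penalised and unpenalised logistic regression by Newton iteration.

A single solver backs both the rare-variant burden test (Firth's
penalised likelihood, which keeps estimates finite under complete
separation) and the CNV association model (ordinary logistic), so the
permutation loop in the CNV module stays cheap. Collinear columns are
detected with a pivoted QR and dropped before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = ["LogisticFit", "fit_logistic"]

_MAX_ITER = 100
_SCORE_TOL = 1e-6


@dataclass
class LogisticFit:
    """Coefficients, standard errors and Wald p-values of a logistic fit.

    ``kept`` holds indices of design columns retained after collinearity
    screening; entries of ``beta``/``se``/``p`` for dropped columns are NaN.
    """

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    n_iter: int
    kept: np.ndarray
    dropped: np.ndarray
    loglik: float


def _screen_collinear(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (kept, dropped) column indices using pivoted QR rank detection."""
    n, k = X.shape
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size and diag.max() > 0 else 0.0
    rank = int((diag > tol).sum())
    kept = np.sort(piv[:rank])
    dropped = np.sort(piv[rank:])
    return kept, dropped


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    firth: bool = False,
) -> LogisticFit:
    """Fit ``logit P(y=1) = X beta`` by Newton-Raphson.

    With ``firth=True`` the Jeffreys-prior penalty ``0.5 log det I(beta)``
    is added to the likelihood and the score is adjusted by the standard
    hat-diagonal term, giving finite estimates even under complete
    separation. Convergence requires the max absolute (adjusted) score
    component below 1e-6 within 100 iterations; step-halving guards each
    Newton update. Standard errors come from the observed (penalised)
    information; p-values are two-sided Wald.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    n, k_full = X.shape

    kept, dropped = _screen_collinear(X)
    Xk = X[:, kept]
    k = Xk.shape[1]
    if n < k:
        raise ValueError("more columns than observations after screening")

    beta = np.zeros(k)

    def penalised_loglik(b: np.ndarray) -> float:
        eta = Xk @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if firth:
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            info = Xk.T @ (Xk * w[:, None])
            sign, logdet = np.linalg.slogdet(info)
            ll += 0.5 * logdet if sign > 0 else -np.inf
        return ll

    ll = penalised_loglik(beta)
    converged = False
    it = 0
    info = np.eye(k)
    for it in range(1, _MAX_ITER + 1):
        eta = Xk @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = Xk.T @ (Xk * w[:, None])
        if firth:
            # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
            try:
                cho = linalg.cho_factor(info)
            except linalg.LinAlgError:
                info = info + 1e-8 * np.eye(k)
                cho = linalg.cho_factor(info)
            B = linalg.cho_solve(cho, Xk.T)  # (k, n)
            h = w * np.einsum("ij,ji->i", Xk, B)
            score = Xk.T @ (y - mu + h * (0.5 - mu))
        else:
            try:
                cho = linalg.cho_factor(info)
            except linalg.LinAlgError:
                info = info + 1e-8 * np.eye(k)
                cho = linalg.cho_factor(info)
            score = Xk.T @ (y - mu)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        step = linalg.cho_solve(cho, score)
        # step-halving on the (penalised) objective
        for _ in range(25):
            cand = beta + step
            ll_new = penalised_loglik(cand)
            if ll_new >= ll - 1e-10:
                break
            step *= 0.5
        beta = beta + step
        ll = ll_new

    cov = np.linalg.inv(info)
    se_k = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_k > 0, beta / se_k, np.nan)
    p_k = 2.0 * stats.norm.sf(np.abs(z))

    full_beta = np.full(k_full, np.nan)
    full_se = np.full(k_full, np.nan)
    full_p = np.full(k_full, np.nan)
    full_beta[kept] = beta
    full_se[kept] = se_k
    full_p[kept] = p_k
    return LogisticFit(
        beta=full_beta,
        se=full_se,
        p=full_p,
        converged=converged,
        n_iter=it,
        kept=kept,
        dropped=dropped,
        loglik=ll,
    )
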