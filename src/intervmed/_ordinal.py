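"""Proportional-odds (cumulative logit) maximum likelihood.

Parametrised as P(Y <= j | x) = expit(tau_j - x'beta) with strictly
increasing cutpoints tau.  The log-likelihood is concave in (beta, tau),
so the primary solver is a damped Newton iteration with the analytic
Hessian; a quasi-Newton search on a log-difference reparametrisation is
kept as a fallback.  An optional ridge penalty on the slopes stabilises
separated fits that arise in small bootstrap strata.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_EPS = 1e-12


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:p]
    raw = theta[p:]
    tau = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))]) if len(raw) > 1 else raw.copy()
    return beta, tau


def _start_tau(y_codes: np.ndarray, n_cats: int) -> np.ndarray:
    freqs = np.bincount(y_codes, minlength=n_cats) / len(y_codes)
    cum = np.clip(np.cumsum(freqs)[:-1], 1e-4, 1 - 1e-4)
    tau = np.log(cum / (1 - cum))
    # enforce strict ordering for degenerate starts
    for j in range(1, len(tau)):
        tau[j] = max(tau[j], tau[j - 1] + 1e-3)
    return tau


def _terms(beta, tau, X, y_codes, n_cats):
    eta = X @ beta
    upper = np.where(y_codes < n_cats - 1, tau[np.minimum(y_codes, n_cats - 2)] - eta, np.inf)
    lower = np.where(y_codes > 0, tau[np.maximum(y_codes - 1, 0)] - eta, -np.inf)
    Fu, Fl = expit(upper), expit(lower)
    fu = np.where(np.isfinite(upper), Fu * (1 - Fu), 0.0)
    fl = np.where(np.isfinite(lower), Fl * (1 - Fl), 0.0)
    fpu = np.where(np.isfinite(upper), fu * (1 - 2 * Fu), 0.0)
    fpl = np.where(np.isfinite(lower), fl * (1 - 2 * Fl), 0.0)
    prob = np.clip(Fu - Fl, _EPS, None)
    return prob, fu, fl, fpu, fpl


def _nll(beta, tau, X, y_codes, n_cats, ridge) -> float:
    prob, *_ = _terms(beta, tau, X, y_codes, n_cats)
    return float(-np.sum(np.log(prob)) + ridge * beta @ beta)


def _grad_hess(beta, tau, X, y_codes, n_cats, ridge):
    n, p = X.shape
    k = n_cats - 1
    prob, fu, fl, fpu, fpl = _terms(beta, tau, X, y_codes, n_cats)
    up = np.minimum(y_codes, k - 1)  # index of the upper cutpoint
    lo = np.maximum(y_codes - 1, 0)  # index of the lower cutpoint
    has_u = y_codes < n_cats - 1
    has_l = y_codes > 0

    deta = (fu - fl) / prob
    gbeta = X.T @ deta + 2.0 * ridge * beta
    gtau = np.zeros(k)
    np.add.at(gtau, up, np.where(has_u, -fu / prob, 0.0))
    np.add.at(gtau, lo, np.where(has_l, fl / prob, 0.0))

    p2 = prob * prob
    # -d2 ll / d eta2
    w = ((fl - fu) ** 2 - prob * (fpu - fpl)) / p2
    Hbb = (X.T * w) @ X + 2.0 * ridge * np.eye(p)

    cu = np.where(has_u, ((fl - fu) * fu + prob * fpu) / p2, 0.0)
    cl = np.where(has_l, (-(fl - fu) * fl - prob * fpl) / p2, 0.0)
    Hbt = np.zeros((p, k))
    for j in range(k):
        mask_u = has_u & (up == j)
        mask_l = has_l & (lo == j)
        Hbt[:, j] = X[mask_u].T @ cu[mask_u] + X[mask_l].T @ cl[mask_l]

    Htt = np.zeros((k, k))
    du = np.where(has_u, (fu * fu - prob * fpu) / p2, 0.0)
    dl = np.where(has_l, (fl * fl + prob * fpl) / p2, 0.0)
    diag = np.zeros(k)
    np.add.at(diag, up, du)
    np.add.at(diag, lo, dl)
    Htt[np.diag_indices(k)] = diag
    both = has_u & has_l  # middle categories link adjacent cutpoints
    off = np.zeros(k - 1) if k > 1 else np.zeros(0)
    if k > 1:
        vals = np.where(both, -fu * fl / p2, 0.0)
        np.add.at(off, lo[both], vals[both])
        Htt[np.arange(k - 1), np.arange(1, k)] += off
        Htt[np.arange(1, k), np.arange(k - 1)] += off

    grad = np.concatenate([gbeta, gtau])
    H = np.block([[Hbb, Hbt], [Hbt.T, Htt]])
    return grad, H


def _newton_direct(X, y_codes, n_cats, ridge, maxiter=50):
    n, p = X.shape
    beta = np.zeros(p)
    tau = _start_tau(y_codes, n_cats)
    nll = _nll(beta, tau, X, y_codes, n_cats, ridge)
    for _ in range(maxiter):
        grad, H = _grad_hess(beta, tau, X, y_codes, n_cats, ridge)
        if np.max(np.abs(grad)) < 1e-8 * (1.0 + abs(nll)):
            return beta, tau, nll, True
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(grad)), grad)
        except np.linalg.LinAlgError:
            return beta, tau, nll, False
        scale = 1.0
        for _ in range(40):
            nb = beta - scale * step[:p]
            nt = tau - scale * step[p:]
            if (n_cats <= 2 or np.all(np.diff(nt) > 0)):
                nll_new = _nll(nb, nt, X, y_codes, n_cats, ridge)
                if np.isfinite(nll_new) and nll_new <= nll + 1e-10:
                    break
            scale *= 0.5
        else:
            return beta, tau, nll, False
        converged = abs(nll - nll_new) < 1e-12 * (1.0 + abs(nll))
        beta, tau, nll = nb, nt, nll_new
        if converged:
            grad, _ = _grad_hess(beta, tau, X, y_codes, n_cats, ridge)
            return beta, tau, nll, bool(np.max(np.abs(grad)) < 1e-6 * (1.0 + abs(nll)))
    grad, _ = _grad_hess(beta, tau, X, y_codes, n_cats, ridge)
    return beta, tau, nll, bool(np.max(np.abs(grad)) < 1e-6 * (1.0 + abs(nll)))


def _nll_grad_reparam(theta, X, y_codes, n_cats, ridge):
    """nll and gradient in the log-difference parametrisation (fallback)."""
    n, p = X.shape
    beta, tau = _unpack(theta, p)
    prob, fu, fl, _, _ = _terms(beta, tau, X, y_codes, n_cats)
    nll = -np.sum(np.log(prob)) + ridge * beta @ beta
    k = n_cats - 1
    deta = (fu - fl) / prob
    gbeta = X.T @ deta + 2.0 * ridge * beta
    gtau = np.zeros(k)
    np.add.at(gtau, np.minimum(y_codes, k - 1), np.where(y_codes < n_cats - 1, -fu / prob, 0.0))
    np.add.at(gtau, np.maximum(y_codes - 1, 0), np.where(y_codes > 0, fl / prob, 0.0))
    graw = np.zeros(k)
    graw[0] = gtau.sum()
    if k > 1:
        raw = theta[p:]
        rev = np.cumsum(gtau[::-1])[::-1]
        graw[1:] = rev[1:] * np.exp(raw[1:])
    return nll, np.concatenate([gbeta, graw])


def fit_proportional_odds(
    X: np.ndarray, y_codes: np.ndarray, n_cats: int, ridge: float = 0.0, maxiter: int = 500
):
    """Fit; returns (beta, cutpoints, nll, converged)."""
    n, p = X.shape
    beta, tau, nll, ok = _newton_direct(X, y_codes, n_cats, ridge)
    if not ok:
        tau0 = _start_tau(y_codes, n_cats)
        raw0 = np.concatenate([[tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-4))])
        res = minimize(
            _nll_grad_reparam,
            np.concatenate([np.zeros(p), raw0]),
            args=(X, y_codes, n_cats, ridge),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res.fun < nll:  # keep whichever solver got further
            beta, tau = _unpack(res.x, p)
            nll, ok = float(res.fun), bool(res.success)
        else:
            ok = True
    return beta, tau, float(nll - ridge * beta @ beta), bool(ok)


def category_probs(eta: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """(n, K) matrix of category probabilities given linear predictors."""
    cum = expit(tau[None, :] - np.asarray(eta)[:, None])
    cum = np.concatenate([np.zeros((len(cum), 1)), cum, np.ones((len(cum), 1))], axis=1)
    return np.diff(cum, axis=1)
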