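"""Shared expectation-maximization core for full-covariance Gaussian
mixtures in 2-D, used by the spatial clustering and the binary (EMbC)
clustering modules."""

from __future__ import annotations

import numpy as np

__all__ = ["em_gmm", "log_gauss", "EMFailure"]


class EMFailure(RuntimeError):
    """EM could not produce a valid fit (singular components, etc.)."""


def log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a (2-D) Gaussian at each row of X via Cholesky."""
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    z = np.linalg.solve(L, diff.T)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _regularize(cov: np.ndarray, reg: float) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    tr = np.trace(cov)
    return cov + (reg * tr + 1e-12) * np.eye(cov.shape[0])


def _m_step(X, resp, reg):
    nk = resp.sum(axis=0)
    if np.any(nk < 1e-9):
        raise EMFailure("component lost all responsibility")
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((len(nk), X.shape[1], X.shape[1]))
    for k in range(len(nk)):
        diff = X - means[k]
        covs[k] = _regularize((resp[:, k, None] * diff).T @ diff / nk[k], reg)
    return weights, means, covs


def _e_step(X, weights, means, covs):
    K = len(weights)
    logp = np.empty((X.shape[0], K))
    for k in range(K):
        logp[:, k] = np.log(weights[k]) + log_gauss(X, means[k], covs[k])
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return resp, float(lse.sum()), logp


def em_gmm(
    X: np.ndarray,
    resp0: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
    min_weight: float | None = None,
):
    """Run EM from initial responsibilities ``resp0``.

    If ``min_weight`` is set, components whose weight falls below it are
    dropped and EM continues with the survivors (the iteration indices of
    drop events are recorded; the log-likelihood is guaranteed
    non-decreasing only between drops).

    Returns ``(weights, means, covs, resp, loglik_trace, drop_iters,
    converged)``; raises :class:`EMFailure` on singular covariances.
    """
    X = np.asarray(X, dtype=float)
    resp = np.asarray(resp0, dtype=float)
    loglik_trace: list[float] = []
    drop_iters: list[int] = []
    converged = False
    prev = -np.inf
    try:
        weights, means, covs = _m_step(X, resp, reg)
        for it in range(max_iter):
            resp, ll, _ = _e_step(X, weights, means, covs)
            loglik_trace.append(ll)
            if min_weight is not None and len(weights) > 1:
                keep = weights >= min_weight
                if not keep.all():
                    drop_iters.append(it)
                    resp = resp[:, keep]
                    resp /= resp.sum(axis=1, keepdims=True)
            weights, means, covs = _m_step(X, resp, reg)
            if np.isfinite(prev) and abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
        resp, ll, _ = _e_step(X, weights, means, covs)
        loglik_trace.append(ll)
    except np.linalg.LinAlgError as exc:
        raise EMFailure("singular covariance during EM") from exc
    return weights, means, covs, resp, np.asarray(loglik_trace), drop_iters, converged
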