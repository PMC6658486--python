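"""Spatial Gaussian-mixture clustering of sampling coordinates.

Coordinates are projected from WGS84 degrees to a local equirectangular
meter frame (degrees are anisotropic at mid latitudes), a full-covariance
2-D Gaussian mixture is fit by EM from seeded random-assignment starts, and
the model is selected by minimum AIC jointly over several initial component
counts and restarts. A raw-degree mode is available for parity with tools
that fit directly on lon/lat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._em import EMFailure, em_gmm, log_gauss

__all__ = [
    "SpatialPoints",
    "GMMFit",
    "SpatialClustering",
    "project_coordinates",
    "em_fit",
    "aic",
    "select_clustering",
    "assign_clusters",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class SpatialPoints:
    """Geo-referenced individuals with a local meter-frame projection."""

    individual_ids: list[str]
    lon: np.ndarray
    lat: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lon0: float
    lat0: float
    cohort: str | None = None

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def n(self) -> int:
        return len(self.individual_ids)


def project_coordinates(individual_ids, lon, lat, cohort=None) -> SpatialPoints:
    """Project lon/lat (WGS84 decimal degrees) to meters with a local
    equirectangular projection about the centroid:
    x = R * dlon * cos(lat0), y = R * dlat (radians)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat) > 89.0):
        raise ValueError("latitudes must be within +/-89 degrees")
    lon0 = float(lon.mean())
    lat0 = float(lat.mean())
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * np.cos(np.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return SpatialPoints(list(individual_ids), lon, lat, x, y, lon0, lat0, cohort)


def unproject_coordinates(x, y, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_coordinates` (exact up to float rounding)."""
    lon = lon0 + np.degrees(np.asarray(x, float) / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    lat = lat0 + np.degrees(np.asarray(y, float) / EARTH_RADIUS_M)
    return lon, lat


@dataclass
class GMMFit:
    """One converged EM fit of a 2-D Gaussian mixture."""

    K_init: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    loglik_trace: np.ndarray
    drop_iters: list[int]
    converged: bool
    seed: int

    @property
    def n_effective_components(self) -> int:
        return len(self.weights)

    @property
    def aic(self) -> float:
        return aic(self)


def aic(fit: GMMFit) -> float:
    """Akaike information criterion, 2k - 2 lnL with
    k = 2K (means) + 3K (covariances) + (K - 1) (weights) free parameters,
    K the number of effective components."""
    k = 6 * fit.n_effective_components - 1
    return 2.0 * k - 2.0 * fit.log_likelihood


def em_fit(
    points: SpatialPoints | np.ndarray,
    K: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_weight: float = 1e-3,
    max_restarts: int = 5,
) -> GMMFit:
    """EM fit of a K-component full-covariance Gaussian mixture.

    Initialization assigns points uniformly at random to K groups (seeded).
    Covariances are regularized by +1e-6*trace*I; components whose weight
    falls below ``min_weight`` are dropped and EM continues, so the
    effective component count can be smaller than K. Convergence is
    |delta logL| < tol. Singular fits are retried with fresh seeds up to
    ``max_restarts`` times.
    """
    X = points.xy if isinstance(points, SpatialPoints) else np.asarray(points, dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError("need more points than components")
    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        # seeded random partition with distance-weighted (k-means++ style)
        # seed spreading, then nearest-seed groups. Uniform random labels
        # leave all K groups at the global centroid (EM stalls at a
        # symmetric saddle); uniformly drawn seed points often miss one of
        # K equal clusters. Spread seeds avoid both failure modes.
        seeds = [X[rng.integers(n)]]
        for _ in range(K - 1):
            d2min = np.min(
                ((X[:, None, :] - np.asarray(seeds)[None, :, :]) ** 2).sum(axis=2),
                axis=1,
            )
            tot = d2min.sum()
            if tot <= 0:
                seeds.append(X[rng.integers(n)])
                continue
            seeds.append(X[rng.choice(n, p=d2min / tot)])
        seeds = np.asarray(seeds)
        d2 = ((X[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        for k in range(K):
            if not np.any(assign == k):
                assign[rng.integers(0, n)] = k
        resp0 = np.zeros((n, K))
        resp0[np.arange(n), assign] = 1.0
        try:
            weights, means, covs, _, trace, drops, converged = em_gmm(
                X, resp0, tol=tol, max_iter=max_iter, min_weight=min_weight
            )
            return GMMFit(
                K_init=K,
                weights=weights,
                means=means,
                covariances=covs,
                log_likelihood=float(trace[-1]),
                loglik_trace=trace,
                drop_iters=drops,
                converged=converged,
                seed=seed,
            )
        except EMFailure as exc:
            last_exc = exc
    raise EMFailure(f"EM failed after {max_restarts} restarts") from last_exc


@dataclass
class SpatialClustering:
    """Minimum-AIC mixture fit with MAP cluster labels (1-based)."""

    points: SpatialPoints
    fit: GMMFit
    labels: np.ndarray
    responsibilities: np.ndarray
    candidates: pd.DataFrame  # K_init, seed, aic, effective K per attempted run
    all_fits: list | None = None  # every attempted GMMFit (keep_fits=True)

    @property
    def n_clusters(self) -> int:
        return self.fit.n_effective_components

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.points.individual_ids,
                "cluster": self.labels,
                "posterior_max": self.responsibilities.max(axis=1),
            }
        )


def assign_clusters(fit: GMMFit, points: SpatialPoints | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MAP component (1-based label) and posterior responsibilities per
    point; exact posterior ties go to the lowest component index."""
    X = points.xy if isinstance(points, SpatialPoints) else np.asarray(points, dtype=float)
    K = fit.n_effective_components
    logp = np.empty((X.shape[0], K))
    for k in range(K):
        logp[:, k] = np.log(fit.weights[k]) + log_gauss(X, fit.means[k], fit.covariances[k])
    m = logp.max(axis=1, keepdims=True)
    resp = np.exp(logp - m)
    resp /= resp.sum(axis=1, keepdims=True)
    labels = np.argmax(logp, axis=1) + 1  # argmax takes the lowest index on ties
    return labels, resp


def select_clustering(
    points: SpatialPoints,
    K_list=(4, 5, 6),
    runs_per_K: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    keep_fits: bool = False,
) -> SpatialClustering:
    """Fit ``runs_per_K`` seeded restarts for every K in ``K_list`` and keep
    the minimum-AIC fit across all runs and K values jointly.

    Components of the chosen fit are re-ordered by increasing mean x
    (i.e. roughly SW to NE in the projected frame) so labels are stable and
    geographically interpretable. All candidate AICs are recorded.
    """
    if points.n <= max(K_list):
        raise ValueError("need more points than the largest K")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) for s in ss.generate_state(len(K_list) * runs_per_K) % (2**31 - 1)]
    rows = []
    fits: list[GMMFit] = []
    best: GMMFit | None = None
    idx = 0
    for K in K_list:
        for _ in range(runs_per_K):
            rseed = run_seeds[idx]
            idx += 1
            try:
                fit = em_fit(points, K, seed=rseed, tol=tol, max_iter=max_iter)
            except EMFailure:
                rows.append({"K_init": K, "seed": rseed, "aic": np.nan, "effective_K": 0})
                continue
            rows.append(
                {
                    "K_init": K,
                    "seed": rseed,
                    "aic": fit.aic,
                    "effective_K": fit.n_effective_components,
                }
            )
            if keep_fits:
                fits.append(fit)
            if best is None or fit.aic < best.aic:
                best = fit
        # K loop
    if best is None:
        raise EMFailure("all mixture fits failed")
    order = np.argsort(best.means[:, 0], kind="stable")
    best = GMMFit(
        K_init=best.K_init,
        weights=best.weights[order],
        means=best.means[order],
        covariances=best.covariances[order],
        log_likelihood=best.log_likelihood,
        loglik_trace=best.loglik_trace,
        drop_iters=best.drop_iters,
        converged=best.converged,
        seed=best.seed,
    )
    labels, resp = assign_clusters(best, points)
    return SpatialClustering(
        points=points,
        fit=best,
        labels=labels,
        responsibilities=resp,
        candidates=pd.DataFrame(rows),
        all_fits=fits if keep_fits else None,
    )
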