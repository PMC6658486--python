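"""Disperser categories from relatedness and space.

Pairwise relatedness is rescaled to [0, 1]; each individual is summarized
by its mean normalized relatedness to members of its own spatial cluster
(rIN) and to everyone outside it (rOUT); a 4-component Gaussian mixture is
fit to the (rIN, rOUT) plane by EM and each component is coded low/high on
each axis (expectation-maximization binary clustering), yielding the four
disperser categories:

- MIXED  (HH): high rIN, high rOUT — common genotypes, related to many;
- SHORT  (HL): high rIN, low rOUT — likely local recruits;
- MEDIUM (LH): low rIN, high rOUT — movers from elsewhere in the area;
- LONG   (LL): low rIN, low rOUT — likely immigrants from afar.

Two normalization modes exist. ``order_preserving`` (default) maps
d = (r - a)/(b - a) so the axes read as relatedness, matching the verbal
category semantics. ``literal_inverted`` applies d = 1 - (r - a)/(b - a),
which reverses the order; with the fixed code-to-category map this swaps
MIXED with LONG and SHORT with MEDIUM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._em import EMFailure, em_gmm, log_gauss
from .relatedness import RelatednessMatrix
from .spatial import SpatialClustering

__all__ = [
    "NormalizedRelatedness",
    "InOutProfile",
    "EmbcModel",
    "DisperserAssignment",
    "normalize_relatedness",
    "compute_rin_rout",
    "embc_fit",
    "assign_categories",
    "category_proportions",
    "CODE_TO_CATEGORY",
    "CATEGORIES",
]

CODE_TO_CATEGORY = {"HH": "MIXED", "HL": "SHORT", "LH": "MEDIUM", "LL": "LONG"}
CATEGORIES = ("MIXED", "SHORT", "MEDIUM", "LONG")
_CODES = ("LL", "LH", "HL", "HH")


@dataclass
class NormalizedRelatedness:
    """Pairwise relatedness rescaled to [0, 1] (masked pairs stay NaN)."""

    individual_ids: list[str]
    d: np.ndarray
    a: float  # min of r
    b: float  # max of r
    mode: str


def normalize_relatedness(rm: RelatednessMatrix, mode: str = "order_preserving") -> NormalizedRelatedness:
    """Rescale relatedness values to [0, 1] using the observed min (a) and
    max (b): order_preserving d = (r-a)/(b-a); literal_inverted d = 1 - that."""
    if mode not in ("order_preserving", "literal_inverted"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = rm.offdiag_values()
    if vals.size == 0:
        raise ValueError("no defined relatedness values")
    a = float(vals.min())
    b = float(vals.max())
    if not b > a:
        raise ValueError("degenerate relatedness: min == max")
    d = (rm.r - a) / (b - a)
    if mode == "literal_inverted":
        d = 1.0 - d
    return NormalizedRelatedness(list(rm.individual_ids), d, a, b, mode)


@dataclass
class InOutProfile:
    """Per-individual within/outside-cluster mean normalized relatedness."""

    table: pd.DataFrame  # columns: id, cluster, r_in, r_out, valid

    @property
    def valid_mask(self) -> np.ndarray:
        return self.table["valid"].to_numpy(dtype=bool)

    def valid_xy(self) -> np.ndarray:
        t = self.table[self.table["valid"]]
        return t[["r_in", "r_out"]].to_numpy(dtype=float)


def compute_rin_rout(d: NormalizedRelatedness, clustering: SpatialClustering | np.ndarray) -> InOutProfile:
    """Mean normalized relatedness of each individual to its own spatial
    cluster (rIN, excluding itself) and to all individuals outside it (rOUT).

    Masked pairs are excluded from both means. Members of singleton
    clusters (rIN undefined) and of a cluster covering the whole cohort
    (rOUT undefined) are flagged invalid.
    """
    if isinstance(clustering, SpatialClustering):
        if list(clustering.points.individual_ids) != list(d.individual_ids):
            raise ValueError("clustering and relatedness cover different individuals")
        labels = clustering.labels
    else:
        labels = np.asarray(clustering)
        if labels.shape[0] != len(d.individual_ids):
            raise ValueError("label vector length mismatch")
    n = len(d.individual_ids)
    same = labels[:, None] == labels[None, :]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for i in range(n):
            din = d.d[i, same[i]]
            dout = d.d[i, ~same[i]]
            r_in = np.nanmean(din) if din.size else np.nan  # diagonal NaN drops self
            r_out = np.nanmean(dout) if dout.size else np.nan
            rows.append(
                {
                    "id": d.individual_ids[i],
                    "cluster": labels[i],
                    "r_in": r_in,
                    "r_out": r_out,
                    "valid": bool(np.isfinite(r_in) and np.isfinite(r_out)),
                }
            )
    return InOutProfile(table=pd.DataFrame(rows))


@dataclass
class EmbcModel:
    """4-component binary-coded Gaussian mixture over (rIN, rOUT)."""

    weights: np.ndarray
    means: np.ndarray        # (4, 2)
    covariances: np.ndarray  # (4, 2, 2)
    codes: tuple[str, ...]   # per-component code over (rIN, rOUT), e.g. "HL"
    delimiters: tuple[float, float]  # per-axis low/high frontier
    seed: int
    converged: bool
    loglik_trace: np.ndarray


def _quadrant_resp(X: np.ndarray, cut_x: float, cut_y: float) -> np.ndarray | None:
    """Hard responsibilities from a 2-D threshold split; None if a quadrant
    is empty."""
    qx = (X[:, 0] >= cut_x).astype(int)
    qy = (X[:, 1] >= cut_y).astype(int)
    assign = 2 * qx + qy
    if len(np.unique(assign)) < 4:
        return None
    resp = np.zeros((X.shape[0], 4))
    resp[np.arange(X.shape[0]), assign] = 1.0
    return resp


def _corner_codes(X: np.ndarray, means: np.ndarray) -> tuple[tuple[str, ...], float]:
    """Match the 4 component means to the 4 corner prototypes built from
    per-axis lower/upper half means, minimizing total squared distance over
    all 24 assignments. Returns the per-component codes and the matching
    cost (a binary-coherence score: low when components sit near corners)."""
    lows, highs = [], []
    for ax in range(2):
        med = np.median(X[:, ax])
        lo = X[X[:, ax] <= med, ax].mean()
        hi = X[X[:, ax] > med, ax].mean() if np.any(X[:, ax] > med) else lo
        lows.append(lo)
        highs.append(hi)
    corners = {
        "LL": np.array([lows[0], lows[1]]),
        "LH": np.array([lows[0], highs[1]]),
        "HL": np.array([highs[0], lows[1]]),
        "HH": np.array([highs[0], highs[1]]),
    }
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(_CODES):
        cost = sum(
            float(np.sum((means[k] - corners[perm[k]]) ** 2)) for k in range(4)
        )
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return tuple(best_perm), best_cost


def _axis_delimiter(weights, means, covs, codes, axis: int) -> float:
    """Equiprobability frontier on one axis: the point where the weighted
    sums of the 1-D marginal densities of L-coded and H-coded components are
    equal, found by bisection (tolerance 1e-9)."""
    lo_idx = [k for k in range(4) if codes[k][axis] == "L"]
    hi_idx = [k for k in range(4) if codes[k][axis] == "H"]
    mus = means[:, axis]
    sds = np.sqrt(covs[:, axis, axis])

    def g(t: float) -> float:
        fl = sum(weights[k] * norm.pdf(t, mus[k], sds[k]) for k in lo_idx)
        fh = sum(weights[k] * norm.pdf(t, mus[k], sds[k]) for k in hi_idx)
        return fl - fh

    wl = sum(weights[k] for k in lo_idx)
    wh = sum(weights[k] for k in hi_idx)
    m_lo = sum(weights[k] * mus[k] for k in lo_idx) / wl
    m_hi = sum(weights[k] * mus[k] for k in hi_idx) / wh
    a, b = (m_lo, m_hi) if m_lo <= m_hi else (m_hi, m_lo)
    ga, gb = g(a), g(b)
    if ga == 0.0:
        return float(a)
    if ga * gb > 0:  # not bracketed; scan for a crossing
        grid = np.linspace(a, b, 513)
        vals = np.array([g(t) for t in grid])
        sign = np.sign(vals)
        flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
        if flips.size == 0:
            return float((m_lo + m_hi) / 2.0)
        a, b = grid[flips[0]], grid[flips[0] + 1]
        ga = g(a)
    for _ in range(200):
        mid = (a + b) / 2.0
        if b - a < 1e-9:
            break
        gm = g(mid)
        if gm == 0.0:
            return float(mid)
        if ga * gm < 0:
            b = mid
        else:
            a, ga = mid, gm
    return float((a + b) / 2.0)


def embc_fit(profiles, seed: int = 0, tol: float = 1e-6, max_iter: int = 500,
             n_random_starts: int = 3) -> EmbcModel:
    """Expectation-maximization binary clustering of (rIN, rOUT) profiles.

    A 4-component full-covariance Gaussian mixture is fit by EM from
    several quadrant-split starts (axis cuts at the median and at the
    quartiles, plus seeded random assignments). Components of each
    converged fit get binary codes over (rIN, rOUT) by corner matching
    (minimum total squared distance between component means and the 4
    corner prototypes built from per-axis lower/upper half means), and
    per-axis low/high delimiters are placed at the equiprobability frontier
    of the L- and H-coded component groups.

    Among the candidate fits the maximum-likelihood one is kept, subject
    to the binary-support constraint that no component is nearly empty
    (weight >= 0.03): every one of the four low/high regions must be
    carried by a real component. Degenerate fits — where the mixture
    spends a component on a sliver of density instead of a binary region —
    are used only if nothing better converged.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("profiles must be (n, 2): columns rIN, rOUT")
    if X.shape[0] < 8:
        raise ValueError("need at least 8 valid profiles")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero variance on an axis")

    qx = np.quantile(X[:, 0], [0.25, 0.5, 0.75])
    qy = np.quantile(X[:, 1], [0.25, 0.5, 0.75])
    cut_inits = [
        (qx[1], qy[1]),
        (qx[0], qy[0]),
        (qx[2], qy[2]),
        (qx[0], qy[2]),
        (qx[2], qy[0]),
    ]
    resp_inits = [r for r in (_quadrant_resp(X, cx, cy) for cx, cy in cut_inits)
                  if r is not None]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        assign = rng.integers(0, 4, size=X.shape[0])
        for k in range(4):
            if not np.any(assign == k):
                assign[rng.integers(0, X.shape[0])] = k
        r = np.zeros((X.shape[0], 4))
        r[np.arange(X.shape[0]), assign] = 1.0
        resp_inits.append(r)

    best = None
    last_exc: Exception | None = None
    for resp0 in resp_inits:
        try:
            weights, means, covs, _, trace, _, converged = em_gmm(
                X, resp0, tol=tol, max_iter=max_iter, min_weight=None
            )
        except EMFailure as exc:
            last_exc = exc
            continue
        codes, _ = _corner_codes(X, means)
        delim = (
            _axis_delimiter(weights, means, covs, codes, axis=0),
            _axis_delimiter(weights, means, covs, codes, axis=1),
        )
        # constrained maximum likelihood: a component with near-zero weight
        # cannot carry one of the four binary regions, so such fits are
        # used only when nothing better converged
        degenerate = float(weights.min()) < 0.03
        cand = (degenerate, -trace[-1], weights, means, covs,
                codes, delim, trace, converged)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise EMFailure("all EMbC starts failed") from last_exc
    _, _, weights, means, covs, codes, delim, trace, converged = best
    return EmbcModel(
        weights=weights,
        means=means,
        covariances=covs,
        codes=codes,
        delimiters=delim,
        seed=seed,
        converged=converged,
        loglik_trace=trace,
    )


@dataclass
class DisperserAssignment:
    """Per-individual rIN/rOUT, binary code and disperser category."""

    table: pd.DataFrame  # id, cluster, r_in, r_out, code, category

    def counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()


def assign_categories(model: EmbcModel, profiles: InOutProfile) -> DisperserAssignment:
    """MAP-component binary code per valid profile, mapped to categories via
    the fixed map HH→MIXED, HL→SHORT, LH→MEDIUM, LL→LONG; invalid profiles
    are UNASSIGNED."""
    t = profiles.table.copy()
    codes = np.array(["" for _ in range(len(t))], dtype=object)
    cats = np.array(["UNASSIGNED"] * len(t), dtype=object)
    valid = profiles.valid_mask
    if valid.any():
        X = t.loc[valid, ["r_in", "r_out"]].to_numpy(dtype=float)
        logp = np.empty((X.shape[0], 4))
        for k in range(4):
            logp[:, k] = np.log(model.weights[k]) + log_gauss(
                X, model.means[k], model.covariances[k]
            )
        comp = np.argmax(logp, axis=1)
        codes[valid] = [model.codes[k] for k in comp]
        cats[valid] = [CODE_TO_CATEGORY[model.codes[k]] for k in comp]
    t["code"] = codes
    t["category"] = cats
    return DisperserAssignment(table=t)


def category_proportions(assign: DisperserAssignment, clustering=None) -> pd.DataFrame:
    """Per-spatial-cluster counts and category proportions (among assigned,
    non-UNASSIGNED members). Rows sum to 1; empty clusters are omitted with
    a warning. Column order: cluster, N, MIXED, SHORT, MEDIUM, LONG."""
    t = assign.table
    rows = []
    for cluster, grp in t.groupby("cluster", sort=True):
        assigned = grp[grp["category"] != "UNASSIGNED"]
        if len(assigned) == 0:
            warnings.warn(f"cluster {cluster} has no assigned members; row omitted")
            continue
        row = {"cluster": cluster, "N": len(grp)}
        for cat in CATEGORIES:
            row[cat] = float((assigned["category"] == cat).mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["cluster", "N", *CATEGORIES])
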