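"""Cohort comparison statistics: Welch t-tests, two-sample
Kolmogorov-Smirnov tests on coastline-axis positions, and Pearson
correlations, each returned as a labelled :class:`TestResult`."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spatial import SpatialPoints

__all__ = [
    "TestResult",
    "welch_t_test",
    "ks_two_sample",
    "project_to_coastline_axis",
    "compare_cohorts",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    label: str = ""

    def describe(self) -> str:
        return (
            f"{self.label or self.test}: stat={self.statistic:.4g}, "
            f"p={self.p_value:.4g} (n1={self.n1}, n2={self.n2}, "
            f"means {self.mean1:.4g} vs {self.mean2:.4g})"
        )


def _descriptives(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x, y, dict(
        n1=int(x.size),
        n2=int(y.size),
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        sd1=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        sd2=float(y.std(ddof=1)) if y.size > 1 else 0.0,
    )


def welch_t_test(x, y, label: str = "") -> TestResult:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df).

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1.
    """
    x, y, desc = _descriptives(x, y)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if desc["sd1"] == 0.0 and desc["sd2"] == 0.0:
        if desc["mean1"] == desc["mean2"]:
            return TestResult("welch_t", 0.0, 1.0, **desc, label=label)
        return TestResult("welch_t", np.inf if desc["mean1"] > desc["mean2"] else -np.inf,
                          0.0, **desc, label=label)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(t), float(p), **desc, label=label)


def ks_two_sample(x, y, method: str = "auto", label: str = "") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs
    (right-continuous convention for ties); the p-value uses the exact
    small-sample distribution when feasible and the asymptotic Kolmogorov
    distribution otherwise (``method`` as in scipy).
    """
    x, y, desc = _descriptives(x, y)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    res = stats.ks_2samp(x, y, method=method)
    return TestResult("ks_2samp", float(res.statistic), float(res.pvalue), **desc, label=label)


def project_to_coastline_axis(points: SpatialPoints | np.ndarray) -> np.ndarray:
    """Project meter-frame coordinates onto the first principal axis of the
    pooled point cloud, oriented so SW→NE is increasing.

    The sampling area is a quasi-one-dimensional stretch of coastline, so
    its first principal axis is the natural 1-D frame for distributional
    (KS) comparisons.
    """
    X = points.xy if isinstance(points, SpatialPoints) else np.asarray(points, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / X.shape[0]
    if np.allclose(cov, 0):
        raise ValueError("degenerate point cloud: all points identical")
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    # Orient toward the northeast quadrant (positive x+y); fall back to +x.
    s = axis[0] + axis[1]
    if s < 0 or (s == 0 and axis[0] < 0):
        axis = -axis
    return Xc @ axis


def compare_cohorts(values1, values2, variable: str, kind: str | None = None,
                    label: str = "") -> TestResult:
    """Dispatch a labelled comparison between two cohorts.

    ``kind`` may be "welch_t" or "ks"; when omitted it is inferred from the
    variable name: spatial positions go to KS, scalar traits (PLD, sizes,
    heterozygosity, relatedness means...) to Welch's t.
    """
    if kind is None:
        kind = "ks" if variable in ("position", "coastline_position", "space") else "welch_t"
    label = label or f"{variable}"
    if kind == "welch_t":
        return welch_t_test(values1, values2, label=label)
    if kind == "ks":
        return ks_two_sample(values1, values2, label=label)
    raise ValueError(f"unknown test kind {kind!r}")
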