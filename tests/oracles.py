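"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (exact
rational arithmetic, naive double loops, ECDF sweeps) and share no code
with the implementation paths they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided HWE p-value by full enumeration with rational
    arithmetic: P(h) proportional to 2^h * n! / (n1! h! n2!) over all
    heterozygote counts with the observed allele totals and parity."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    if na == 0 or nb == 0:
        return 1.0

    def weight(h: int) -> Fraction:
        n1 = (na - h) // 2
        n2 = (nb - h) // 2
        # multinomial n!/(n1! h! n2!) * 2^h, exact
        return Fraction(2**h) * Fraction(
            comb(n, n1) * comb(n - n1, h)
        )

    hs = [h for h in range(na % 2, min(na, nb) + 1, 2)]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    p_obs = weights[n_het]
    acc = sum(w for w in weights.values() if w <= p_obs)
    return float(Fraction(acc, total))


def qg_brute_force(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Naive per-pair, per-locus, per-allele Queller-Goodnight matrix.

    Works on allele strings built from dosage (count of allele "A"),
    evaluating the directional formula symbol by symbol and pooling
    numerators/denominators over loci and both directions.
    """
    n, L = dosage.shape

    def alleles(i, l):
        d = dosage[i, l]
        if d < 0:
            return None
        return ["A"] * int(d) + ["B"] * int(2 - d)

    def freq(l, a):
        return p[l] if a == "A" else 1.0 - p[l]

    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for l in range(L):
                if not np.isfinite(p[l]):
                    continue
                xi, xj = alleles(i, l), alleles(j, l)
                if xi is None or xj is None:
                    continue
                for focal, other in ((xi, xj), (xj, xi)):
                    a, b = focal
                    c, d = other
                    share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
                    num += share - freq(l, a) - freq(l, b)
                    den += 1.0 + (a == b) - freq(l, a) - freq(l, b)
            if abs(den) > 1e-12:
                out[i, j] = out[j, i] = num / den
    return out


def ks_statistic_sweep(x, y) -> float:
    """Two-sample KS D by evaluating both ECDFs at every pooled point."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    d = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        d = max(d, abs(fx - fy))
    return float(d)
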