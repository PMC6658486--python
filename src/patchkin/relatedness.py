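"""Pairwise Queller-Goodnight relatedness, the per-individual relatedness
ratio, and the quantile local / recent-migrant classification.

The Queller-Goodnight estimator measures relatedness of a pair relative to
reference allele frequencies: full sibs expect ~0.5, unrelated pairs ~0, and
values can be negative for pairs sharing fewer alleles than random draws
would. Multilocus estimates here pool numerator and denominator sums over
loci and over both focal directions (ratio of sums, SPAGeDi-style), which is
stable when single-locus denominators are small.

For biallelic loci the per-locus directional terms reduce to functions of
allele-1 dosages x (focal) and y (partner) and allele-1 frequency p::

    num = 0.5*(x*y + (2-x)*(2-y)) - S_x
    den = 1 + hom_x - S_x,   S_x = x*p + (2-x)*(1-p),  hom_x = [x != 1]

which is what the vectorized matrix path computes; the pooled symmetric
estimate is (num_xy + num_yx) / (den_xy + den_yx) summed over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, allele_frequencies

__all__ = [
    "RelatednessMatrix",
    "RatioClassification",
    "qg_pair_directional",
    "qg_matrix",
    "relatedness_ratio",
    "classify_locals_migrants",
]


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness estimates for one cohort.

    ``r`` is N x N with NaN on the diagonal and at pairs with no informative
    locus; ``n_loci`` counts pairwise-complete loci per pair.
    """

    individual_ids: list[str]
    r: np.ndarray
    n_loci: np.ndarray

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def offdiag_values(self) -> np.ndarray:
        """All defined pairwise values (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.r[iu]
        return vals[np.isfinite(vals)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (id_i, id_j, r, n_loci) table, i < j."""
        ii, jj = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "id_i": [self.individual_ids[i] for i in ii],
                "id_j": [self.individual_ids[j] for j in jj],
                "r": self.r[ii, jj],
                "n_loci": self.n_loci[ii, jj],
            }
        )


def qg_pair_directional(x_calls, y_calls, freqs) -> tuple[float, float]:
    """Directional Queller-Goodnight numerator/denominator sums with ``x``
    as the focal individual.

    Parameters
    ----------
    x_calls, y_calls : sequences of allele pairs (2-tuples of hashables) or
        None for a missing call, one entry per locus.
    freqs : sequence of dicts mapping allele -> frequency, one per locus
        (reference frequencies, normally from the whole cohort).

    Per locus, with focal alleles (a, b) and partner alleles (c, d)::

        num = 0.5*(d_ac + d_ad + d_bc + d_bd) - p_a - p_b
        den = 1 + d_ab - p_a - p_b

    where ``d`` is the allele-identity indicator. Loci missing in either
    individual are skipped; loci where num = den = 0 still contribute (0, 0).
    """
    num = 0.0
    den = 0.0
    used = 0
    for x, y, pf in zip(x_calls, y_calls, freqs):
        if x is None or y is None:
            continue
        a, b = x
        c, d = y
        pa = pf[a]
        pb = pf[b]
        share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num += share - pa - pb
        den += 1.0 + (a == b) - pa - pb
        used += 1
    if used == 0:
        raise ValueError("no pairwise-complete loci for this pair")
    return num, den


def qg_matrix(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelatednessMatrix:
    """Symmetric multilocus Queller-Goodnight relatedness matrix.

    Reference allele frequencies default to the cohort's own (including each
    focal pair, SPAGeDi-style). Pairs whose pooled denominator is zero are
    masked (NaN), as are the diagonal entries.
    """
    if g.n_individuals < 2:
        raise ValueError("cohort of one: relatedness undefined")
    p = allele_frequencies(g) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (g.n_loci,):
        raise ValueError("frequency vector length must equal number of loci")

    typed = g.typed & np.isfinite(p)  # drop fully-missing loci (p undefined)
    m = typed.astype(float)
    x = np.where(typed, g.dosage, 0).astype(float)
    psafe = np.where(np.isfinite(p), p, 0.0)

    # Per-individual per-locus terms (zeroed at missing entries).
    s = (x * psafe + (2.0 - x) * (1.0 - psafe)) * m  # p_a + p_b of own alleles
    hom = ((x != 1.0).astype(float)) * m             # delta_ab indicator

    xm = x * m
    mmt = m @ m.T                                    # pairwise-complete loci
    # Sum over loci of symmetrized numerator:
    #   (2xy - 2x - 2y + 4) - S_i - S_j  on jointly typed loci
    num = 2.0 * (xm @ xm.T) - 2.0 * (xm @ m.T) - 2.0 * (m @ xm.T) + 4.0 * mmt
    num -= (s @ m.T) + (m @ s.T)
    # Sum over loci of symmetrized denominator: 2 + hom_i + hom_j - S_i - S_j
    den = 2.0 * mmt + (hom @ m.T) + (m @ hom.T) - (s @ m.T) - (m @ s.T)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(np.abs(den) > 1e-12, num / den, np.nan)
    np.fill_diagonal(r, np.nan)
    r = (r + r.T) / 2.0  # symmetric up to float noise by construction
    n_loci = mmt.astype(int)
    np.fill_diagonal(n_loci, 0)
    return RelatednessMatrix(list(g.individual_ids), r, n_loci)


def relatedness_ratio(rm: RelatednessMatrix, r_threshold: float = 0.1) -> np.ndarray:
    """Per-individual fraction of pairwise r-values strictly above
    ``r_threshold`` among that individual's defined comparisons.

    Individuals with no defined pair get NaN (excluded downstream).
    """
    defined = np.isfinite(rm.r)
    above = defined & (rm.r > r_threshold)
    n_def = defined.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_def > 0, above.sum(axis=1) / n_def, np.nan)
    return ratio


@dataclass
class RatioClassification:
    """Quantile classification of a cohort by relatedness ratio."""

    table: pd.DataFrame  # columns: id, ratio, label
    cutoff_quantile: float
    r_threshold: float
    k: int

    @property
    def locals_(self) -> list[str]:
        return self.table.loc[self.table["label"] == "local", "id"].tolist()

    @property
    def migrants(self) -> list[str]:
        return self.table.loc[self.table["label"] == "recent_migrant", "id"].tolist()

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def classify_locals_migrants(
    ids,
    ratios,
    q: float = 0.25,
    r_threshold: float = 0.1,
) -> RatioClassification:
    """Label the top-q fraction of ratios 'local' and the bottom-q fraction
    'recent_migrant'; everyone else is 'unclassified'.

    k = round-half-up(q * N) per tail over individuals with a defined ratio;
    ties are broken by stable input (id) order. Individuals with undefined
    ratios are always 'unclassified'.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    ids = list(ids)
    ratios = np.asarray(ratios, dtype=float)
    if len(ids) != ratios.shape[0]:
        raise ValueError("ids and ratios differ in length")
    valid = np.flatnonzero(np.isfinite(ratios))
    n = valid.size
    if n < 4:
        raise ValueError("need at least 4 individuals with defined ratios")
    k = _round_half_up(q * n)
    vals = ratios[valid]
    if np.unique(vals).size == 1:
        warnings.warn("all relatedness ratios equal; quantile cut taken by id order")
    # Stable orderings: descending for locals, ascending for migrants.
    desc = valid[np.argsort(-vals, kind="stable")]
    asc = valid[np.argsort(vals, kind="stable")]
    labels = np.array(["unclassified"] * len(ids), dtype=object)
    local_set = list(desc[:k])
    taken = set(local_set)
    migrant_set = [i for i in asc if i not in taken][:k]
    labels[local_set] = "local"
    labels[migrant_set] = "recent_migrant"
    table = pd.DataFrame({"id": ids, "ratio": ratios, "label": labels})
    return RatioClassification(table=table, cutoff_quantile=q, r_threshold=r_threshold, k=k)
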