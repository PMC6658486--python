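"""Diploid biallelic SNP genotype tables: containers, I/O, locus summaries
and the Hardy-Weinberg / linkage-disequilibrium locus filter.

Genotypes are held as an N x L *dosage* matrix: the number of copies
(0, 1 or 2) of each locus' first allele, where the first allele is the
lexicographically smaller of the two observed alleles so that different
file dialects normalize to the same matrix. Missing calls are -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "GenotypeError",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "allele_frequencies",
    "locus_summaries",
    "hwe_exact_test",
    "ld_r2",
    "filter_loci",
]

MISSING = -1
_MISSING_TOKENS = {"0", "./.", ".", "", "0/0:missing", "NA", "nan"}


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci diploid genotype matrix.

    Parameters
    ----------
    individual_ids : list of unique individual identifiers (length N).
    locus_ids : list of unique locus identifiers (length L).
    alleles : (L, 2) array of allele strings; ``alleles[l, 0]`` is the
        lexicographically smaller allele of locus ``l``.
    dosage : (N, L) int8 array counting copies of ``alleles[l, 0]``;
        -1 marks a missing call.
    stage : optional per-individual life-stage labels (e.g. adult/juvenile).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray
    dosage: np.ndarray
    stage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.alleles = np.asarray(self.alleles)
        n, l = self.dosage.shape
        if n < 2:
            raise GenotypeError("need at least 2 individuals")
        if l < 1:
            raise GenotypeError("need at least 1 locus")
        if len(self.individual_ids) != n or len(self.locus_ids) != l:
            raise GenotypeError("id lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        if len(set(self.locus_ids)) != l:
            raise GenotypeError("duplicate locus ids")
        if self.alleles.shape != (l, 2):
            raise GenotypeError("alleles must be (L, 2)")
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise GenotypeError("dosage values must be in {-1, 0, 1, 2}")
        if self.stage is not None:
            self.stage = np.asarray(self.stage, dtype=object)
            if self.stage.shape[0] != n:
                raise GenotypeError("stage length does not match N")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def typed(self) -> np.ndarray:
        """(N, L) boolean mask of non-missing calls."""
        return self.dosage >= 0

    def call(self, i: int, l: int) -> str:
        """Slash-separated call for one cell, ``"./."`` when missing."""
        d = self.dosage[i, l]
        if d < 0:
            return "./."
        a, b = self.alleles[l]
        return "/".join([a] * int(d) + [b] * int(2 - d))

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or index array; order preserved."""
        ii = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        ll = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if ii.dtype == bool:
            ii = np.flatnonzero(ii)
        if ll.dtype == bool:
            ll = np.flatnonzero(ll)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ii],
            locus_ids=[self.locus_ids[l] for l in ll],
            alleles=self.alleles[ll],
            dosage=self.dosage[np.ix_(ii, ll)],
            stage=None if self.stage is None else self.stage[ii],
        )

    def to_slash_frame(self) -> pd.DataFrame:
        """One "A/G"-style column per locus, indexed by individual id."""
        cols = {}
        for l, lid in enumerate(self.locus_ids):
            a, b = self.alleles[l]
            lut = np.array(["/".join([b, b]), "/".join([a, b]), "/".join([a, a])], dtype=object)
            col = np.where(self.dosage[:, l] >= 0, lut[self.dosage[:, l]], "./.")
            cols[lid] = col
        return pd.DataFrame(cols, index=pd.Index(self.individual_ids, name="id"))


def _cell_to_alleles(token: object, row: object, col: str) -> tuple[str, str] | None:
    s = str(token).strip()
    if s in _MISSING_TOKENS:
        return None
    parts = s.split("/")
    if len(parts) == 1 and len(s) == 2:  # e.g. "AG"
        parts = [s[0], s[1]]
    if len(parts) != 2:
        raise GenotypeError(f"malformed call {s!r} at row {row!r}, column {col!r}")
    a, b = (p.strip() for p in parts)
    if not a or not b:
        raise GenotypeError(f"malformed call {s!r} at row {row!r}, column {col!r}")
    if a in _MISSING_TOKENS or b in _MISSING_TOKENS:
        return None
    return a, b


def _build_matrix(ids, locus_ids, pair_calls, stage=None) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from per-locus lists of allele pairs/None."""
    n, l = len(ids), len(locus_ids)
    dosage = np.full((n, l), MISSING, dtype=np.int8)
    alleles = np.empty((l, 2), dtype=object)
    for j, lid in enumerate(locus_ids):
        seen: set[str] = set()
        for pair in pair_calls[j]:
            if pair is not None:
                seen.update(pair)
        if len(seen) > 2:
            raise GenotypeError(f"locus {lid!r} has more than 2 alleles: {sorted(seen)}")
        if not seen:
            seen = {"?"}
        ordered = sorted(seen)
        if len(ordered) == 1:
            ordered = [ordered[0], ordered[0] + "*"]  # placeholder second allele
        alleles[j] = ordered
        a1 = ordered[0]
        for i, pair in enumerate(pair_calls[j]):
            if pair is not None:
                dosage[i, j] = (pair[0] == a1) + (pair[1] == a1)
    return GenotypeMatrix(list(ids), list(locus_ids), alleles, dosage, stage=stage)


def read_genotypes(path, format: str = "slash-call", id_column: str = "id") -> GenotypeMatrix:
    """Read a genotype table.

    ``format`` is one of:

    - ``"slash-call"`` — one column per locus holding calls like ``"A/G"``;
    - ``"two-column"`` — two columns per locus named ``<locus>_1``/``<locus>_2``;
    - ``"vcf"`` — a VCF file (biallelic SNP records only; needs cyvcf2).

    Missing genotypes may be coded ``"0"`` or ``"./."``. Row order is
    preserved and allele coding is normalized so the first allele of each
    locus is the lexicographically smaller one.
    """
    if format == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, dtype=str)
    if id_column not in df.columns:
        raise GenotypeError(f"missing id column {id_column!r}")
    ids = df[id_column].tolist()
    if format == "slash-call":
        locus_ids = [c for c in df.columns if c != id_column]
        pair_calls = [
            [_cell_to_alleles(v, ids[i], c) for i, v in enumerate(df[c])] for c in locus_ids
        ]
    elif format == "two-column":
        suffixed = [c for c in df.columns if c != id_column]
        bases: list[str] = []
        for c in suffixed:
            if c.endswith("_1"):
                base = c[:-2]
                if base + "_2" not in df.columns:
                    raise GenotypeError(f"column {c!r} has no matching {base + '_2'!r}")
                bases.append(base)
        if not bases:
            raise GenotypeError("no <locus>_1/<locus>_2 column pairs found")
        locus_ids = bases
        pair_calls = []
        for base in bases:
            col = []
            for i in range(len(ids)):
                a = str(df[base + "_1"].iloc[i]).strip()
                b = str(df[base + "_2"].iloc[i]).strip()
                if a in _MISSING_TOKENS or b in _MISSING_TOKENS:
                    col.append(None)
                else:
                    col.append((a, b))
            pair_calls.append(col)
    else:
        raise GenotypeError(f"unknown format {format!r}")
    if len(set(ids)) != len(ids):
        raise GenotypeError("duplicate individual ids in input")
    return _build_matrix(ids, locus_ids, pair_calls)


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenotypeError("VCF support requires cyvcf2") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    locus_ids, alleles_rows, dosage_cols = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at {v.CHROM}:{v.POS}")
            continue
        ref, alt = v.REF, v.ALT[0]
        a1, a2 = sorted([ref, alt])
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        ref_dose = np.select([gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING)
        dose = ref_dose if a1 == ref else np.where(ref_dose >= 0, 2 - ref_dose, MISSING)
        locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        alleles_rows.append([a1, a2])
        dosage_cols.append(dose.astype(np.int8))
    if not locus_ids:
        raise GenotypeError("no biallelic SNP records in VCF")
    dosage = np.stack(dosage_cols, axis=1)
    return GenotypeMatrix(ids, locus_ids, np.asarray(alleles_rows, dtype=object), dosage)


def write_genotypes(g: GenotypeMatrix, path, format: str = "slash-call") -> None:
    """Write a genotype table in one of the CSV dialects read back by
    :func:`read_genotypes` (round-trip safe)."""
    if format == "slash-call":
        g.to_slash_frame().to_csv(path)
    elif format == "two-column":
        cols: dict[str, list[str]] = {}
        for l, lid in enumerate(g.locus_ids):
            a, b = g.alleles[l]
            first, second = [], []
            for d in g.dosage[:, l]:
                if d < 0:
                    first.append("0")
                    second.append("0")
                else:
                    pair = [a] * int(d) + [b] * int(2 - d)
                    first.append(pair[0])
                    second.append(pair[1])
            cols[f"{lid}_1"] = first
            cols[f"{lid}_2"] = second
        pd.DataFrame(cols, index=pd.Index(g.individual_ids, name="id")).to_csv(path)
    else:
        raise GenotypeError(f"unknown format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-individual metadata table (id, stage, lon, lat,
    collection_date ISO 8601, length_mm)."""
    df = pd.read_csv(path)
    required = {"id", "stage", "lon", "lat", "collection_date", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeError(f"metadata missing columns: {sorted(missing)}")
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    return df


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus frequency of the first (lexicographically smaller) allele,
    computed over typed individuals only. Fully missing loci give NaN."""
    typed = g.typed
    n_typed = typed.sum(axis=0)
    counts = np.where(typed, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_typed > 0, counts / (2.0 * n_typed), np.nan)
    return p


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic locus.

    Conditional on the allele counts, heterozygote counts follow the
    Levene-Haldane distribution; the p-value sums the probabilities of all
    heterozygote counts (same parity, same allele totals) whose probability
    does not exceed that of the observed count.
    """
    n1, h, n2 = int(n_hom1), int(n_het), int(n_hom2)
    if min(n1, h, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n1 + h + n2
    if n < 1:
        raise ValueError("need at least one individual")
    na = 2 * n1 + h  # copies of allele 1
    nb = 2 * n2 + h
    if na == 0 or nb == 0:
        return 1.0  # monomorphic convention
    rare = min(na, nb)
    hs = np.arange(rare % 2, rare + 1, 2)
    # log P(h') up to a constant: -log(n1'! h'! n2'!) + h'*log 2
    h1 = (na - hs) // 2
    h2 = (nb - hs) // 2
    logp = hs * np.log(2.0) - gammaln(h1 + 1.0) - gammaln(hs + 1.0) - gammaln(h2 + 1.0)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.flatnonzero(hs == h)
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def locus_summaries(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary: allele-1 frequency ``p``, typed count, observed and
    expected heterozygosity and exact HWE p-value.

    Mean Ho/He across loci are ``df["Ho"].mean()`` / ``df["He"].mean()``.
    """
    typed = g.typed
    n_typed = typed.sum(axis=0)
    p = allele_frequencies(g)
    het = (g.dosage == 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_typed > 0, het.sum(axis=0) / n_typed, np.nan)
    he = 2.0 * p * (1.0 - p)
    hwe = np.empty(g.n_loci)
    for l in range(g.n_loci):
        d = g.dosage[typed[:, l], l]
        if d.size == 0:
            hwe[l] = np.nan
            continue
        hwe[l] = hwe_exact_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    return pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "p": p,
            "n_typed": n_typed,
            "Ho": ho,
            "He": he,
            "hwe_p": hwe,
        }
    )


def ld_r2(g: GenotypeMatrix, locus_a, locus_b) -> float:
    """Squared Pearson correlation of allele-dosage vectors over individuals
    typed at both loci. NaN if either locus is monomorphic in the shared set."""
    ia = locus_a if isinstance(locus_a, (int, np.integer)) else g.locus_ids.index(locus_a)
    ib = locus_b if isinstance(locus_b, (int, np.integer)) else g.locus_ids.index(locus_b)
    both = g.typed[:, ia] & g.typed[:, ib]
    x = g.dosage[both, ia].astype(float)
    y = g.dosage[both, ib].astype(float)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(g: GenotypeMatrix) -> np.ndarray:
    """Full L x L dosage-correlation-squared matrix, pairwise complete."""
    L = g.n_loci
    out = np.full((L, L), np.nan)
    typed = g.typed
    dose = g.dosage.astype(float)
    for a in range(L):
        for b in range(a + 1, L):
            both = typed[:, a] & typed[:, b]
            if both.sum() < 2:
                continue
            x, y = dose[both, a], dose[both, b]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
            out[a, b] = out[b, a] = r * r
    return out


def filter_loci(
    g: GenotypeMatrix,
    hwe_alpha: float = 0.05,
    r2_max: float = 0.8,
    bonferroni: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci out of Hardy-Weinberg equilibrium, then prune one locus of
    each pair in strong linkage disequilibrium.

    HWE: drop when the exact-test p-value falls below ``hwe_alpha``
    (Bonferroni-corrected across loci by default). LD: for each remaining
    pair with dosage r² > ``r2_max``, greedily drop the member with the lower
    typed count (ties: the larger locus index). Returns the filtered matrix
    and a report of dropped loci with reasons.
    """
    summ = locus_summaries(g)
    alpha = hwe_alpha / g.n_loci if bonferroni else hwe_alpha
    records = []
    keep = np.ones(g.n_loci, dtype=bool)
    for l in range(g.n_loci):
        pval = summ["hwe_p"].iloc[l]
        if np.isfinite(pval) and pval < alpha:
            keep[l] = False
            records.append({"locus_id": g.locus_ids[l], "reason": "hwe", "statistic": pval})
    sub_idx = np.flatnonzero(keep)
    if sub_idx.size == 0:
        raise GenotypeError("all loci dropped by the HWE filter")
    sub = g.subset(loci=sub_idx)
    r2 = _pairwise_r2(sub)
    n_typed = sub.typed.sum(axis=0)
    alive = np.ones(sub.n_loci, dtype=bool)
    for a in range(sub.n_loci):
        for b in range(a + 1, sub.n_loci):
            if not (alive[a] and alive[b]):
                continue
            v = r2[a, b]
            if np.isfinite(v) and v > r2_max:
                if n_typed[a] < n_typed[b]:
                    drop = a
                elif n_typed[b] < n_typed[a]:
                    drop = b
                else:
                    drop = max(a, b)
                alive[drop] = False
                records.append(
                    {"locus_id": sub.locus_ids[drop], "reason": "ld", "statistic": v}
                )
    final_idx = sub_idx[alive]
    if final_idx.size == 0:
        raise GenotypeError("all loci dropped")
    report = pd.DataFrame(records, columns=["locus_id", "reason", "statistic"])
    return g.subset(loci=final_idx), report
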