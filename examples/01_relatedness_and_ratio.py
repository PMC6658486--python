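"""Pairwise Queller-Goodnight relatedness and the local/migrant ratio.

Builds a small kin-structured cohort (full-sib families plus unrelated
singles), estimates the pairwise relatedness matrix, and classifies the
top/bottom quartiles of the per-individual relatedness ratio.
"""

import numpy as np

import patchkin as pk
from patchkin.genotypes import GenotypeMatrix

p = pk.simulate_allele_frequencies(178, seed=1)
dosage, family, _ = pk.simulate_families(p, n_families=10, family_size=4,
                                         seed=2, n_unrelated=40)
g = GenotypeMatrix(
    individual_ids=[f"fish{k:02d}" for k in range(len(dosage))],
    locus_ids=[f"snp{l}" for l in range(178)],
    alleles=np.array([["A", "G"]] * 178, dtype=object),
    dosage=dosage,
)

rm = pk.qg_matrix(g)
iu = np.triu_indices(rm.n, 1)
sib = (family[:, None] == family[None, :]) & (family[:, None] >= 0)
print(f"mean r among full sibs:  {np.nanmean(rm.r[iu][sib[iu]]):+.3f}  (expect ~0.5)")
print(f"mean r among unrelated:  {np.nanmean(rm.r[iu][~sib[iu]]):+.3f}  (expect ~0)")

ratios = pk.relatedness_ratio(rm, r_threshold=0.1)
cls = pk.classify_locals_migrants(g.individual_ids, ratios, q=0.25)
print(f"cohort of {rm.n}: {len(cls.locals_)} 'locals', {len(cls.migrants)} 'recent migrants'")
print("locals are the individuals with the most r-values above 0.1 — here,")
print("family members:", sorted(cls.locals_)[:6], "...")
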