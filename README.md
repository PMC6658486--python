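# patchkin

Fine-scale dispersal patchiness in marine populations from SNP relatedness,
spatial mixture clustering and otolith life-history traits.

Well-connected marine populations often look genetically homogeneous with
classical tools (F-statistics, assignment tests), yet recruitment can be
patchy on scales of a few kilometres: cohorts of related larvae settle
together, immigrants arrive unevenly, and the pattern shifts between years —
*chaotic genetic patchiness*. `patchkin` implements an integrative analysis
that makes such structure visible, for molecular ecologists working with
geo-referenced SNP genotypes of a dense cohort sample (here, a rocky-shore
fish, juveniles and adults typed at ~178 biallelic SNPs along ~2 km of
coastline), plus otolith-derived early-life-history traits.

## The method

1. **Locus filtering.** Loci out of Hardy–Weinberg equilibrium (exact
   Levene–Haldane test, Bonferroni-corrected) or in strong linkage
   disequilibrium (dosage r² pruning) are discarded.
2. **Pairwise relatedness.** The Queller–Goodnight moment estimator with
   cohort allele frequencies, pooled ratio-of-sums over loci and both focal
   directions: full sibs expect r ≈ 0.5, unrelated pairs r ≈ 0, negative
   values are informative. Per individual, the *relatedness ratio* —
   #{r > 0.1}/(N−1) — flags 'locals' (top 25%) and 'recent migrants'
   (bottom 25%).
3. **Spatial clustering.** Sampling coordinates (projected to a local meter
   frame) are clustered with a full-covariance Gaussian mixture fit by EM;
   4, 5 and 6 initial components × 10 seeded runs; minimum AIC
   (k = 6K − 1 parameters) selects the model.
4. **rIN / rOUT.** Relatedness is min–max normalized, d = (r−a)/(b−a)
   (an order-inverting variant d = 1 − (r−a)/(b−a) is available); each
   individual gets its mean d to members of its own spatial cluster (rIN)
   and to everyone outside it (rOUT).
5. **Binary clustering (EMbC).** A 4-component Gaussian mixture on the
   (rIN, rOUT) plane, with per-axis low/high delimiters at the
   equiprobability frontier between component groups, codes every
   individual LL/LH/HL/HH, read as four disperser categories:
   **MIXED** (HH — common genotypes, related to many), **SHORT** (HL —
   likely local recruits), **MEDIUM** (LH — movers from elsewhere in the
   area), **LONG** (LL — likely immigrants). Per-spatial-cluster category
   proportions are the headline output.
6. **Life history.** Otolith readings give pelagic larval duration (PLD)
   and total age for a subset; age ~ length OLS extends ages to the whole
   cohort; hatch dates, early/late season cohorts, recent-settler vs
   survivor classes, and PLD–hatch-date correlations follow. Cohort
   contrasts use Welch t-tests and two-sample Kolmogorov–Smirnov tests on
   coastline-axis positions.

A synthetic-data generator (`patchkin.simulate`) plants ground truth for
every stage — full-sib families retained at their natal site, displaced
family members, rare-allele-biased immigrants, common-genotype individuals,
Gaussian spatial clusters with a SW→NE gradient in local recruitment, and
linear trait models — so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs the full pipeline on the default synthetic cohort (627 juveniles,
178 SNPs, 6 spatial clusters) and prints:

```
cohort of 627: spatial K = 6, 157 locals, 157 recent migrants

per-cluster category proportions (clusters ordered SW->NE):
 cluster   N  MIXED  SHORT  MEDIUM  LONG
       1  92  0.315  0.228   0.380 0.076
       2  97  0.258  0.320   0.351 0.072
       3 106  0.264  0.358   0.311 0.066
       4 111  0.234  0.414   0.288 0.063
       5 110  0.245  0.491   0.200 0.064
       6 111  0.216  0.604   0.117 0.063

SHORT-range proportion, estimated vs planted:
  cluster 1: 0.228 vs 0.228
  ...
  cluster 6: 0.604 vs 0.559
max absolute error: 0.045
```

157 is round(0.25 × 627), the quantile rule's exact count; the SHORT
column rises from 0.23 (SW) to 0.60 (NE), recovering the planted gradient
of local recruitment within ±0.05 per cluster. The other examples
demonstrate each stage in isolation: relatedness and the ratio classifier
(`01`), AIC-selected spatial mixtures (`02`), disperser categories against
planted truth (`03`), and otolith analytics (`04`).

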