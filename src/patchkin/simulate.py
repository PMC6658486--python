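"""Kin-structured, spatially clustered synthetic SNP datasets with planted
truth.

The generator emulates the statistical structure of a dense coastal
sampling of a rocky-shore fish cohort: ~178 biallelic SNPs; full-sib
families retained near their natal site (SHORT-range dispersers); single
family members displaced to another spatial cluster (MEDIUM); immigrants
drawn from a Balding-Nichols-diverged source population, shifted toward
locally-rare alleles to mimic local ascertainment of the SNP panel (LONG);
and unrelated individuals carrying common-allele-biased genotypes that
confer mildly elevated relatedness to everybody (MIXED). Spatial clusters are
Gaussian blobs along a SW→NE coastline axis, with the planted SHORT
proportion increasing along it. Traits follow linear models: PLD declines
with hatch day (warmer water, faster development) and body length grows
linearly with age.

Every individual carries truth labels (family, source, planted class,
planted cluster), so each pipeline stage can be scored against ground
truth. All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_genotypes

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_allele_frequencies",
    "simulate_immigrant_frequencies",
    "simulate_families",
    "place_individuals",
    "simulate_traits",
    "generate",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the emulated study: a juvenile cohort of
    627 fish typed at 178 SNPs across 6 spatial clusters spanning ~2 km of
    coastline, with a SW→NE gradient in the planted SHORT-range proportion.
    """

    seed: int = 0
    n_individuals: int = 627
    n_loci: int = 178
    stage: str = "juvenile"

    # spatial layout: cluster centers every `cluster_spacing_m` along a
    # coastline bearing, isotropic Gaussian scatter of `cluster_sd_m`
    n_clusters: int = 6
    cluster_spacing_m: float = 330.0
    cluster_sd_m: float = 30.0
    coast_bearing_deg: float = 40.0
    origin_lon: float = 2.803
    origin_lat: float = 41.675

    # planted composition per cluster (SW→NE); MEDIUM takes the remainder
    short_proportions: tuple[float, ...] = (0.20, 0.28, 0.36, 0.44, 0.52, 0.60)
    mixed_proportion: float = 0.25
    long_proportion: float = 0.07

    # genetic structure
    family_size: int = 24
    fst_immigrants: float = 0.10
    common_genotype_bias: float = 0.35
    immigrant_rarity_bias: float = 0.35
    missing_rate: float = 0.02

    # trait models: pld = b0 + b1*hatch_day + N(0, sd); length = a0 + a1*age
    pld_intercept: float = 25.0
    pld_slope: float = -0.05
    pld_sd: float = 2.0
    pld_floor: int = 5
    length_intercept: float = 15.0
    length_slope: float = 0.45
    length_sd: float = 4.5
    post_settlement_max_days: int = 80

    year: int = 2010
    spawn_start: tuple[int, int] = (4, 1)   # spawning season opens in April
    spawn_end: tuple[int, int] = (7, 31)    # and closes at the end of July
    n_otolith: int = 200

    def __post_init__(self) -> None:
        if len(self.short_proportions) != self.n_clusters:
            raise ValueError("short_proportions must have one entry per cluster")
        for c, s in enumerate(self.short_proportions):
            rest = s + self.mixed_proportion + self.long_proportion
            if not 0.0 <= rest <= 1.0:
                raise ValueError(f"class proportions for cluster {c} exceed 1")
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        if not 0.0 < self.fst_immigrants < 1.0:
            raise ValueError("fst_immigrants must be in (0, 1)")


@dataclass
class SyntheticDataset:
    """Generated genotypes, metadata, otolith records and planted truth."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    otoliths: pd.DataFrame
    truth: pd.DataFrame
    parents: dict[int, np.ndarray]  # family -> (2, L) parental dosages
    config: SimulationConfig

    def planted_proportions(self) -> pd.DataFrame:
        """Realized per-cluster class proportions of the planted truth."""
        rows = []
        for cluster, grp in self.truth.groupby("planted_cluster", sort=True):
            row = {"cluster": cluster, "N": len(grp)}
            for cat in ("MIXED", "SHORT", "MEDIUM", "LONG"):
                row[cat] = float((grp["planted_class"] == cat).mean())
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, out / "genotypes.csv", format="slash-call")
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.otoliths.to_csv(out / "otoliths.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def simulate_allele_frequencies(n_loci: int, seed: int) -> np.ndarray:
    """Base (local-population) allele-1 frequencies, i.i.d. Uniform(0.1, 0.9)
    so all loci are comfortably polymorphic."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 0.9, size=n_loci)


def simulate_immigrant_frequencies(p_base, fst: float, seed: int) -> np.ndarray:
    """Allele frequencies of a diverged source population under the
    Balding-Nichols model: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F) per locus,
    so E[p'] = p and divergence is controlled by the single FST parameter."""
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    p = np.asarray(p_base, dtype=float)
    rng = np.random.default_rng(seed)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _hw_dosage(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """n Hardy-Weinberg genotypes (allele-1 dosage) at frequencies p."""
    return rng.binomial(2, p[None, :], size=(n, p.size)).astype(np.int8)


def _mendelian_offspring(rng, mother: np.ndarray, father: np.ndarray, n: int) -> np.ndarray:
    """n full-sib offspring dosages by Mendelian transmission: each parent
    passes its first allele with probability dosage/2 per locus."""
    pm = mother / 2.0
    pf = father / 2.0
    tm = rng.random((n, mother.size)) < pm[None, :]
    tf = rng.random((n, father.size)) < pf[None, :]
    return (tm.astype(np.int8) + tf.astype(np.int8))


def simulate_families(p, n_families: int, family_size: int, seed: int,
                      n_unrelated: int = 0):
    """Full-sib families by Mendelian drop plus optional unrelated singles.

    Two Hardy-Weinberg parents are drawn per family (parents are not part
    of the returned cohort); ``family_size`` offspring inherit one allele
    from each. Returns ``(dosage, family_ids, parents)`` where unrelated
    singles carry family id -1 and ``parents[f]`` is the (2, L) parental
    dosage pair of family ``f`` for Mendelian audits.
    """
    if family_size < 2:
        raise ValueError("family_size must be >= 2")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    blocks, fams = [], []
    parents: dict[int, np.ndarray] = {}
    for f in range(n_families):
        mother = _hw_dosage(rng, p, 1)[0]
        father = _hw_dosage(rng, p, 1)[0]
        parents[f] = np.stack([mother, father])
        blocks.append(_mendelian_offspring(rng, mother, father, family_size))
        fams.extend([f] * family_size)
    if n_unrelated:
        blocks.append(_hw_dosage(rng, p, n_unrelated))
        fams.extend([-1] * n_unrelated)
    dosage = np.vstack(blocks)
    return dosage, np.asarray(fams), parents


def _biased_frequencies(p: np.ndarray, bias: float, toward: str = "major") -> np.ndarray:
    """Shift frequencies toward each locus' major (or minor) allele of the
    local population by ``bias``.

    Major-shifted genotypes look 'common' and show mildly elevated
    relatedness to every cohort member. Minor-shifted frequencies model
    local ascertainment of the SNP panel: alleles common here are rarer in
    a distant source population, which is what makes immigrants stand out
    as low-relatedness individuals on a locally developed marker set.
    """
    major = np.where(p >= 0.5, 1.0, 0.0)
    target = major if toward == "major" else 1.0 - major
    return p + bias * (target - p)


def _balanced_split(total: int, k: int) -> np.ndarray:
    base = total // k
    sizes = np.full(k, base, dtype=int)
    sizes[: total - base * k] += 1
    return sizes


def _plan_composition(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plan per-individual planted class, cluster and family.

    SHORT demand per cluster is served by families whose stayers share the
    natal cluster; each family's remaining members are moved to other
    clusters with MEDIUM demand. Leftover MEDIUM demand is served by
    all-mover families whose sibs are scattered over distinct clusters.
    """
    K = config.n_clusters
    sizes = _balanced_split(config.n_individuals, K)
    n_long = np.round(config.long_proportion * sizes).astype(int)
    n_mixed = np.round(config.mixed_proportion * sizes).astype(int)
    n_short = np.round(np.asarray(config.short_proportions) * sizes).astype(int)
    n_medium = sizes - n_long - n_mixed - n_short
    if np.any(n_medium < 0):
        raise ValueError("class proportions inconsistent with cluster sizes")

    short_demand = n_short.copy()
    medium_demand = n_medium.copy()
    rows: list[dict] = []
    fam = 0

    def _move_targets(natal: int, m: int) -> list[int]:
        """Distinct non-natal clusters by remaining MEDIUM demand, so a
        moved sib never shares a cluster with another member of its family
        (keeps the MEDIUM rIN signature clean)."""
        order = np.argsort(-medium_demand, kind="stable")
        targets = [int(c) for c in order if c != natal][:m]
        for t in targets:
            medium_demand[t] -= 1
        return targets

    # families anchored by stayers; stayer counts are balanced across a
    # cluster's families (equal-strength rIN signatures) and each family
    # exports at most K-1 movers, one per distinct non-natal cluster
    for natal in range(K):
        demand = int(short_demand[natal])
        if demand == 0:
            continue
        n_fam = int(np.ceil(demand / (config.family_size - 1)))
        for s in _balanced_split(demand, n_fam):
            m = min(config.family_size - int(s), K - 1)
            if medium_demand.sum() <= 0:
                m = 0
            for _ in range(int(s)):
                rows.append({"planted_class": "SHORT", "planted_cluster": natal, "family": fam})
            for tgt in _move_targets(natal, m):
                rows.append({"planted_class": "MEDIUM", "planted_cluster": tgt, "family": fam})
            fam += 1
        short_demand[natal] = 0
    # all-mover families (scattered over distinct clusters) for leftover demand
    while medium_demand.sum() > 0:
        natal = int(np.argmin(medium_demand))
        m = int(min(K - 1, medium_demand.sum()))
        for tgt in _move_targets(natal, m):
            rows.append({"planted_class": "MEDIUM", "planted_cluster": tgt, "family": fam})
        fam += 1
    for c in range(K):
        for _ in range(int(n_mixed[c])):
            rows.append({"planted_class": "MIXED", "planted_cluster": c, "family": -1})
        for _ in range(int(n_long[c])):
            rows.append({"planted_class": "LONG", "planted_cluster": c, "family": -1})
    plan = pd.DataFrame(rows)
    plan["source"] = np.where(plan["planted_class"] == "LONG", "immigrant", "local")
    # shuffle row order so ids carry no information
    perm = rng.permutation(len(plan))
    plan = plan.iloc[perm].reset_index(drop=True)
    plan.insert(0, "id", [f"ind{i:04d}" for i in range(len(plan))])
    return plan


def place_individuals(plan: pd.DataFrame, config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Draw coordinates for each planned individual from its planted
    cluster's Gaussian and convert the local meter frame to lon/lat."""
    rng = np.random.default_rng(seed)
    theta = np.radians(config.coast_bearing_deg)
    axis = np.array([np.cos(theta), np.sin(theta)])
    centers = np.arange(config.n_clusters)[:, None] * config.cluster_spacing_m * axis[None, :]
    cl = plan["planted_cluster"].to_numpy()
    xy = centers[cl] + rng.normal(0.0, config.cluster_sd_m, size=(len(plan), 2))
    R = 6_371_000.0
    lon = config.origin_lon + np.degrees(xy[:, 0] / (R * np.cos(np.radians(config.origin_lat))))
    lat = config.origin_lat + np.degrees(xy[:, 1] / R)
    out = plan.copy()
    out["x_m"], out["y_m"] = xy[:, 0], xy[:, 1]
    out["lon"], out["lat"] = lon, lat
    return out


def simulate_traits(n: int, config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Hatch days uniform over the spawning season; PLD declines linearly
    with hatch day (floored); age adds a uniform post-settlement tenure;
    length grows linearly with age. Collection date = hatch + age."""
    rng = np.random.default_rng(seed)
    d0 = date(config.year, *config.spawn_start).timetuple().tm_yday
    d1 = date(config.year, *config.spawn_end).timetuple().tm_yday
    if d1 <= d0:
        raise ValueError("invalid spawning window")
    hatch_day = rng.integers(d0, d1 + 1, size=n)
    pld = config.pld_intercept + config.pld_slope * hatch_day + rng.normal(0, config.pld_sd, n)
    pld = np.maximum(np.rint(pld).astype(int), config.pld_floor)
    post = rng.integers(0, config.post_settlement_max_days + 1, size=n)
    age = pld + post
    length = config.length_intercept + config.length_slope * age + rng.normal(0, config.length_sd, n)
    length = np.maximum(length, 8.0)
    base = date(config.year, 1, 1)
    hatch_date = [base + timedelta(days=int(d) - 1) for d in hatch_day]
    coll_date = [h + timedelta(days=int(a)) for h, a in zip(hatch_date, age)]
    return pd.DataFrame(
        {
            "hatch_day": hatch_day,
            "hatch_date": pd.to_datetime(hatch_date),
            "pld_days": pld,
            "age_days": age,
            "length_mm": np.round(length, 1),
            "collection_date": pd.to_datetime(coll_date),
        }
    )


def generate(config: SimulationConfig, outdir=None) -> SyntheticDataset:
    """Generate a full synthetic dataset (deterministic given config.seed);
    optionally write the four CSV tables to ``outdir``."""
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_imm, s_plan, s_geno, s_place, s_trait, s_miss, s_oto = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(8)
    )
    p = simulate_allele_frequencies(config.n_loci, s_freq)
    p_imm = _biased_frequencies(
        simulate_immigrant_frequencies(p, config.fst_immigrants, s_imm),
        config.immigrant_rarity_bias,
        toward="minor",
    )
    q_common = _biased_frequencies(p, config.common_genotype_bias)

    plan = _plan_composition(config, np.random.default_rng(s_plan))
    n = len(plan)
    rng_g = np.random.default_rng(s_geno)
    dosage = np.empty((n, config.n_loci), dtype=np.int8)
    parents: dict[int, np.ndarray] = {}
    for f in sorted(set(plan["family"]) - {-1}):
        idx = np.flatnonzero(plan["family"].to_numpy() == f)
        mother = _hw_dosage(rng_g, p, 1)[0]
        father = _hw_dosage(rng_g, p, 1)[0]
        parents[int(f)] = np.stack([mother, father])
        dosage[idx] = _mendelian_offspring(rng_g, mother, father, idx.size)
    mixed_idx = np.flatnonzero((plan["planted_class"] == "MIXED").to_numpy())
    dosage[mixed_idx] = _hw_dosage(rng_g, q_common, mixed_idx.size)
    long_idx = np.flatnonzero((plan["planted_class"] == "LONG").to_numpy())
    dosage[long_idx] = _hw_dosage(rng_g, p_imm, long_idx.size)

    # missing calls, keeping every locus typed in at least 2 individuals
    rng_m = np.random.default_rng(s_miss)
    miss = rng_m.random(dosage.shape) < config.missing_rate
    for l in range(config.n_loci):
        if (~miss[:, l]).sum() < 2:
            miss[:, l] = False
    dosage[miss] = -1

    # allele letters per locus, first allele lexicographically smaller
    rng_a = np.random.default_rng(s_freq + 1)
    letters = np.array(list("ACGT"))
    alleles = np.empty((config.n_loci, 2), dtype=object)
    for l in range(config.n_loci):
        pair = sorted(rng_a.choice(4, size=2, replace=False))
        alleles[l] = letters[pair]
    gm = GenotypeMatrix(
        individual_ids=plan["id"].tolist(),
        locus_ids=[f"snp{l:03d}" for l in range(config.n_loci)],
        alleles=alleles,
        dosage=dosage,
        stage=np.full(n, config.stage, dtype=object),
    )

    placed = place_individuals(plan, config, s_place)
    traits = simulate_traits(n, config, s_trait)
    metadata = pd.DataFrame(
        {
            "id": plan["id"],
            "stage": config.stage,
            "lon": placed["lon"],
            "lat": placed["lat"],
            "collection_date": traits["collection_date"].dt.date,
            "length_mm": traits["length_mm"],
        }
    )
    rng_o = np.random.default_rng(s_oto)
    oto_idx = np.sort(rng_o.choice(n, size=min(config.n_otolith, n), replace=False))
    otoliths = pd.DataFrame(
        {
            "id": plan["id"].iloc[oto_idx].to_numpy(),
            "pld_days": traits["pld_days"].iloc[oto_idx].to_numpy(),
            "size_at_hatching_um": np.round(rng_o.normal(12.0, 1.5, oto_idx.size), 2),
            "size_at_settlement_um": np.round(rng_o.normal(120.0, 15.0, oto_idx.size), 1),
            "total_age_days": traits["age_days"].iloc[oto_idx].to_numpy(),
        }
    )
    truth = plan[["id", "family", "source", "planted_class", "planted_cluster"]].copy()
    truth["hatch_day"] = traits["hatch_day"]
    truth["pld_days"] = traits["pld_days"]
    truth["age_days"] = traits["age_days"]
    ds = SyntheticDataset(gm, metadata, otoliths, truth, parents, config)
    if outdir is not None:
        ds.write(outdir)
    return ds
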