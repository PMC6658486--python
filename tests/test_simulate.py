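import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_genotypes

import patchkin as pk
from patchkin.simulate import SimulationConfig, _plan_composition


class TestAlleleFrequencies:
    def test_support(self):
        p = pk.simulate_allele_frequencies(500, seed=0)
        assert np.all((p >= 0.1) & (p <= 0.9))

    def test_seeded_reproducibility(self):
        a = pk.simulate_allele_frequencies(100, seed=3)
        b = pk.simulate_allele_frequencies(100, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_mean_law_of_large_numbers(self):
        p = pk.simulate_allele_frequencies(10_000, seed=1)
        assert p.mean() == pytest.approx(0.5, abs=0.01)


class TestImmigrantFrequencies:
    def test_balding_nichols_mean(self):
        p = np.full(10_000, 0.5)
        q = pk.simulate_immigrant_frequencies(p, fst=0.1, seed=2)
        assert q.mean() == pytest.approx(0.5, abs=0.01)

    def test_realized_divergence_matches_fst(self):
        """E[(p'-p)^2] = F p(1-p) under the model; the moment estimator of
        F over many loci recovers the planted value."""
        p = pk.simulate_allele_frequencies(10_000, seed=4)
        for f in (0.05, 0.2):
            q = pk.simulate_immigrant_frequencies(p, fst=f, seed=5)
            fhat = np.mean((q - p) ** 2 / (p * (1 - p)))
            assert fhat == pytest.approx(f, abs=0.02)

    def test_vanishing_fst_limit(self):
        p = np.full(2_000, 0.5)
        q = pk.simulate_immigrant_frequencies(p, fst=1e-4, seed=6)
        assert np.var(q - p) < 1e-3

    def test_invalid_fst(self):
        with pytest.raises(ValueError):
            pk.simulate_immigrant_frequencies(np.array([0.5]), fst=0.0, seed=0)

    def test_immigrant_relatedness_decreases_with_fst(self):
        """With a half-immigrant cohort, mean between-group relatedness
        (cohort-referenced) falls as the planted divergence grows."""
        p = pk.simulate_allele_frequencies(178, seed=7)
        rng = np.random.default_rng(8)
        means = []
        for f in (0.05, 0.15, 0.30):
            q = pk.simulate_immigrant_frequencies(p, fst=f, seed=9)
            locals_ = rng.binomial(2, p[None, :], (100, 178))
            imms = rng.binomial(2, q[None, :], (100, 178))
            g = make_genotypes(np.vstack([locals_, imms]).astype(np.int8))
            rm = pk.qg_matrix(g)
            means.append(np.nanmean(rm.r[:100, 100:]))
        assert means[0] > means[1] > means[2]


class TestFamilies:
    def test_mendelian_consistency_audited(self):
        """Every offspring dosage is attainable from its parents: a parent
        homozygous for one allele always transmits it."""
        p = pk.simulate_allele_frequencies(60, seed=10)
        dosage, fam, parents = pk.simulate_families(p, 12, 5, seed=11)
        for f, (mother, father) in parents.items():
            kids = dosage[fam == f]
            lo = (mother == 2).astype(int) + (father == 2).astype(int)
            hi = 2 - (mother == 0).astype(int) - (father == 0).astype(int)
            assert np.all(kids >= lo[None, :])
            assert np.all(kids <= hi[None, :])

    def test_sib_and_unrelated_means(self):
        p = pk.simulate_allele_frequencies(178, seed=12)
        dosage, fam, _ = pk.simulate_families(p, 20, 4, seed=13, n_unrelated=60)
        rm = pk.qg_matrix(make_genotypes(dosage))
        same = (fam[:, None] == fam[None, :]) & (fam[:, None] >= 0)
        iu = np.triu_indices(len(fam), 1)
        assert np.nanmean(rm.r[iu][same[iu]]) == pytest.approx(0.5, abs=0.05)
        assert np.nanmean(rm.r[iu][~same[iu]]) == pytest.approx(0.0, abs=0.02)

    def test_family_size_validation(self):
        with pytest.raises(ValueError):
            pk.simulate_families(np.array([0.5]), 2, 1, seed=0)


class TestPlacement:
    def test_all_short_families_monophyletic(self):
        cfg = SimulationConfig(seed=0, n_individuals=120, n_loci=10,
                               short_proportions=(1.0,) * 6,
                               mixed_proportion=0.0, long_proportion=0.0)
        plan = _plan_composition(cfg, np.random.default_rng(0))
        assert (plan["planted_class"] == "SHORT").all()
        spread = plan.groupby("family")["planted_cluster"].nunique()
        assert (spread == 1).all()

    def test_gradient_monotone_in_truth(self, default_dataset):
        pl = default_dataset.planted_proportions()
        assert np.all(np.diff(pl["SHORT"].to_numpy()) > 0)

    def test_medium_movers_never_share_cluster_with_sibs(self, default_dataset):
        truth = default_dataset.truth
        med = truth[truth["planted_class"] == "MEDIUM"]
        for _, row in med.iterrows():
            fam_rows = truth[(truth["family"] == row["family"])
                             & (truth["id"] != row["id"])]
            assert row["planted_cluster"] not in set(fam_rows["planted_cluster"])

    def test_immigrants_carry_source_frequencies(self):
        """LONG individuals' genotype frequencies track the diverged,
        ascertainment-biased source frequencies more closely than the local
        ones."""
        from patchkin.simulate import _biased_frequencies

        cfg = SimulationConfig(seed=30, fst_immigrants=0.3, long_proportion=0.15)
        ds = pk.generate(cfg)
        ss = np.random.SeedSequence(cfg.seed)
        s_freq, s_imm = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(8)[:2])
        p = pk.simulate_allele_frequencies(cfg.n_loci, s_freq)
        p_src = _biased_frequencies(
            pk.simulate_immigrant_frequencies(p, cfg.fst_immigrants, s_imm),
            cfg.immigrant_rarity_bias, toward="minor",
        )
        imm_ids = ds.truth.loc[ds.truth["source"] == "immigrant", "id"]
        mask = np.isin(ds.genotypes.individual_ids, imm_ids)
        sub = ds.genotypes.subset(individuals=mask)
        freq = pk.allele_frequencies(sub)
        err_imm = np.nanmean((freq - p_src) ** 2)
        err_loc = np.nanmean((freq - p) ** 2)
        assert err_imm < err_loc

    def test_coordinates_cluster_around_planted_centers(self, default_dataset):
        ds = default_dataset
        meta = ds.metadata
        pts = pk.project_coordinates(meta["id"].tolist(), meta["lon"].to_numpy(),
                                     meta["lat"].to_numpy())
        df = pd.DataFrame({"cluster": ds.truth["planted_cluster"], "x": pts.x, "y": pts.y})
        centers = df.groupby("cluster")[["x", "y"]].mean().to_numpy()
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        assert np.allclose(gaps, ds.config.cluster_spacing_m, atol=15.0)
        within = df.groupby("cluster")[["x", "y"]].std().to_numpy()
        assert np.all(np.abs(within - ds.config.cluster_sd_m) < 8.0)


class TestTraits:
    def test_slope_recovered(self):
        cfg = SimulationConfig(seed=0)
        traits = pk.simulate_traits(500, cfg, seed=41)
        slope = stats.linregress(traits["hatch_day"], traits["pld_days"]).slope
        assert slope == pytest.approx(cfg.pld_slope, rel=0.2)

    def test_early_late_gap_matches_planted(self):
        cfg = SimulationConfig(seed=0)
        traits = pk.simulate_traits(2_000, cfg, seed=42)
        season = pk.SeasonConfig(year=cfg.year)
        labels = pk.assign_season_cohort(traits["hatch_date"], season)
        early = traits.loc[labels == "early"]
        late = traits.loc[labels == "late"]
        observed = early["pld_days"].mean() - late["pld_days"].mean()
        planted = cfg.pld_slope * (early["hatch_day"].mean() - late["hatch_day"].mean())
        assert observed == pytest.approx(planted, abs=0.5)
        assert observed == pytest.approx(3.8, abs=1.0)

    def test_pld_floor(self):
        cfg = SimulationConfig(seed=0, pld_intercept=6.0)
        traits = pk.simulate_traits(500, cfg, seed=43)
        assert traits["pld_days"].min() >= cfg.pld_floor

    def test_collection_date_consistency(self):
        traits = pk.simulate_traits(50, SimulationConfig(seed=0), seed=44)
        delta = (traits["collection_date"] - traits["hatch_date"]).dt.days
        np.testing.assert_array_equal(delta.to_numpy(), traits["age_days"].to_numpy())


class TestGenerate:
    def test_sizes_and_truth_coverage(self, default_dataset):
        ds = default_dataset
        assert ds.genotypes.n_individuals == ds.config.n_individuals
        assert ds.genotypes.n_loci == ds.config.n_loci
        assert len(ds.truth) == ds.config.n_individuals
        assert set(ds.truth["id"]) == set(ds.genotypes.individual_ids)
        assert len(ds.otoliths) == ds.config.n_otolith

    def test_byte_identical_outputs_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=99, n_individuals=120, n_loci=30, n_otolith=40)
        pk.generate(cfg, outdir=tmp_path / "a")
        pk.generate(cfg, outdir=tmp_path / "b")
        for name in ("genotypes.csv", "metadata.csv", "otoliths.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_different_data(self):
        a = pk.generate(SimulationConfig(seed=1, n_individuals=60, n_loci=20, n_otolith=10))
        b = pk.generate(SimulationConfig(seed=2, n_individuals=60, n_loci=20, n_otolith=10))
        assert not np.array_equal(a.genotypes.dosage, b.genotypes.dosage)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(short_proportions=(0.9,) * 6, mixed_proportion=0.2,
                             long_proportion=0.2)
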