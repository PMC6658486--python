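import numpy as np
import pandas as pd
import pytest

import patchkin as pk
from patchkin.dispersal import CATEGORIES, CODE_TO_CATEGORY, InOutProfile
from patchkin.relatedness import RelatednessMatrix


def _rm(values):
    r = np.asarray(values, dtype=float)
    np.fill_diagonal(r, np.nan)
    return RelatednessMatrix([f"i{k}" for k in range(len(r))], r,
                             np.ones_like(r, dtype=int))


class TestNormalize:
    def _simple(self):
        # off-diagonal values: 0.0 (min), 0.5 (mid), 1.0 (max)
        r = np.array([[0, 0.0, 0.5], [0.0, 0, 1.0], [0.5, 1.0, 0]], float)
        return _rm(r)

    def test_order_preserving_endpoints(self):
        d = pk.normalize_relatedness(self._simple(), mode="order_preserving")
        assert d.d[0, 1] == pytest.approx(0.0)   # r = a
        assert d.d[1, 2] == pytest.approx(1.0)   # r = b
        assert d.d[0, 2] == pytest.approx(0.5)   # midpoint

    def test_literal_inverted_endpoints(self):
        d = pk.normalize_relatedness(self._simple(), mode="literal_inverted")
        assert d.d[0, 1] == pytest.approx(1.0)
        assert d.d[1, 2] == pytest.approx(0.0)
        assert d.d[0, 2] == pytest.approx(0.5)   # midpoint is mode-invariant

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pk.normalize_relatedness(_rm(np.full((3, 3), 0.2)))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pk.normalize_relatedness(self._simple(), mode="upside_down")

    def test_masked_pairs_stay_masked(self):
        r = np.array([[0, np.nan, 0.5], [np.nan, 0, 1.0], [0.5, 1.0, 0]], float)
        d = pk.normalize_relatedness(_rm(r))
        assert np.isnan(d.d[0, 1])


class TestInOut:
    def test_hand_example(self):
        # clusters {i,j} and {k,l}; d(i,j)=0.8, d(i,k)=0.2, d(i,l)=0.4
        d = np.array(
            [
                [np.nan, 0.8, 0.2, 0.4],
                [0.8, np.nan, 0.1, 0.3],
                [0.2, 0.1, np.nan, 0.6],
                [0.4, 0.3, 0.6, np.nan],
            ]
        )
        norm = pk.NormalizedRelatedness(list("ijkl"), d, 0.0, 1.0, "order_preserving")
        prof = pk.compute_rin_rout(norm, np.array([1, 1, 2, 2]))
        row = prof.table.set_index("id").loc["i"]
        assert row["r_in"] == pytest.approx(0.8)
        assert row["r_out"] == pytest.approx(0.3)

    def test_constant_matrix(self):
        d = np.full((6, 6), 0.4)
        np.fill_diagonal(d, np.nan)
        norm = pk.NormalizedRelatedness([f"i{k}" for k in range(6)], d, 0, 1, "order_preserving")
        prof = pk.compute_rin_rout(norm, np.array([1, 1, 1, 2, 2, 2]))
        assert np.allclose(prof.table["r_in"], 0.4)
        assert np.allclose(prof.table["r_out"], 0.4)

    def test_singleton_cluster_invalid(self):
        d = np.full((4, 4), 0.4)
        np.fill_diagonal(d, np.nan)
        norm = pk.NormalizedRelatedness(list("abcd"), d, 0, 1, "order_preserving")
        prof = pk.compute_rin_rout(norm, np.array([1, 2, 2, 2]))
        assert not prof.table.set_index("id").loc["a", "valid"]
        assert prof.table.set_index("id").loc["b", "valid"]

    def test_whole_cohort_cluster_invalid(self):
        d = np.full((4, 4), 0.4)
        np.fill_diagonal(d, np.nan)
        norm = pk.NormalizedRelatedness(list("abcd"), d, 0, 1, "order_preserving")
        prof = pk.compute_rin_rout(norm, np.array([1, 1, 1, 1]))
        assert not prof.table["valid"].any()


def corner_clouds(seed=5, n=50, sd=0.02):
    rng = np.random.default_rng(seed)
    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
    X = np.vstack([c + rng.normal(0, sd, size=(n, 2)) for c in corners])
    codes = ["LL"] * n + ["LH"] * n + ["HL"] * n + ["HH"] * n
    return X, np.array(codes)


class TestEmbc:
    def test_corner_cloud_codes_and_delimiters(self):
        X, truth = corner_clouds()
        m = pk.embc_fit(X, seed=1)
        prof = InOutProfile(
            table=pd.DataFrame(
                {"id": range(len(X)), "cluster": 0,
                 "r_in": X[:, 0], "r_out": X[:, 1], "valid": True}
            )
        )
        asg = pk.assign_categories(m, prof)
        expected = pd.Series(truth).map(CODE_TO_CATEGORY)
        accuracy = (asg.table["category"].to_numpy() == expected.to_numpy()).mean()
        assert accuracy >= 0.95
        assert 0.25 < m.delimiters[0] < 0.75
        assert 0.25 < m.delimiters[1] < 0.75

    def test_loglik_nondecreasing(self):
        X, _ = corner_clouds(seed=2)
        m = pk.embc_fit(X, seed=0)
        trace = m.loglik_trace
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_axis_swap_symmetry(self):
        X, _ = corner_clouds(seed=3)
        Xs = np.vstack([X, X[:, ::-1]])  # exactly symmetric under axis swap
        m = pk.embc_fit(Xs, seed=0)
        assert m.delimiters[0] == pytest.approx(m.delimiters[1], abs=1e-6)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            pk.embc_fit(np.random.default_rng(0).random((5, 2)), seed=0)

    def test_zero_variance_axis(self):
        X = np.column_stack([np.zeros(20), np.linspace(0, 1, 20)])
        with pytest.raises(ValueError):
            pk.embc_fit(X, seed=0)

    def test_code_bijection(self):
        X, _ = corner_clouds(seed=7)
        m = pk.embc_fit(X, seed=0)
        assert sorted(m.codes) == ["HH", "HL", "LH", "LL"]


class TestAssignCategories:
    def test_invalid_profile_unassigned(self):
        X, _ = corner_clouds()
        m = pk.embc_fit(X, seed=0)
        prof = InOutProfile(
            table=pd.DataFrame(
                {"id": ["a", "b"], "cluster": [1, 1],
                 "r_in": [0.9, np.nan], "r_out": [0.1, np.nan],
                 "valid": [True, False]}
            )
        )
        asg = pk.assign_categories(m, prof)
        tbl = asg.table.set_index("id")
        assert tbl.loc["a", "category"] == "SHORT"  # high rIN, low rOUT
        assert tbl.loc["b", "category"] == "UNASSIGNED"

    def test_deep_quadrant_profiles(self):
        X, _ = corner_clouds()
        m = pk.embc_fit(X, seed=0)
        prof = InOutProfile(
            table=pd.DataFrame(
                {"id": ["ll", "lh", "hl", "hh"], "cluster": 1,
                 "r_in": [0.0, 0.0, 1.0, 1.0], "r_out": [0.0, 1.0, 0.0, 1.0],
                 "valid": True}
            )
        )
        cats = pk.assign_categories(m, prof).table.set_index("id")["category"]
        assert cats["ll"] == "LONG" and cats["lh"] == "MEDIUM"
        assert cats["hl"] == "SHORT" and cats["hh"] == "MIXED"


@pytest.fixture(scope="module")
def small_cohort():
    ds = pk.generate(pk.SimulationConfig(seed=21, n_individuals=240, n_loci=120,
                                         n_otolith=60))
    g, _ = pk.filter_loci(ds.genotypes)
    rm = pk.qg_matrix(g)
    return ds, rm


class TestModeAndScaleInvariance:
    def _categories(self, rm, labels, mode):
        norm = pk.normalize_relatedness(rm, mode=mode)
        prof = pk.compute_rin_rout(norm, labels)
        m = pk.embc_fit(prof.valid_xy(), seed=4)
        return pk.assign_categories(m, prof).table["category"].to_numpy()

    def test_mode_swap_exchanges_categories(self, small_cohort):
        """Inverting the normalization flips H and L on both axes, so the
        diagonal categories swap: MIXED<->LONG and SHORT<->MEDIUM."""
        ds, rm = small_cohort
        labels = ds.truth["planted_cluster"].to_numpy()
        a = self._categories(rm, labels, "order_preserving")
        b = self._categories(rm, labels, "literal_inverted")
        swap = {"MIXED": "LONG", "LONG": "MIXED", "SHORT": "MEDIUM",
                "MEDIUM": "SHORT", "UNASSIGNED": "UNASSIGNED"}
        assert (np.vectorize(swap.get)(a) == b).all()

    def test_affine_rescaling_invariance(self, small_cohort):
        """Categories depend on r only through the min-max normalization,
        so any increasing affine map of r leaves them unchanged."""
        ds, rm = small_cohort
        labels = ds.truth["planted_cluster"].to_numpy()
        scaled = RelatednessMatrix(rm.individual_ids, 2.0 * rm.r + 3.0, rm.n_loci)
        a = self._categories(rm, labels, "order_preserving")
        b = self._categories(scaled, labels, "order_preserving")
        assert (a == b).all()


class TestProportions:
    def _assignment(self, clusters, cats):
        return pk.DisperserAssignment(
            table=pd.DataFrame(
                {"id": range(len(cats)), "cluster": clusters,
                 "r_in": 0.5, "r_out": 0.5, "code": "",
                 "category": cats}
            )
        )

    def test_hand_counts(self):
        asg = self._assignment([1] * 4, ["SHORT", "SHORT", "LONG", "MEDIUM"])
        tab = pk.category_proportions(asg)
        row = tab.set_index("cluster").loc[1]
        assert row["SHORT"] == pytest.approx(0.5)
        assert row["MEDIUM"] == pytest.approx(0.25)
        assert row["LONG"] == pytest.approx(0.25)
        assert row["MIXED"] == 0.0

    def test_schema_and_row_sums(self):
        asg = self._assignment([1, 1, 2, 2, 2], ["SHORT", "MIXED", "LONG", "LONG", "MEDIUM"])
        tab = pk.category_proportions(asg)
        assert list(tab.columns) == ["cluster", "N", "MIXED", "SHORT", "MEDIUM", "LONG"]
        np.testing.assert_allclose(tab[list(CATEGORIES)].sum(axis=1), 1.0, atol=1e-9)

    def test_unassigned_only_cluster_omitted_with_warning(self):
        asg = self._assignment([1, 1, 2], ["SHORT", "SHORT", "UNASSIGNED"])
        with pytest.warns(UserWarning, match="omitted"):
            tab = pk.category_proportions(asg)
        assert list(tab["cluster"]) == [1]
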