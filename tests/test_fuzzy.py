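"""Fuzzy agreement: t-norms, level distributions, reductions and identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzykappa import (
    CategorySet,
    CodingError,
    CrispSheet,
    DimensionScheme,
    MembershipTable,
    MembershipWarning,
    cohen_kappa,
    default_categories,
    equal_split,
    expand_two_tier,
    expected_agreement_crisp,
    fuzzy_expected,
    fuzzy_kappa,
    fuzzy_observed,
    fuzzy_pi,
    level_distribution,
    observed_agreement_crisp,
    one_hot,
    scott_pi,
    t_norm,
    two_tier_integrated,
)
from fuzzykappa.coding import RankedSheet

from conftest import (
    LEVEL_COUNTS,
    brute_fuzzy_expected,
    brute_fuzzy_observed,
    random_membership_pair,
    random_one_hot_pair,
)

GRID = np.linspace(0.0, 1.0, 11)


class TestTNorms:
    def test_known_values(self):
        assert t_norm(0.3, 0.7, "min") == 0.3
        assert t_norm(0.7, 0.6, "luka") == pytest.approx(0.3)
        assert t_norm(0.5, 0.4, "product") == pytest.approx(0.2)

    @pytest.mark.parametrize("name", ["min", "product", "luka"])
    def test_axioms_on_grid(self, name):
        """Commutativity, monotonicity, identity 1, annihilator 0."""
        for a in GRID:
            assert t_norm(a, 1.0, name) == pytest.approx(a)
            assert t_norm(a, 0.0, name) == 0.0
            for b in GRID:
                assert t_norm(a, b, name) == pytest.approx(t_norm(b, a, name))
                for b2 in GRID[GRID >= b]:
                    assert t_norm(a, b2, name) >= t_norm(a, b, name) - 1e-15

    def test_pointwise_ordering_luka_product_min(self):
        for a in GRID:
            for b in GRID:
                luka = t_norm(a, b, "luka")
                prod = t_norm(a, b, "product")
                mn = t_norm(a, b, "min")
                assert luka <= prod + 1e-15 <= mn + 2e-15

    def test_out_of_range_rejected(self):
        with pytest.raises(CodingError):
            t_norm(1.2, 0.5)
        with pytest.raises(CodingError):
            t_norm(0.5, -0.1, "luka")


class TestLevelDistribution:
    def test_one_hot_column_tallies_marginal(self):
        cats = default_categories(2)
        m = one_hot(["c1"] * 3 + ["c2"] * 7, cats)
        levels, probs = level_distribution(m).for_category("c1")
        assert levels.tolist() == [0.0, 1.0]
        assert probs.tolist() == [0.7, 0.3]

    def test_fractional_level_column(self):
        cats = default_categories(2)
        values = np.zeros((100, 2))
        values[:40, 0] = 1 / 9
        values[:, 1] = 1.0 - values[:, 0]
        m = MembershipTable([str(i) for i in range(100)], cats, values)
        levels, probs = level_distribution(m).for_category("c1")
        assert levels.tolist() == [0.0, 1 / 9]
        assert probs.tolist() == [0.6, 0.4]

    def test_mixed_levels_match_brute_tally(self):
        rng = np.random.default_rng(21)
        m, _ = random_membership_pair(rng, 40, 5)
        dist = level_distribution(m)
        for j, lab in enumerate(m.categories):
            levels, probs = dist.for_category(lab)
            col = list(m.values[:, j])
            for v, p in zip(levels, probs):
                assert col.count(v) / 40 == pytest.approx(p, abs=1e-15)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestFuzzyObserved:
    def test_half_overlap_single_unit(self):
        cats = default_categories(3)
        m1 = MembershipTable(["u"], cats, [[0.5, 0.5, 0.0]])
        m2 = MembershipTable(["u"], cats, [[0.5, 0.0, 0.5]])
        assert fuzzy_observed(m1, m2, "min") == pytest.approx(0.5)

    def test_equals_crisp_observed_on_one_hot(self):
        rng = np.random.default_rng(2)
        m1, m2 = random_one_hot_pair(rng, 60, 5)
        for name in ("min", "product", "luka"):
            assert fuzzy_observed(m1, m2, name) == pytest.approx(
                observed_agreement_crisp(m1, m2), abs=1e-14)

    def test_two_tier_eight_of_nine_dimensions(self):
        """Raters agreeing on exactly 8 of 9 dimensions per unit score 8/9."""
        scheme = DimensionScheme.from_level_counts(
            [f"D{i}" for i in range(9)], [3] * 9)
        n = 12
        ids = [str(i) for i in range(n)]
        codes1 = np.ones((n, 9), dtype=int)
        codes2 = codes1.copy()
        codes2[:, 0] = 2  # disagree on the first dimension only
        m1 = expand_two_tier(CrispSheet(ids, codes1), scheme)
        m2 = expand_two_tier(CrispSheet(ids, codes2), scheme)
        assert fuzzy_observed(m1, m2, "min") == pytest.approx(8 / 9)
        assert fuzzy_observed(m1, m2, "min") == pytest.approx(
            brute_fuzzy_observed(m1, m2, "min"), abs=1e-14)

    def test_unnormalized_rows_warn_for_product(self):
        cats = default_categories(2)
        m = MembershipTable(["u"], cats, [[0.9, 0.9]])
        with pytest.warns(MembershipWarning, match="may exceed 1"):
            fuzzy_observed(m, m, "product")

    def test_identity_iff_identical_under_min(self):
        rng = np.random.default_rng(13)
        m1, m2 = random_membership_pair(rng, 25, 4)
        assert fuzzy_observed(m1, m1, "min") == pytest.approx(1.0, abs=1e-12)
        if not np.array_equal(m1.values, m2.values):
            assert fuzzy_observed(m1, m2, "min") < 1.0 - 1e-12


class TestFuzzyExpected:
    def test_reduces_to_crisp_chance_on_skewed_binary(self):
        cats = default_categories(2)
        m1 = one_hot(["c1"] + ["c2"] * 9, cats)
        m2 = one_hot(["c2"] * 5 + ["c1"] + ["c2"] * 4, cats)
        assert fuzzy_expected(m1, m2, "min") == pytest.approx(0.82)

    def test_two_tier_identity_mean_of_dimension_chances(self,
                                                         example1_scheme):
        """Under equal-split expansion and min, the fuzzy chance agreement is
        the mean of the per-dimension crisp chance agreements."""
        rng = np.random.default_rng(17)
        n = 50
        codes = [np.column_stack([rng.integers(0, k, n)
                                  for k in LEVEL_COUNTS]) for _ in range(2)]
        ids = [str(i) for i in range(n)]
        sheets = [CrispSheet(ids, c) for c in codes]
        m1, m2 = (expand_two_tier(s, example1_scheme) for s in sheets)
        per_dim = []
        for d, (_, levels) in enumerate(example1_scheme.dimensions):
            cats = CategorySet(levels)
            a = one_hot([levels[c] for c in codes[0][:, d]], cats, ids)
            b = one_hot([levels[c] for c in codes[1][:, d]], cats, ids)
            per_dim.append(expected_agreement_crisp(a, b))
        assert fuzzy_expected(m1, m2, "min") == pytest.approx(
            float(np.mean(per_dim)), abs=1e-12)
        assert fuzzy_expected(m1, m2, "min") == pytest.approx(
            brute_fuzzy_expected(m1, m2, "min"), abs=1e-12)

    def test_matches_triple_loop_oracle_product(self):
        rng = np.random.default_rng(29)
        m1, m2 = random_membership_pair(rng, 30, 5)
        assert fuzzy_expected(m1, m2, "product") == pytest.approx(
            brute_fuzzy_expected(m1, m2, "product"), abs=1e-12)


class TestFuzzyKappaAndPi:
    def test_identical_tables_give_one(self):
        rng = np.random.default_rng(31)
        m, _ = random_membership_pair(rng, 20, 4)
        assert fuzzy_kappa(m, m, "min").kappa == pytest.approx(1.0, abs=1e-9)

    def test_one_hot_reduction_to_cohen_and_scott(self):
        rng = np.random.default_rng(37)
        m1, m2 = random_one_hot_pair(rng, 80, 6)
        for name in ("min", "product", "luka"):
            assert fuzzy_kappa(m1, m2, name).kappa == pytest.approx(
                cohen_kappa(m1, m2).kappa, abs=1e-13)
            assert fuzzy_pi(m1, m2, name).kappa == pytest.approx(
                scott_pi(m1, m2).kappa, abs=1e-13)

    def test_integrated_two_tier_published_components(self):
        """The nine per-dimension agreement pairs of the Russia study
        integrate to the published 0.90 / 0.53 / 0.79."""
        po = [0.95, 0.99, 0.85, 0.73, 0.96, 0.85, 0.96, 0.92, 0.91]
        pe = [0.43, 0.80, 0.39, 0.28, 0.68, 0.50, 0.57, 0.53, 0.60]
        res = two_tier_integrated(po, pe)
        assert res.observed == pytest.approx(0.90, abs=0.01)
        assert res.expected == pytest.approx(0.53, abs=0.01)
        assert res.kappa == pytest.approx(0.79, abs=0.01)

    def test_pi_equals_kappa_for_identical_level_distributions(self):
        cats = default_categories(3)
        ids = ["a", "b", "c", "d"]
        vals = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5],
                         [1.0, 0.0, 0.0], [0.5, 0.0, 0.5]])
        m1 = MembershipTable(ids, cats, vals)
        m2 = MembershipTable(ids, cats, vals[[1, 0, 3, 2]])
        # same multiset of rows per rater -> identical level distributions
        assert fuzzy_pi(m1, m2).expected == pytest.approx(
            fuzzy_kappa(m1, m2).expected, abs=1e-14)

    def test_pi_matches_brute_force_pooled_chance(self):
        rng = np.random.default_rng(41)
        m1, m2 = random_membership_pair(rng, 25, 4)
        n = m1.n_units
        total = 0.0
        for j in range(4):
            tally: dict[float, float] = {}
            for col in (m1.values[:, j], m2.values[:, j]):
                for v in col:
                    tally[v] = tally.get(v, 0.0) + 0.5 / n
            for v1, p1 in tally.items():
                for v2, p2 in tally.items():
                    total += p1 * p2 * min(v1, v2)
        assert fuzzy_pi(m1, m2, "min").expected == pytest.approx(
            total, abs=1e-12)

    def test_tnorm_ordering_transfers_to_observed_agreement(self):
        rng = np.random.default_rng(43)
        m1, m2 = random_membership_pair(rng, 30, 5)
        po = {name: fuzzy_observed(m1, m2, name)
              for name in ("luka", "product", "min")}
        assert po["luka"] <= po["product"] + 1e-14 <= po["min"] + 2e-14

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 30))
    def test_symmetry_and_padding_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = random_membership_pair(rng, int(rng.integers(3, 20)), 4)
        res_ab = fuzzy_kappa(m1, m2, "min")
        res_ba = fuzzy_kappa(m2, m1, "min")
        assert res_ab.observed == pytest.approx(res_ba.observed, abs=1e-14)
        assert res_ab.expected == pytest.approx(res_ba.expected, abs=1e-14)
        padded = CategorySet(list(m1.categories) + ["pad1", "pad2"])
        z = np.zeros((m1.n_units, 2))
        p1 = MembershipTable(m1.unit_ids, padded,
                             np.hstack([m1.values, z]))
        p2 = MembershipTable(m2.unit_ids, padded,
                             np.hstack([m2.values, z]))
        assert fuzzy_kappa(p1, p2, "min").expected == pytest.approx(
            res_ab.expected, abs=1e-12)
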