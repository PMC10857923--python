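"""Rank tests and Bray-Curtis against enumeration and scipy oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import mannwhitneyu, norm

from phenobalance import (
    bray_curtis,
    host_dissimilarity,
    host_dissimilarity_matrix,
    kruskal_wallis,
    mann_whitney,
)
from phenobalance.synthetic import GeneratorConfig, generate_leaves


class TestBrayCurtis:
    def test_identical_vectors_give_zero(self):
        assert bray_curtis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert bray_curtis([1.0, 0.0, 2.0], [0.0, 3.0, 0.0]) == 1.0

    def test_hand_value(self):
        assert math.isclose(bray_curtis([1, 2, 0], [0, 2, 4]), 5 / 9, abs_tol=1e-12)

    def test_all_zero_pair_is_missing(self):
        assert math.isnan(bray_curtis([0.0, 0.0], [0.0, 0.0]))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([1.0, -1.0], [0.0, 1.0])

    @given(
        u=st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=8),
        v=st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_bounded_and_matches_scipy(self, u, v):
        u, v = u[: min(len(u), len(v))], v[: min(len(u), len(v))]
        if sum(u) + sum(v) == 0:
            return
        d = bray_curtis(u, v)
        assert math.isclose(d, bray_curtis(v, u), abs_tol=1e-12)
        assert 0.0 <= d <= 1.0
        assert math.isclose(d, float(scipy_bc(u, v)), abs_tol=1e-12)


class TestMannWhitney:
    def test_enumeration_hand_value(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact_enumeration"
        assert res.statistic == 0.0
        assert math.isclose(res.p_value, 1 / 3, abs_tol=1e-12)

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    @given(
        data=st.lists(
            st.integers(min_value=0, max_value=1000), min_size=4, max_size=10, unique=True
        ),
        split=st.integers(min_value=1, max_value=9),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_exact_p_matches_scipy_enumeration(self, data, split):
        if split >= len(data):
            return
        x, y = [float(v) for v in data[:split]], [float(v) for v in data[split:]]
        ours = mann_whitney(x, y)
        assert ours.method == "exact_enumeration"
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert math.isclose(ours.statistic, float(ref.statistic), abs_tol=1e-12)
        assert math.isclose(ours.p_value, float(ref.pvalue), abs_tol=1e-12)

    def test_normal_approx_close_to_exact_for_8_plus_8(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(0.5, 1.0, size=8)
            exact = mann_whitney(list(x), list(y), exact_cap=16)
            approx = mann_whitney(list(x), list(y), exact_cap=0)
            assert exact.method == "exact_enumeration"
            assert approx.method == "normal_approx"
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_ties_force_normal_approximation(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "normal_approx"

    def test_one_sided_not_offered(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0], alternative="greater")


class TestKruskalWallis:
    def test_hand_value(self):
        res = kruskal_wallis([(1, 2), (3, 4), (5, 6)])
        assert math.isclose(res.statistic, 32 / 7, abs_tol=1e-9)

    def test_duplicated_group_gives_zero(self):
        res = kruskal_wallis([(1.0, 2.0), (1.0, 2.0)])
        assert math.isclose(res.statistic, 0.0, abs_tol=1e-12)

    def test_all_identical_observations(self):
        res = kruskal_wallis([(5.0, 5.0), (5.0, 5.0, 5.0)])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=7), rng.normal(1, 1, size=5), rng.normal(2, 1, size=6)]
        ours = kruskal_wallis(groups)
        ref = scipy_kruskal(*groups)
        assert math.isclose(ours.statistic, float(ref.statistic), rel_tol=1e-10)
        assert math.isclose(ours.p_value, float(ref.pvalue), rel_tol=1e-8)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.uniform(1, 2, 5), rng.uniform(1.5, 3, 6)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert math.isclose(a.statistic, b.statistic, rel_tol=1e-12)

    def test_two_groups_equals_squared_mw_z(self, rng):
        """With 2 tie-free groups, H is the square of the standardized U."""
        x, y = rng.normal(size=6), rng.normal(size=7)
        h = kruskal_wallis([x, y]).statistic
        u = mann_whitney(list(x), list(y), exact_cap=0).statistic
        n_x, n_y = 6, 7
        z = (u - n_x * n_y / 2) / math.sqrt(n_x * n_y * (n_x + n_y + 1) / 12)
        assert math.isclose(h, z**2, rel_tol=1e-9)


class TestHostDissimilarity:
    def test_species_vs_itself_is_zero(self, catalog):
        leaves, _ = generate_leaves(GeneratorConfig(), seed=0)
        assert host_dissimilarity(leaves, "acer", "acer", catalog) == 0.0

    def test_disjoint_species_on_compound_basis(self, catalog):
        config = GeneratorConfig(tree_cv=0.0)
        base = {sp: {cid: 0.0 for cid in catalog.ids} for sp in ("acer", "carpinus", "quercus")}
        base["acer"]["CA1"] = 5.0
        base["carpinus"]["HH1"] = 5.0
        base["quercus"]["FL5"] = 5.0
        config = GeneratorConfig(tree_cv=0.0, base_concentrations=base)
        leaves, _ = generate_leaves(config, seed=0)
        assert host_dissimilarity(leaves, "acer", "carpinus", catalog) == 1.0

    def test_matrix_symmetric_zero_diagonal(self, catalog):
        leaves, _ = generate_leaves(GeneratorConfig(), seed=0)
        for basis in ("compounds", "subgroups_activities"):
            m = host_dissimilarity_matrix(leaves, catalog, basis)
            assert np.allclose(m.to_numpy(), m.to_numpy().T)
            assert np.all(np.diag(m.to_numpy()) == 0)

    def test_unknown_basis_rejected(self, catalog):
        leaves, _ = generate_leaves(GeneratorConfig(), seed=0)
        with pytest.raises(ValueError, match="basis"):
            host_dissimilarity(leaves, "acer", "quercus", catalog, basis="phylogeny")
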