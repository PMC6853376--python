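import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cernet import (
    UndefinedMetricError,
    asymmetry_index,
    expression_cv,
    intensity_stats,
    locality_correlation,
    locality_matrix,
    make_motif,
    selectivity,
    sextile_persistence,
    solve_steady_state,
    susceptibility_matrix,
    susceptible_region,
)
from cernet.network_model import BHScenario, BindingMode, InteractionNetwork, build_parameters


class TestIntensityStats:
    def test_identity_matrix_limit(self):
        mean_chi, max_chi, mean_self, max_self = intensity_stats(np.eye(4))
        assert (mean_chi, max_chi, mean_self, max_self) == (0.0, 0.0, 1.0, 1.0)

    def test_two_by_two_arithmetic(self):
        chi = np.array([[1.0, 0.3], [0.1, 1.0]])
        mean_chi, max_chi, _, _ = intensity_stats(chi)
        assert mean_chi == pytest.approx(0.2)
        assert max_chi == pytest.approx(0.3)


class TestSelectivity:
    def test_single_partner_is_maximally_selective(self):
        chi = np.zeros((3, 3))
        chi[0, 2] = 0.7
        chi[1, 0] = chi[1, 2] = chi[2, 0] = chi[2, 1] = 0.1
        _, _, g, _ = selectivity(chi)
        assert g[0] == pytest.approx(1.0)

    def test_uniform_row_is_minimally_selective(self):
        chi = np.full((5, 5), 0.2)
        _, _, g, h = selectivity(chi)
        assert g[0] == pytest.approx(1 / 4)
        assert h[0] == pytest.approx(1 / 4)

    def test_row_arithmetic(self):
        chi = np.zeros((3, 3))
        chi[0, 1], chi[0, 2] = 0.3, 0.1
        chi[1, 0] = chi[2, 0] = 0.5
        _, _, g, _ = selectivity(chi)
        assert g[0] == pytest.approx(0.625)

    def test_zero_rows_excluded_from_average(self):
        chi = np.zeros((3, 3))
        chi[0, 1] = 1.0
        s_in, s_out, g, h = selectivity(chi)
        assert s_in == pytest.approx(1.0)  # rows 1, 2 are undefined, excluded
        assert np.isnan(g[1]) and np.isnan(g[2])

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            selectivity(np.eye(3))

    @given(
        chi=hnp.arrays(
            float,
            (6, 6),
            # zero or O(1) entries; subnormal magnitudes would underflow
            # the squares and say nothing about the selectivity bounds
            elements=st.one_of(st.just(0.0), st.floats(1e-3, 10.0)),
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounds_on_defined_rows(self, chi):
        off = chi * ~np.eye(6, dtype=bool)
        if not off.sum(axis=1).any():
            return
        try:
            _, _, g, _ = selectivity(chi)
        except UndefinedMetricError:
            return
        defined = g[~np.isnan(g)]
        assert np.all(defined >= 1 / 5 - 1e-12)
        assert np.all(defined <= 1.0 + 1e-12)


class TestLocalityKernel:
    def make_net(self, edges, modes, n_rna, n_mirna, scenario):
        net = InteractionNetwork(
            tuple(f"r{i}" for i in range(n_rna)),
            tuple(f"a{a}" for a in range(n_mirna)),
            [e[0] for e in edges],
            [e[1] for e in edges],
            tuple(modes),
        )
        params = build_parameters(
            net, scenario, np.full(n_rna, 8.0), np.full(n_mirna, 1.0)
        )
        return net, params

    def test_single_shared_mirna(self):
        # medium BH: kmer edge carries mu0 = 4, seed-nc edge mu0 = 8
        net, params = self.make_net(
            [(0, 0), (1, 0)],
            [BindingMode.KMER, BindingMode.SEED_NC],
            2,
            2,
            BHScenario.medium(),
        )
        K = locality_matrix(net, params)
        assert K[0, 1] == pytest.approx(1 / 2 * 1 / 32)
        np.testing.assert_allclose(K, K.T)

    def test_two_shared_mirnas(self):
        # medium BH, all kmer: every edge carries mu0 = 4
        net, params = self.make_net(
            [(0, 0), (1, 0), (0, 1), (1, 1)],
            [BindingMode.KMER] * 4,
            2,
            2,
            BHScenario.medium(),
        )
        K = locality_matrix(net, params)
        assert K[0, 1] == pytest.approx(0.0625)

    def test_disjoint_pairs_are_zero(self):
        net, params = self.make_net(
            [(0, 0), (1, 1)], [BindingMode.KMER] * 2, 2, 2, BHScenario.medium()
        )
        assert locality_matrix(net, params)[0, 1] == 0.0


class TestLocalityCorrelation:
    def test_perfect_linearity(self):
        rng = np.random.default_rng(0)
        K = rng.random((5, 5))
        K = (K + K.T) / 2
        assert locality_correlation(3.0 * K, K) == pytest.approx(1.0)

    def test_anti_linear_case(self):
        # the implementation returns the true Pearson value in [-1, 1]
        chi = np.zeros((3, 3))
        K = np.zeros((3, 3))
        mask = ~np.eye(3, dtype=bool)
        chi[mask] = np.arange(1.0, 7.0)
        K[mask] = np.arange(6.0, 0.0, -1.0)
        assert locality_correlation(chi, K) == pytest.approx(-1.0)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(1)
        chi, K = rng.random((6, 6)), rng.random((6, 6))
        r1 = locality_correlation(chi, K)
        r2 = locality_correlation(0.3 * chi + 5.0, 7.0 * K + 1.0)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            locality_correlation(np.zeros((3, 3)), np.ones((3, 3)))


class TestAsymmetry:
    def test_symmetric_pattern_scores_zero(self):
        chi = np.array([[1.0, 0.2], [0.2, 1.0]])
        assert asymmetry_index(chi) == 0.0

    def test_one_directional_pair_scores_one(self):
        chi = np.zeros((2, 2))
        chi[0, 1] = 0.5
        assert asymmetry_index(chi) == pytest.approx(1.0)

    def test_no_pair_above_floor_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            asymmetry_index(np.eye(3), floor=1.0)

    def test_v_motif_with_unequal_rates_is_asymmetric(self):
        net, params = make_motif("v_motif")
        params = params.with_rates(np.array([12.0, 3.0]), np.array([3.0]))
        result, _ = susceptibility_matrix(net, params)
        assert asymmetry_index(result.chi) > 0.0


class TestExpressionCv:
    def test_equals_cv_of_b_without_repression(self, small_network):
        rng = np.random.default_rng(3)
        b = rng.lognormal(2.0, 0.5, small_network.n_rna)
        params = build_parameters(
            small_network, BHScenario.low(), b, np.zeros(small_network.n_mirna)
        )
        st = solve_steady_state(small_network, params)
        assert expression_cv(st) == pytest.approx(np.std(b) / np.mean(b), rel=1e-10)

    def test_constant_rates_give_zero(self, small_network):
        params = build_parameters(
            small_network,
            BHScenario.low(),
            np.full(small_network.n_rna, 8.0),
            np.zeros(small_network.n_mirna),
        )
        st = solve_steady_state(small_network, params)
        assert expression_cv(st) == pytest.approx(0.0, abs=1e-12)


class TestSextilePersistence:
    def test_identical_rankings_fully_conserved(self):
        rng = np.random.default_rng(5)
        x = rng.random(120)
        fractions, overall, _ = sextile_persistence(x, x.copy(), seed=0)
        assert np.all(fractions == 1.0)
        assert overall == 1.0

    def test_reversed_rankings_lose_top_bin(self):
        x = np.arange(120, dtype=float)
        fractions, _, _ = sextile_persistence(x, -x, seed=0)
        assert fractions[0] == 0.0

    def test_independent_rankings_match_chance(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(1200), rng.random(1200)
        fractions, overall, chance = sextile_persistence(x, y, seed=1)
        assert chance == pytest.approx(1 / 6, abs=0.01)
        # binomial fluctuation on 200 pairs per bin: 3 SE ~ 0.08
        assert np.all(np.abs(fractions - 1 / 6) < 0.09)
        assert overall == pytest.approx(1 / 6, abs=0.05)

    def test_bins_partition_pairs(self):
        x = np.arange(121, dtype=float)  # not divisible by 6
        fractions, overall, _ = sextile_persistence(x, x, n_permutations=10, seed=0)
        assert len(fractions) == 6
        assert overall == 1.0

    def test_pair_set_mismatch(self):
        with pytest.raises(ValueError, match="pair set"):
            sextile_persistence(np.arange(12.0), np.arange(10.0))


class TestSusceptibleRegion:
    def test_single_positive_point(self):
        beta = np.array([1.0, 10.0, 100.0])
        chi = np.array([0.0, 1.0, 0.0])
        assert susceptible_region(beta, chi) == (10.0, 10.0)

    def test_flat_curve_spans_grid(self):
        beta = np.array([1.0, 10.0, 100.0])
        assert susceptible_region(beta, np.ones(3)) == (1.0, 100.0)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            susceptible_region(np.array([1.0, 2.0, 3.0]), np.zeros(3))
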