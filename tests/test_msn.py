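"""Similarity-network construction: z-scoring identities, brute-force
correlation oracle, edge vectorisation, density thresholding and strength."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainage_msn.atlas import FEATURES, N_EDGES, N_FEATURES, N_REGIONS
from brainage_msn.msn import (
    MSNGraph,
    build_msn,
    edges_to_matrix,
    nodal_strength,
    threshold_by_density,
    vectorize_edges,
    zscore_across_regions,
)


def _random_block(rng, scale=True):
    block = rng.normal(2.0, 1.0, (N_REGIONS, N_FEATURES))
    if scale:
        block *= np.array([100, 1, 5, 0.1, 0.1, 2, 500])
    return block


class TestZscore:
    def test_columns_have_mean_zero_sd_one(self, rng):
        z = zscore_across_regions(_random_block(rng))
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_monotone_column_stays_monotone(self, rng):
        block = _random_block(rng)
        block[:, 0] = np.arange(1, N_REGIONS + 1)
        z = zscore_across_regions(block)
        assert np.all(np.diff(z[:, 0]) > 0)

    def test_constant_feature_errors_naming_subject_and_feature(self, rng):
        block = _random_block(rng)
        block[:, 3] = 1.0
        with pytest.raises(ValueError, match="gaussian_curvature.*sub-x"):
            zscore_across_regions(block, subject_id="sub-x")

    def test_affine_rescaling_leaves_msn_invariant(self, rng):
        """Edges are correlations of z-scores: scaling/shifting a raw feature
        column cannot change them."""
        block = _random_block(rng)
        g1 = build_msn(zscore_across_regions(block))
        block2 = block.copy()
        block2[:, 5] = 3.7 * block2[:, 5] - 12.0
        g2 = build_msn(zscore_across_regions(block2))
        np.testing.assert_allclose(g1.weights, g2.weights, atol=1e-12)


class TestBuildMSN:
    def test_identical_profiles_give_edge_one(self, rng):
        block = _random_block(rng, scale=False)
        block[1] = block[0]
        z = (block - block.mean(0)) / block.std(0)
        g = build_msn(z)
        assert g.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_correlation_oracle(self, rng):
        z = zscore_across_regions(_random_block(rng))
        g = build_msn(z)

        def pearson(u, v):  # textbook two-vector formula
            uc, vc = u - u.mean(), v - v.mean()
            return float((uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc)))

        for i, j in [(0, 1), (5, 40), (12, 67), (30, 31), (66, 67)]:
            assert abs(g.weights[i, j] - pearson(z[i], z[j])) < 1e-12
        assert np.allclose(g.weights, g.weights.T)
        i, j = np.triu_indices(N_REGIONS, 1)
        assert np.all(np.abs(g.weights[i, j]) <= 1.0)

    def test_anti_profile_gives_edge_minus_one(self):
        # build a full valid z matrix, then check the anti-correlated pair
        rng = np.random.default_rng(0)
        block = _random_block(rng, scale=False)
        z = zscore_across_regions(block)
        z[1] = -z[0]
        g = build_msn(z)
        assert g.weights[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_unthresholded_degree_is_67(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        assert np.all(g.degree == N_REGIONS - 1)

    def test_constant_region_profile_is_hard_error(self, rng):
        z = zscore_across_regions(_random_block(rng))
        z[7] = 0.42
        with pytest.raises(ValueError, match="constant feature profile"):
            build_msn(z)


class TestEdges:
    def test_edge_vector_length_is_2278(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        assert vectorize_edges(g).shape == (N_EDGES,) == (2278,)

    def test_three_node_toy_order(self):
        w = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        g = MSNGraph(subject_id="toy", weights=w)
        np.testing.assert_allclose(vectorize_edges(g), [0.1, 0.2, 0.3])

    def test_round_trip(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        np.testing.assert_allclose(edges_to_matrix(vectorize_edges(g)), g.weights, atol=0)


class TestThreshold:
    def test_density_one_keeps_everything(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        gt = threshold_by_density(g, 1.0)
        assert np.all(gt.degree == N_REGIONS - 1)
        np.testing.assert_array_equal(gt.mask, g.mask)

    def test_four_node_toy_matches_enumeration(self):
        # distinct |weights|; at 50% density of 6 edges, the top 3 survive:
        # (2,3)=0.9, (0,3)=-0.8, (1,2)=0.7 by exhaustive enumeration
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.1, (0, 2): 0.4, (0, 3): -0.8, (1, 2): 0.7, (1, 3): -0.2, (2, 3): 0.9}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        g = MSNGraph(subject_id="toy", weights=w)
        gt = threshold_by_density(g, 0.5)
        expected = {(2, 3), (0, 3), (1, 2)}
        surviving = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if gt.mask[i, j]}
        assert surviving == expected
        assert gt.weights[0, 3] == -0.8  # signed weights retained

    def test_density_5pct_keeps_114_edges(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        gt = threshold_by_density(g, 0.05)
        assert gt.mask[np.triu_indices(N_REGIONS, 1)].sum() == 114

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_nested_edge_sets_across_densities(self, seed):
        rng = np.random.default_rng(seed)
        g = build_msn(zscore_across_regions(_random_block(rng)))
        m1 = threshold_by_density(g, 0.10).mask
        m2 = threshold_by_density(g, 0.40).mask
        assert np.all(m2[m1])  # d1 < d2 -> surviving(d1) subseteq surviving(d2)

    def test_density_out_of_range_errors(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_by_density(g, bad)


class TestStrength:
    def test_unthresholded_strength_is_mean_edge_weight(self, rng):
        g = build_msn(zscore_across_regions(_random_block(rng)))
        strength, global_s = nodal_strength(g)
        expected = (g.weights.sum(axis=1)) / (N_REGIONS - 1)  # diagonal is zero
        np.testing.assert_allclose(strength, expected, atol=1e-12)
        assert global_s == pytest.approx(strength.mean())

    def test_constant_edges_give_constant_strength(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0.0)
        strength, global_s = nodal_strength(MSNGraph(subject_id="c", weights=w))
        np.testing.assert_allclose(strength, 0.3, atol=1e-12)
        assert global_s == pytest.approx(0.3)

    def test_thresholded_strength_matches_direct_summation(self, rng):
        g = threshold_by_density(build_msn(zscore_across_regions(_random_block(rng))), 0.3)
        strength, _ = nodal_strength(g)
        for i in range(N_REGIONS):
            s = sum(g.weights[i, j] for j in range(N_REGIONS) if g.mask[i, j])
            assert abs(strength[i] - s / g.degree[i]) < 1e-12

    def test_zero_degree_node_errors(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        g = MSNGraph(subject_id="z", weights=w)
        g.mask = np.zeros((4, 4), dtype=bool)
        g.mask[0, 1] = g.mask[1, 0] = True
        with pytest.raises(ValueError, match="zero degree"):
            nodal_strength(g)
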