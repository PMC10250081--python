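"""Block network type and its elementary operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from multinep.network import (
    FeatureSet,
    MultiOmicsNetwork,
    WeightConfig,
    column_normalize,
    compose,
    decompose,
    denoise,
    reweight,
    symmetrize,
)

from conftest import random_network


class TestFeatureSet:
    def test_canonical_order_is_genes_then_metabolites(self, toy_features):
        assert toy_features.all_ids == ("G1", "G2", "G3", "M1", "M2")
        assert toy_features.index_of("M1") == 3

    @pytest.mark.parametrize(
        "genes,mets",
        [([], ["M1"]), (["G1"], []), (["G1", "G1"], ["M1"]), (["X"], ["X"])],
    )
    def test_invalid_sets_rejected(self, genes, mets):
        with pytest.raises(ValueError):
            FeatureSet(genes, mets)


class TestNetworkValidation:
    def test_asymmetric_gg_rejected(self, toy_features):
        gg = np.zeros((3, 3))
        gg[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            MultiOmicsNetwork(toy_features, gg, np.zeros((2, 2)), np.zeros((3, 2)))

    def test_raw_confidence_bounded_at_999(self, toy_features):
        gm = np.zeros((3, 2))
        gm[0, 0] = 1000.0
        with pytest.raises(ValueError, match="999"):
            MultiOmicsNetwork(
                toy_features, np.zeros((3, 3)), np.zeros((2, 2)), gm,
                weight_scale="raw_confidence",
            )

    def test_negative_weights_rejected(self, toy_features):
        gm = np.zeros((3, 2))
        gm[1, 1] = -1.0
        with pytest.raises(ValueError, match="negative"):
            MultiOmicsNetwork(toy_features, np.zeros((3, 3)), np.zeros((2, 2)), gm)


class TestReweight:
    def test_identity_lambdas(self, toy_network):
        out = reweight(toy_network, 1.0, 1.0)
        np.testing.assert_array_equal(out.gg, toy_network.gg)
        np.testing.assert_array_equal(out.mm, toy_network.mm)
        np.testing.assert_array_equal(out.gm, toy_network.gm)

    def test_elementwise_scaling(self, toy_network):
        out = reweight(toy_network, 0.05, 20.0)
        assert out.gg[0, 1] == pytest.approx(45.0)  # 900 * 0.05
        assert out.mm[0, 1] == pytest.approx(200.0)  # 10 * 20
        np.testing.assert_array_equal(out.gm, toy_network.gm)

    def test_two_gene_one_metabolite_toy(self):
        feats = FeatureSet(["a", "b"], ["x"])
        net = MultiOmicsNetwork(
            feats,
            gg=np.array([[0.0, 1.0], [1.0, 0.0]]),
            mm=np.zeros((1, 1)),
            gm=np.ones((2, 1)),
        )
        out = reweight(net, 0.5, 2.0)
        assert out.gg[0, 1] == 0.5
        assert out.mm[0, 0] == 0.0
        np.testing.assert_array_equal(out.gm, np.ones((2, 1)))

    @pytest.mark.parametrize("lg,lm", [(0, 1), (-1, 1), (1, 0)])
    def test_nonpositive_lambda_rejected(self, toy_network, lg, lm):
        with pytest.raises(ValueError):
            reweight(toy_network, lg, lm)

    def test_linearity_per_block(self, rng):
        net = random_network(rng)
        a, b = 0.3, 1.7
        once = reweight(net, a * b, 1.0)
        twice = reweight(reweight(net, b, 1.0), a, 1.0)
        np.testing.assert_allclose(once.gg, twice.gg, rtol=1e-12)


class TestSymmetrize:
    def test_forced_arithmetic(self):
        out = symmetrize(np.array([[0.0, 2.0], [0.0, 0.0]]))
        np.testing.assert_array_equal(out, np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            symmetrize(np.zeros((2, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (4, 4), elements=st.floats(-10, 10)))
    def test_idempotent_and_exact(self, M):
        out = symmetrize(M)
        np.testing.assert_array_equal(out, out.T)
        np.testing.assert_array_equal(symmetrize(out), out)


class TestDenoise:
    def test_keep_all_is_identity(self, toy_network):
        out = denoise(toy_network, 1.0, 1.0, 1.0)
        np.testing.assert_array_equal(out.gg, toy_network.gg)
        np.testing.assert_array_equal(out.gm, toy_network.gm)

    def test_top_fraction_cut(self):
        # 5 distinct gg edge weights; keep 0.4 -> ceil(0.4*5)=2 edges survive
        feats = FeatureSet([f"g{i}" for i in range(5)], ["m0"])
        gg = np.zeros((5, 5))
        for (i, j), w in zip([(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)], [9, 7, 5, 3, 1]):
            gg[i, j] = gg[j, i] = w
        net = MultiOmicsNetwork(feats, gg, np.zeros((1, 1)), np.zeros((5, 1)))
        out = denoise(net, 0.4, 1.0, 1.0)
        kept = sorted(out.gg[np.triu_indices(5, k=1)][out.gg[np.triu_indices(5, k=1)] > 0])
        assert kept == [7.0, 9.0]

    def test_tie_break_keeps_exact_count(self):
        # all weights equal: exactly ceil(keep*E) edges survive, chosen by
        # (row, col) lexicographic order
        feats = FeatureSet([f"g{i}" for i in range(4)], ["m0"])
        gg = np.ones((4, 4)) - np.eye(4)
        net = MultiOmicsNetwork(feats, gg, np.zeros((1, 1)), np.zeros((4, 1)))
        out = denoise(net, 0.5, 1.0, 1.0)  # 6 edges -> keep 3
        iu = np.triu_indices(4, k=1)
        survivors = [(i, j) for i, j, w in zip(*iu, out.gg[iu]) if w > 0]
        assert survivors == [(0, 1), (0, 2), (0, 3)]

    def test_empty_block_passes_through(self, toy_features, caplog):
        net = MultiOmicsNetwork(
            toy_features, np.zeros((3, 3)), np.zeros((2, 2)), np.ones((3, 2))
        )
        out = denoise(net, 0.5, 0.5, 1.0)
        np.testing.assert_array_equal(out.gg, net.gg)

    def test_never_increases_weights_or_edges(self, rng):
        net = random_network(rng, n_genes=12, n_metabolites=5)
        out = denoise(net, 0.3, 0.5, 0.2)
        for block in ("gg", "mm", "gm"):
            assert np.all(out.block(block) <= net.block(block))
            assert out.edge_count(block) <= net.edge_count(block)
            np.testing.assert_array_equal(out.gg, out.gg.T)


class TestColumnNormalize:
    def test_forced_arithmetic_with_zero_column(self):
        out = column_normalize(np.array([[1.0, 0.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(out[:, 0], [0.5, 0.5])
        np.testing.assert_array_equal(out[:, 1], [0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            column_normalize(np.array([[1.0, -1.0], [0.0, 2.0]]))

    def test_stochastic_and_idempotent(self, rng):
        M = rng.random((6, 6))
        M[:, 2] = 0.0
        out = column_normalize(M)
        sums = out.sum(axis=0)
        np.testing.assert_allclose(np.delete(sums, 2), 1.0, atol=1e-12)
        assert sums[2] == 0.0
        np.testing.assert_allclose(column_normalize(out), out, atol=1e-14)


class TestComposeDecompose:
    def test_round_trip_exact(self, rng):
        net = random_network(rng)
        back = decompose(compose(net), net.features, net.weight_scale)
        np.testing.assert_array_equal(compose(back), compose(net))

    def test_block_order(self):
        feats = FeatureSet(["a", "b"], ["x"])
        net = MultiOmicsNetwork(
            feats,
            gg=np.array([[0.0, 5.0], [5.0, 0.0]]),
            mm=np.zeros((1, 1)),
            gm=np.array([[7.0], [0.0]]),
        )
        full = compose(net)
        assert full.shape == (3, 3)
        assert full[0, 1] == 5.0 and full[0, 2] == 7.0 and full[2, 0] == 7.0

    def test_dimension_mismatch_rejected(self):
        feats = FeatureSet(["a", "b"], ["x"])
        with pytest.raises(ValueError):
            decompose(np.zeros((4, 4)), feats)


class TestWeightConfig:
    def test_defaults_match_reference_parameterization(self):
        cfg = WeightConfig()
        assert (cfg.lambda_g, cfg.lambda_m) == (0.05, 20.0)
        assert cfg.alpha == cfg.beta == 0.75
        assert (cfg.keep_gg, cfg.keep_mm, cfg.keep_gm) == (0.05, 0.30, 0.15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 1.0},
            {"beta": -0.1},
            {"lambda_g": 0.0},
            {"keep_gg": 0.0},
            {"keep_gm": 1.5},
            {"tol": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WeightConfig(**kwargs)
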