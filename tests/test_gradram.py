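"""Grad-RAM localization maps: analytic gradients, variant algebra, I/O."""

import numpy as np
import pytest

from xdta.gradram import (VARIANTS, FeatureMapStack, LocalizationMap,
                          feature_gradients, gradram_map, maps_for_batch,
                          project_to_input, read_map_tsv, write_map_tsv)
from xdta.model import AffinityCNN, NetworkSpec


def brute_force_map(acts, grads, pooling, guided):
    """Literal elementwise recomputation of the localization-map formulas."""
    u, k = acts.shape
    g = grads.copy()
    if guided:
        for i in range(u):
            for j in range(k):
                if not (acts[i, j] > 0 and g[i, j] > 0):
                    g[i, j] = 0.0
    out = np.zeros(u)
    for j in range(k):
        alpha = max(g[:, j]) if pooling == "GMP" else sum(g[:, j]) / u
        for i in range(u):
            out[i] += alpha * acts[i, j]
    return np.maximum(out, 0.0)


def random_stack(seed, u=6, k=3):
    rng = np.random.default_rng(seed)
    return FeatureMapStack(activations=np.maximum(rng.normal(size=(u, k)), 0.0),
                           gradients=rng.normal(size=(u, k)))


class TestGradramMap:
    def test_all_negative_gradients_guided_gives_zero_map(self):
        stack = FeatureMapStack(activations=np.abs(np.random.default_rng(0).normal(size=(5, 2))),
                                gradients=-np.ones((5, 2)))
        for pooling in ("GMP", "GAP"):
            assert not gradram_map(stack, pooling, guided=True).values.any()

    def test_single_map_constant_gradient_reduces_to_scaled_activation(self):
        stack = FeatureMapStack(activations=np.array([[0.0], [2.0], [1.0]]),
                                gradients=np.full((3, 1), 0.5))
        loc = gradram_map(stack, "GMP", guided=True)
        np.testing.assert_allclose(loc.values, [0.0, 1.0, 0.5])

    @pytest.mark.parametrize("pooling", ["GMP", "GAP"])
    @pytest.mark.parametrize("guided", [True, False])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recomputation(self, pooling, guided, seed):
        stack = random_stack(seed)
        loc = gradram_map(stack, pooling, guided)
        expect = brute_force_map(stack.activations, stack.gradients, pooling, guided)
        np.testing.assert_allclose(loc.values, expect, atol=1e-12)
        assert np.all(loc.values >= 0)

    def test_guided_equals_nonguided_when_all_positive(self):
        rng = np.random.default_rng(3)
        stack = FeatureMapStack(activations=rng.uniform(0.1, 1, (6, 4)),
                                gradients=rng.uniform(0.1, 1, (6, 4)))
        for pooling in ("GMP", "GAP"):
            g = gradram_map(stack, pooling, True).values
            ng = gradram_map(stack, pooling, False).values
            np.testing.assert_allclose(g, ng)

    def test_gradient_scaling_homogeneity_preserves_rank_order(self):
        stack = random_stack(11)
        base = gradram_map(stack, "GAP", guided=False).values
        scaled_stack = FeatureMapStack(activations=stack.activations,
                                       gradients=3.0 * stack.gradients)
        scaled = gradram_map(scaled_stack, "GAP", guided=False).values
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-12)
        assert np.array_equal(np.argsort(base), np.argsort(scaled))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            FeatureMapStack(activations=np.zeros((0, 2)), gradients=np.zeros((0, 2)))


class TestHandComputedToyNet:
    """A 1-conv-layer net with hand-set weights has hand-computable maps."""

    def build(self):
        spec = NetworkSpec(prot_conv=((2, 1),), smiles_conv=((1, 1),),
                          dense=(2,), dropout_rate=0.0)
        net = AffinityCNN(spec, prot_len=3, prot_dict_size=2,
                          smiles_len=2, smiles_dict_size=1, seed=0)
        # conv weights (k=1, cin, cout): filter0 detects symbol0, filter1 symbol1
        net.params["p_conv0_w"] = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
        net.params["p_conv0_b"] = np.zeros(2, dtype=np.float32)
        net.params["s_conv0_w"] = np.zeros((1, 1, 1), dtype=np.float32)
        net.params["s_conv0_b"] = np.zeros(1, dtype=np.float32)
        # head: identity-ish -> y = 2*pool_p0 + 1*pool_p1
        net.params["dense0_w"] = np.array([[2.0, 0.0], [1.0, 0.0], [0.0, 0.0]],
                                          dtype=np.float32)
        net.params["dense0_b"] = np.zeros(2, dtype=np.float32)
        net.params["out_w"] = np.array([[1.0], [0.0]], dtype=np.float32)
        net.params["out_b"] = np.zeros(1, dtype=np.float32)
        return net

    def test_maps_equal_hand_computation(self):
        net = self.build()
        xp = np.array([[[1, 0], [0, 1], [1, 0]]], dtype=np.float32)
        xs = np.zeros((1, 2, 1), dtype=np.float32)
        stack = feature_gradients(net, xp, xs, "protein")
        # activations: A = one-hot input itself; y = 2*max(A0) + 1*max(A1) = 3
        np.testing.assert_allclose(stack.activations, xp[0])
        # dy/dA nonzero only at each filter's (first) argmax: (0,0)->2, (1,1)->1
        expect_g = np.array([[2, 0], [0, 1], [0, 0]], dtype=float)
        np.testing.assert_allclose(stack.gradients, expect_g)
        # GMP-G: alpha = (2, 1); map = 2*A0 + 1*A1 = [2,1,2]
        np.testing.assert_allclose(gradram_map(stack, "GMP", True).values, [2, 1, 2])
        # GAP-G: alpha = (2/3, 1/3); map = [2/3, 1/3, 2/3]
        np.testing.assert_allclose(gradram_map(stack, "GAP", True).values,
                                   [2 / 3, 1 / 3, 2 / 3], atol=1e-6)
        # non-guided variants coincide here (all grads/acts nonnegative)
        np.testing.assert_allclose(gradram_map(stack, "GMP", False).values, [2, 1, 2])
        np.testing.assert_allclose(gradram_map(stack, "GAP", False).values,
                                   [2 / 3, 1 / 3, 2 / 3], atol=1e-6)


class TestBackpropGradients:
    def test_gradients_match_finite_differences(self, tiny_net, random_onehot):
        """Central finite differences on feature-map cells with a unique
        positive pooled maximum agree to relative 1e-3."""
        xp, xs = random_onehot(1)
        A, G = tiny_net.feature_map_gradients(xp, xs, "protein")
        As, _ = tiny_net.feature_map_gradients(xp, xs, "smiles")
        rng = np.random.default_rng(1)
        eps = 1e-3
        checked = 0
        cells = [(u, k) for u in range(A.shape[1]) for k in range(A.shape[2])]
        rng.shuffle(cells)
        for u, k in cells:
            col = A[0, :, k]
            top2 = np.sort(col)[-2:]
            if top2[1] <= 0 or top2[1] - top2[0] < 10 * eps:
                continue  # max-pool kink: derivative not defined/approximable
            up, down = A.copy(), A.copy()
            up[0, u, k] += eps
            down[0, u, k] -= eps
            fd = (tiny_net.predict_from_feature_maps(up, As)[0]
                  - tiny_net.predict_from_feature_maps(down, As)[0]) / (2 * eps)
            an = G[0, u, k]
            assert an == pytest.approx(fd, rel=1e-3, abs=1e-4)
            checked += 1
            if checked == 20:
                break
        assert checked == 20

    def test_identical_pair_identical_stack_and_shapes(self, tiny_net, random_onehot):
        xp, xs = random_onehot(1)
        s1 = feature_gradients(tiny_net, xp, xs, "protein")
        s2 = feature_gradients(tiny_net, xp, xs, "protein")
        np.testing.assert_array_equal(s1.activations, s2.activations)
        np.testing.assert_array_equal(s1.gradients, s2.gradients)
        assert s1.activations.shape == s1.gradients.shape

    def test_unknown_branch_rejected(self, tiny_net, random_onehot):
        xp, xs = random_onehot(1)
        with pytest.raises(ValueError):
            feature_gradients(tiny_net, xp, xs, "rna")


class TestProjectionAndIO:
    def loc(self, values):
        return LocalizationMap(values=np.asarray(values, dtype=float),
                               branch="protein", variant="GMP-G")

    def test_no_padding_unchanged(self):
        loc = self.loc([1.0, 0.5, 2.0])
        out = project_to_input(loc, np.array([1, 1, 1]))
        np.testing.assert_array_equal(out.values, loc.values)

    def test_padded_tail_zeroed(self):
        out = project_to_input(self.loc([1.0, 0.5, 2.0]), np.array([1, 1, 0]))
        np.testing.assert_array_equal(out.values, [1.0, 0.5, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            project_to_input(self.loc([1.0]), np.array([1, 0]))

    def test_tsv_roundtrip_bit_exact(self, tmp_path):
        values = np.random.default_rng(0).random(7)
        loc = self.loc(values)
        write_map_tsv(tmp_path / "m.tsv", loc, "ACDEFGH")
        loc2, seq = read_map_tsv(tmp_path / "m.tsv")
        assert seq == "ACDEFGH"
        np.testing.assert_array_equal(loc2.values, values)
        assert loc2.variant == "GMP-G" and loc2.branch == "protein"

    def test_maps_for_batch_variants(self, tiny_net, random_onehot):
        xp, xs = random_onehot(3)
        masks = np.ones((3, 12), dtype=np.int64)
        for variant in VARIANTS:
            maps = maps_for_batch(tiny_net, xp, xs, "protein", variant, masks=masks)
            assert len(maps) == 3
            for loc in maps:
                assert loc.variant == variant
                assert np.all(loc.values >= 0)
        with pytest.raises(ValueError):
            maps_for_batch(tiny_net, xp, xs, "protein", "MAX-G")
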