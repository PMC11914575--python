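"""Three-arm network contracts: output shapes, the consistency arm's
pooling invariances, loss-function oracles, and mixed-batch construction."""

import numpy as np
import pytest

from angiodl.network import (MixedBatch, ModelConfig, NetworkOutputs, RnaSlide,
                             ThreeArmNet, TrainingPairLike, build_network,
                             loss_consistency, loss_rna, loss_seg,
                             make_cd31_batch, make_rna_batch,
                             wcce_weights_from_pairs)


@pytest.fixture(scope="module")
def small_net():
    return build_network(ModelConfig(patch_size=32, init_seed=0))


@pytest.fixture(scope="module")
def patch_stack(small_net):
    rng = np.random.default_rng(0)
    return rng.integers(0, 255, (8, 32, 32, 3)).astype(np.uint8)


class TestNetworkContract:
    def test_output_shapes(self, small_net, patch_stack):
        out = small_net.forward(patch_stack)
        assert out.mask_prob.shape == (8, 2, 32, 32)
        assert out.angio.shape == (8,)
        assert out.cons.shape == (8,)

    def test_pixel_probabilities_sum_to_one(self, small_net, patch_stack):
        out = small_net.forward(patch_stack)
        assert np.abs(out.mask_prob.sum(axis=1) - 1.0).max() < 1e-5

    def test_consistency_head_is_pixel_permutation_invariant(self, small_net,
                                                             patch_stack, rng):
        mp = small_net.forward(patch_stack).mask_prob.astype(np.float64)
        perm = rng.permutation(32 * 32)
        shuffled = mp.reshape(8, 2, -1)[:, :, perm].reshape(mp.shape)
        c1 = small_net.consistency_from_mask_prob(mp)
        c2 = small_net.consistency_from_mask_prob(shuffled)
        assert np.abs(c1 - c2).max() <= 1e-6

    def test_consistency_head_monotone_in_uniform_shift(self, small_net,
                                                        patch_stack):
        mp = small_net.forward(patch_stack).mask_prob.astype(np.float64)
        base = small_net.consistency_from_mask_prob(mp)
        for delta in (0.05, 0.1, 0.2):
            up = mp.copy()
            up[:, 1] = np.clip(up[:, 1] + delta, 0, 1)
            up[:, 0] = 1 - up[:, 1]
            assert (small_net.consistency_from_mask_prob(up) >= base).all()
            base = small_net.consistency_from_mask_prob(up)

    def test_odd_patch_size_is_config_error(self):
        with pytest.raises(ValueError):
            ModelConfig(patch_size=65)

    def test_loss_weight_sum_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(dice_weight=0.8, wcce_weight=0.1)

    def test_cons_gradient_stops_at_the_pooled_activation(self, patch_stack):
        # the consistency loss trains the head but must not reshape the mask
        net = build_network(ModelConfig(patch_size=32, init_seed=1))
        out = net.forward_t(patch_stack)
        (out.cons ** 2).sum().backward()
        assert np.abs(net.params["cons2_w"].grad).max() > 0
        for key in ("mask_w", "dec_w", "enc1a_w"):
            grad = net.params[key].grad
            assert grad is None or np.abs(grad).max() == 0

    def test_cons_gradient_flows_when_configured(self, patch_stack):
        net = build_network(ModelConfig(patch_size=32, init_seed=1,
                                        cons_stop_gradient=False))
        out = net.forward_t(patch_stack)
        (out.cons ** 2).sum().backward()
        assert np.abs(net.params["mask_w"].grad).max() > 0

    def test_save_load_roundtrip(self, small_net, patch_stack, tmp_path):
        small_net.save(tmp_path / "ckpt")
        loaded = ThreeArmNet.load(tmp_path / "ckpt")
        a = small_net.forward(patch_stack)
        b = loaded.forward(patch_stack)
        assert np.allclose(a.mask_prob, b.mask_prob)
        assert np.allclose(a.angio, b.angio)


class TestLossRna:
    def test_perfect_prediction_is_zero(self):
        out = NetworkOutputs(None, np.full(4, 2.0), np.full(4, 2.0))
        assert loss_rna(out, {"s": 2.0}, ["s"] * 4).item() == 0.0

    def test_hand_evaluated_single_slide(self):
        out = NetworkOutputs(None, np.array([2.0, 4.0]), np.array([3.0, 5.0]))
        # means 3 and 4 vs target 3: (0 + 1)/1
        assert loss_rna(out, {"a": 3.0}, ["a", "a"]).item() == pytest.approx(1.0)

    def test_average_over_slides(self):
        out = NetworkOutputs(None, np.array([1.0, 3.0]), np.array([0.0, 3.0]))
        # slide a: (0-1)^2+(0-0)^2 = 1 ; slide b: (2-3)^2+(2-3)^2 = 2
        got = loss_rna(out, {"a": 0.0, "b": 2.0}, ["a", "b"]).item()
        assert got == pytest.approx((1.0 + 2.0) / 2)

    def test_brute_force_oracle_over_random_batches(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_slides = int(rng.integers(1, 5))
            per = int(rng.integers(1, 6))
            ids = [f"s{i}" for i in range(n_slides) for _ in range(per)]
            angio = rng.normal(0, 1, len(ids))
            cons = rng.normal(0, 1, len(ids))
            targets = {f"s{i}": float(rng.normal()) for i in range(n_slides)}
            got = loss_rna(NetworkOutputs(None, angio, cons), targets, ids).item()
            exp = np.mean([
                (targets[s] - angio[[i for i, d in enumerate(ids) if d == s]].mean())**2
                + (targets[s] - cons[[i for i, d in enumerate(ids) if d == s]].mean())**2
                for s in dict.fromkeys(ids)])
            assert got == pytest.approx(exp, abs=1e-6)

    def test_missing_target_is_error(self):
        out = NetworkOutputs(None, np.zeros(2), np.zeros(2))
        with pytest.raises(KeyError):
            loss_rna(out, {"a": 1.0}, ["a", "b"])


class TestLossSeg:
    def test_near_one_hot_prediction_is_near_zero(self):
        truth = np.array([[[0, 1], [1, 0]]])
        eps = 1e-6
        prob = np.empty((1, 2, 2, 2))
        prob[0, 1] = np.where(truth[0] == 1, 1 - eps, eps)
        prob[0, 0] = 1 - prob[0, 1]
        assert loss_seg(prob, truth).item() <= 0.01

    def test_hand_evaluated_uniform_prediction(self):
        prob = np.full((1, 2, 2, 2), 0.5)
        truth = np.array([[[0, 0], [1, 1]]])
        dice = 1 - 0.5 * 2 * ((2 * 1.0 + 1) / (2 + 2 + 1))
        wcce = -np.log(0.5 + 1e-7)
        assert loss_seg(prob, truth).item() == pytest.approx(
            0.9 * dice + 0.1 * wcce, abs=1e-9)

    def test_inverted_worse_than_uniform(self):
        truth = np.array([[[0, 0], [1, 1]]])
        uniform = np.full((1, 2, 2, 2), 0.5)
        inverted = np.empty_like(uniform)
        inverted[0, 1] = np.where(truth[0] == 1, 1e-4, 1 - 1e-4)
        inverted[0, 0] = 1 - inverted[0, 1]
        assert loss_seg(inverted, truth).item() > loss_seg(uniform, truth).item()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_seg(np.full((1, 2, 4, 4), 0.5), np.zeros((1, 2, 2)))

    def test_class_weights_scale_the_ce_term(self):
        truth = np.array([[[1, 1], [1, 1]]])
        prob = np.full((1, 2, 2, 2), 0.5)
        light = loss_seg(prob, truth, class_weights=(1.0, 0.5)).item()
        heavy = loss_seg(prob, truth, class_weights=(1.0, 2.0)).item()
        assert heavy > light


class TestLossConsistency:
    @pytest.mark.parametrize("a,c,expected", [
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([0.0, 0.0], [1.0, 1.0], 1.0),
        ([1.0, 3.0], [2.0, 5.0], 2.5),
    ])
    def test_hand_values(self, a, c, expected):
        assert loss_consistency(np.array(a), np.array(c)).item() == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_consistency(np.zeros(3), np.zeros(2))


def _toy_rna_dataset(n_slides=10, per=8, size=16):
    rng = np.random.default_rng(3)
    return [RnaSlide(f"s{i}",
                     [rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
                      for _ in range(per)],
                     float(i))
            for i in range(n_slides)]


class TestBatchConstruction:
    def test_rna_batch_composition(self, rng):
        batch = make_rna_batch(_toy_rna_dataset(), rng, ModelConfig(patch_size=16))
        assert batch.kind == "RNA"
        assert batch.patches.shape[0] == 32
        counts = {s: batch.slide_ids.count(s) for s in set(batch.slide_ids)}
        assert len(counts) == 4 and all(v == 8 for v in counts.values())
        assert set(batch.targets) == set(counts)

    def test_too_few_slides_is_instructive_error(self, rng):
        with pytest.raises(ValueError, match="rna_n_slides"):
            make_rna_batch(_toy_rna_dataset(n_slides=3), rng,
                           ModelConfig(patch_size=16))

    def test_rna_batch_reproducible(self):
        ds = _toy_rna_dataset()
        cfg = ModelConfig(patch_size=16)
        b1 = make_rna_batch(ds, np.random.default_rng(11), cfg)
        b2 = make_rna_batch(ds, np.random.default_rng(11), cfg)
        assert b1.slide_ids == b2.slide_ids
        assert np.array_equal(b1.patches, b2.patches)

    def test_contract_holds_over_many_seeds(self):
        ds = _toy_rna_dataset()
        cfg = ModelConfig(patch_size=16)
        for seed in range(200):
            b = make_rna_batch(ds, np.random.default_rng(seed), cfg)
            assert len(set(b.slide_ids)) == 4
            assert all(b.slide_ids.count(s) == 8 for s in set(b.slide_ids))

    def test_cd31_batch_of_four(self, rng):
        pairs = [TrainingPairLike(np.zeros((16, 16, 3), np.uint8),
                                  np.zeros((16, 16), np.uint8))
                 for _ in range(100)]
        b = make_cd31_batch(pairs, rng, ModelConfig(patch_size=16))
        assert b.kind == "CD31"
        assert b.patches.shape[0] == 4 and b.masks.shape[0] == 4
        assert not b.with_replacement

    def test_small_pair_set_falls_back_to_replacement(self, rng):
        pairs = [TrainingPairLike(np.zeros((16, 16, 3), np.uint8),
                                  np.zeros((16, 16), np.uint8))
                 for _ in range(2)]
        b = make_cd31_batch(pairs, rng, ModelConfig(patch_size=16))
        assert b.patches.shape[0] == 4 and b.with_replacement

    def test_empty_pair_set_is_error(self, rng):
        with pytest.raises(ValueError):
            make_cd31_batch([], rng, ModelConfig(patch_size=16))


def test_wcce_weights_inverse_frequency_mean_one():
    mask = np.zeros((10, 10), np.uint8)
    mask[:2] = 1   # 20% positive
    w = wcce_weights_from_pairs([TrainingPairLike(np.zeros((10, 10, 3)), mask)])
    assert np.mean(w) == pytest.approx(1.0)
    assert w[1] / w[0] == pytest.approx(0.8 / 0.2)
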