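"""Training schedule, checkpoint selection and inference scoring.

Network-level learning checks use tiny patch sizes; the full desk-scale
parameter-recovery run lives in the acceptance suite.
"""

import numpy as np
import pytest

from angiodl.network import (ModelConfig, RnaSlide, ThreeArmNet,
                             TrainingPairLike, build_network, loss_seg)
from angiodl.synth import make_vessel_patch
from angiodl.train import (SlideScore, kfold_slide_split, pretrain_mask_arm,
                           render_heatmap, score_patch, score_slide,
                           select_best_checkpoint, train_mixed)


@pytest.fixture(scope="module")
def tiny_pairs():
    patches = [make_vessel_patch(200 + i, 32, 0.12) for i in range(6)]
    return [TrainingPairLike(p.rgb, p.mask) for p in patches]


def _tiny_config(**kw):
    return ModelConfig(patch_size=32, rna_n_slides=2, rna_patches_per_slide=2,
                       **kw)


def _tiny_rna(n_slides=4, per=2):
    out = []
    for i in range(n_slides):
        ps = [make_vessel_patch(300 + 10 * i + j, 32, 0.02 + 0.06 * i).rgb
              for j in range(per)]
        out.append(RnaSlide(f"s{i}", ps, 0.1 * i))
    return out


class TestPretrain:
    def test_overfitting_one_batch_reduces_seg_loss(self, tiny_pairs):
        cfg = _tiny_config(init_seed=1)
        net0 = build_network(cfg)
        batch = np.stack([tiny_pairs[0].he_patch])
        masks = np.stack([tiny_pairs[0].mask])
        before = loss_seg(net0.forward(batch).mask_prob, masks).item()
        net = pretrain_mask_arm(tiny_pairs[:1], cfg, epochs=25, lr=1e-2, seed=0)
        after = loss_seg(net.forward(batch).mask_prob, masks).item()
        assert after < before

    def test_zero_epochs_returns_initial_network(self, tiny_pairs):
        cfg = _tiny_config(init_seed=2)
        net = pretrain_mask_arm(tiny_pairs, cfg, epochs=0)
        ref = build_network(cfg)
        for k in net.params:
            assert np.array_equal(net.params[k].data, ref.params[k].data)

    def test_loss_trajectory_deterministic(self, tiny_pairs):
        cfg = _tiny_config(init_seed=3)
        a = pretrain_mask_arm(tiny_pairs, cfg, epochs=2, lr=1e-2, seed=4)
        b = pretrain_mask_arm(tiny_pairs, cfg, epochs=2, lr=1e-2, seed=4)
        assert a.pretrain_log == b.pretrain_log

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            pretrain_mask_arm([], _tiny_config())


class TestTrainMixed:
    def test_bookkeeping_checkpoints_and_logs(self, tiny_pairs, tmp_path):
        cfg = _tiny_config(init_seed=5)
        net = build_network(cfg)
        state = train_mixed(net, _tiny_rna(), tiny_pairs, cfg, epochs=2,
                            lr=1e-3, seed=0, checkpoint_dir=tmp_path,
                            validation_slides=_tiny_rna(3))
        assert state.epochs_completed == 2
        assert len(state.checkpoint_paths) == 2
        assert len(state.metric_history) == 2
        kinds = {k for _, k, _ in state.loss_log}
        assert kinds == {"RNA", "CD31"}
        state.write_loss_csv(tmp_path / "log.csv")
        assert (tmp_path / "log.csv").read_text().startswith("step,batch_kind,loss")

    def test_zero_learning_rate_is_null_update(self, tiny_pairs):
        cfg = _tiny_config(init_seed=6)
        net = build_network(cfg)
        before = {k: v.data.copy() for k, v in net.params.items()}
        train_mixed(net, _tiny_rna(), tiny_pairs, cfg, epochs=1, lr=0.0,
                    momentum=0.0, seed=0, init_output_bias=False)
        for k, v in net.params.items():
            assert np.array_equal(v.data, before[k])

    def test_empty_dataset_rejected(self, tiny_pairs):
        net = build_network(_tiny_config())
        with pytest.raises(ValueError):
            train_mixed(net, [], tiny_pairs, epochs=1)
        with pytest.raises(ValueError):
            train_mixed(net, _tiny_rna(), [], epochs=1)


class TestCheckpointSelection:
    def _save(self, tmp_path, name, seed):
        net = build_network(_tiny_config(init_seed=seed))
        net.save(tmp_path / name)
        return tmp_path / name

    def test_single_checkpoint_returned(self, tmp_path):
        p = self._save(tmp_path, "only", 0)
        assert select_best_checkpoint([p], _tiny_rna(3)) == p

    def test_argmax_of_validation_spearman(self, tiny_pairs, tmp_path):
        # one untrained and one pretrained checkpoint: the trained one must
        # rank the validation slides better or equal, and selection follows
        cfg = _tiny_config(init_seed=7)
        raw = build_network(cfg)
        raw.save(tmp_path / "raw")
        trained = pretrain_mask_arm(tiny_pairs, cfg, epochs=10, lr=1e-2, seed=1)
        trained.save(tmp_path / "trained")
        val = []
        for i, f in enumerate([0.02, 0.1, 0.2, 0.3]):
            p = make_vessel_patch(900 + i, 32, f)
            val.append(RnaSlide(f"v{i}", [p.rgb], np.log1p(10 * f)))
        best = select_best_checkpoint([tmp_path / "raw", tmp_path / "trained"], val)
        net = ThreeArmNet.load(best)
        scores = [score_slide(net, s.patches).he_dl_angioscore for s in val]
        from scipy import stats
        got = stats.spearmanr(scores, [s.target for s in val]).statistic
        assert got == max(
            stats.spearmanr(
                [score_slide(ThreeArmNet.load(c), s.patches).he_dl_angioscore
                 for s in val], [s.target for s in val]).statistic
            for c in [tmp_path / "raw", tmp_path / "trained"])

    def test_requires_three_validation_slides(self, tmp_path):
        p = self._save(tmp_path, "x", 0)
        with pytest.raises(ValueError):
            select_best_checkpoint([p], _tiny_rna(2))


class _StubNet:
    """Network stand-in emitting a fixed positive-probability per patch,
    read from the patch's top-left red value (0-255 -> 0-1)."""

    config = ModelConfig(patch_size=32)

    def forward(self, patches):
        from angiodl.network import NetworkOutputs
        n, h, w = patches.shape[0], patches.shape[1], patches.shape[2]
        pos = np.array([np.full((h, w), p[0, 0, 0] / 255.0) for p in patches])
        return NetworkOutputs(np.stack([1 - pos, pos], axis=1),
                              pos.mean(axis=(1, 2)), pos.mean(axis=(1, 2)))


def _const_patch(value, size=32):
    return np.full((size, size, 3), value, np.uint8)


class TestScoring:
    def test_all_positive_scores_100(self):
        assert score_patch(_StubNet(), _const_patch(255)) == 100.0

    def test_all_negative_scores_0(self):
        assert score_patch(_StubNet(), _const_patch(0)) == 0.0

    def test_threshold_splits_at_half(self):
        assert score_patch(_StubNet(), _const_patch(200), threshold=0.5) == 100.0
        assert score_patch(_StubNet(), _const_patch(100), threshold=0.5) == 0.0

    def test_slide_score_is_mean_of_patches(self):
        patches = [_const_patch(0), _const_patch(255), _const_patch(255)]
        s = score_slide(_StubNet(), patches, slide_id="x")
        assert isinstance(s, SlideScore)
        assert s.he_dl_angioscore == pytest.approx(200 / 3)
        assert s.n_patches == 3
        assert min(s.per_patch_scores) <= s.he_dl_angioscore <= max(s.per_patch_scores)

    def test_slide_score_permutation_invariant(self):
        a = score_slide(_StubNet(), [_const_patch(v) for v in (0, 255, 255)])
        b = score_slide(_StubNet(), [_const_patch(v) for v in (255, 0, 255)])
        assert a.he_dl_angioscore == b.he_dl_angioscore

    def test_duplicate_patch_pulls_mean_toward_it(self):
        base = score_slide(_StubNet(), [_const_patch(0), _const_patch(255)])
        dup = score_slide(_StubNet(), [_const_patch(0), _const_patch(255),
                                       _const_patch(255)])
        assert base.he_dl_angioscore < dup.he_dl_angioscore <= 100.0

    def test_zero_patches_rejected(self):
        with pytest.raises(ValueError):
            score_slide(_StubNet(), [])


class TestHeatmap:
    def test_uniform_predictions_give_uniform_heatmap(self):
        items = [(_const_patch(255), (x * 32, 0)) for x in range(4)]
        heat = render_heatmap(_StubNet(), items, grid_px=64)
        vals = heat[~np.isnan(heat)]
        assert np.allclose(vals, 100.0)

    def test_two_regions_ordered_by_planted_fraction(self):
        lo = [(_const_patch(50), (x * 32, 0)) for x in range(2)]
        hi = [(_const_patch(250), (200 + x * 32, 0)) for x in range(2)]
        heat = render_heatmap(_StubNet(), lo + hi, grid_px=64)
        vals = heat[0]
        assert np.nanmin(vals[-2:]) >= np.nanmax(vals[:2])

    def test_empty_cells_are_nan(self):
        items = [(_const_patch(255), (0, 0)), (_const_patch(255), (300, 0))]
        heat = render_heatmap(_StubNet(), items, grid_px=64)
        assert np.isnan(heat).any()
        assert np.nansum(heat) == pytest.approx(200.0)


def test_kfold_split_partitions_slides():
    ids = [f"s{i}" for i in range(10)]
    folds = kfold_slide_split(ids, n_folds=3, seed=1)
    held = [h for _, hold in folds for h in hold]
    assert sorted(held) == sorted(ids)
    for train, hold in folds:
        assert set(train).isdisjoint(hold)
        assert sorted(set(train) | set(hold)) == sorted(ids)
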