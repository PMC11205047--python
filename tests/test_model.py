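"""Model assembly, assignment, loss and inference tests."""

import numpy as np
import pytest

from leafseg import masks_io, model as M
from leafseg.autograd import Tensor
from leafseg.model import ModelConfig, TrainConfig


@pytest.fixture(scope="module")
def nano_cfg():
    return ModelConfig(variant="standard", scale="n", image_size=64)


@pytest.fixture(scope="module")
def nano_model(nano_cfg):
    return M.build_model(nano_cfg, seed=0)


class TestBuild:
    def test_all_variants_emit_three_strides(self, rng):
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        for variant in ("standard", "bifpn", "ghost"):
            net = M.build_model(ModelConfig(variant=variant, scale="n", image_size=64), seed=0)
            outs, proto = net(x)
            assert [o["box"].shape[2] for o in outs] == [8, 4, 2]  # strides 8/16/32
            assert proto.shape == (1, net.cfg.num_prototypes, 16, 16)  # stride 4

    def test_ghost_has_fewer_parameters_than_standard(self):
        std = M.build_model(ModelConfig(variant="standard", scale="n"), seed=0)
        gho = M.build_model(ModelConfig(variant="ghost", scale="n"), seed=0)
        assert gho.num_parameters() < std.num_parameters()

    def test_bifpn_has_fusion_weight_parameters(self):
        from leafseg.net_blocks import FusionWeights

        std = M.build_model(ModelConfig(variant="standard", scale="n"), seed=0)
        bif = M.build_model(ModelConfig(variant="bifpn", scale="n"), seed=0)
        n_std = sum(isinstance(m, FusionWeights) for m in std.modules())
        n_bif = sum(isinstance(m, FusionWeights) for m in bif.modules())
        assert n_std == 0 and n_bif == 4  # two transition + two output nodes

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="huge")
        with pytest.raises(ValueError):
            ModelConfig(image_size=100)
        with pytest.raises(ValueError):
            ModelConfig(scale="q")


class TestAssignment:
    def _anchors(self):
        return M.make_anchors(64)

    def test_full_image_gt_gets_topk_positives(self, rng):
        anchors, _ = self._anchors()
        A = anchors.shape[0]
        gt = np.array([[0.0, 0.0, 64.0, 64.0]])
        scores = rng.uniform(0.2, 0.9, A)
        boxes = np.tile(gt, (A, 1)) + rng.normal(0, 2, (A, 4))
        out = M.assign_targets(scores, boxes, anchors, gt, topk=10)
        assert out.fg_mask.sum() == 10

    def test_disjoint_gts_have_disjoint_positives(self, rng):
        anchors, _ = self._anchors()
        A = anchors.shape[0]
        gt = np.array([[0.0, 0.0, 24.0, 24.0], [40.0, 40.0, 64.0, 64.0]])
        scores = rng.uniform(0.2, 0.9, A)
        # predicted boxes centred on each anchor
        boxes = np.stack(
            [anchors[:, 0] - 8, anchors[:, 1] - 8, anchors[:, 0] + 8, anchors[:, 1] + 8], axis=1
        )
        out = M.assign_targets(scores, boxes, anchors, gt, topk=5)
        pos0 = (out.gt_index == 0) & out.fg_mask
        pos1 = (out.gt_index == 1) & out.fg_mask
        assert pos0.any() and pos1.any()
        assert not (pos0 & pos1).any()
        # anchors inside gt0 never assigned to gt1
        inside0 = (anchors[:, 0] < 24) & (anchors[:, 1] < 24)
        assert not (pos1 & inside0).any()

    def test_zero_iou_anchor_never_positive(self, rng):
        anchors, _ = self._anchors()
        A = anchors.shape[0]
        gt = np.array([[0.0, 0.0, 16.0, 16.0]])
        boxes = np.tile([48.0, 48.0, 60.0, 60.0], (A, 1))  # no overlap with gt
        out = M.assign_targets(np.full(A, 0.9), boxes, anchors, gt)
        assert not out.fg_mask.any()

    def test_no_ground_truth_empty_assignment(self):
        anchors, _ = self._anchors()
        out = M.assign_targets(
            np.full(anchors.shape[0], 0.5),
            np.zeros((anchors.shape[0], 4)),
            anchors,
            np.zeros((0, 4)),
        )
        assert not out.fg_mask.any()
        assert out.target_scores.sum() == 0.0


class TestDflTargets:
    def test_integer_distance_is_delta(self):
        w = M.dfl_target_weights(np.array([3.0]), reg_max=16)
        assert w.shape == (1, 16)
        assert w[0, 3] == 1.0 and w[0].sum() == 1.0
        # a delta prediction on the same bin has zero cross-entropy
        logits = np.full(16, -20.0)
        logits[3] = 20.0
        logp = logits - np.log(np.exp(logits - logits.max()).sum()) - logits.max()
        assert -(w[0] * logp).sum() == pytest.approx(0.0, abs=1e-6)

    def test_fractional_distance_interpolates(self):
        w = M.dfl_target_weights(np.array([2.25]), reg_max=16)
        assert w[0, 2] == pytest.approx(0.75)
        assert w[0, 3] == pytest.approx(0.25)

    def test_out_of_range_clipped(self):
        w = M.dfl_target_weights(np.array([100.0]), reg_max=16)
        assert w[0].sum() == pytest.approx(1.0)
        assert w[0, 14] + w[0, 15] == pytest.approx(1.0)


class TestLoss:
    def test_background_only_image(self, nano_model, nano_cfg, rng):
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        nano_model.train()
        outs, proto = nano_model(x)
        targets = [{"boxes": np.zeros((0, 4)), "masks": np.zeros((0, 16, 16))}]
        loss, comps = M.compute_loss(outs, proto, targets, nano_cfg, TrainConfig(epochs=1, close_mosaic=0))
        assert comps["box"] == comps["dfl"] == comps["mask"] == 0.0
        assert comps["cls"] > 0.0
        assert np.isfinite(float(loss.data))

    def test_loss_finite_with_instances(self, nano_model, nano_cfg, small_scene):
        x = Tensor(small_scene.image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        nano_model.train()
        outs, proto = nano_model(x)
        targets = [M._targets_from_labels(small_scene.labels, (16, 16))]
        loss, comps = M.compute_loss(outs, proto, targets, nano_cfg, TrainConfig(epochs=1, close_mosaic=0))
        assert np.isfinite(float(loss.data))
        assert all(np.isfinite(v) for v in comps.values())

    def test_overfit_fixed_batch_decreases_loss(self, nano_cfg, small_scene):
        """Optimisation sanity: 40 SGD steps on one image cut the loss."""
        from leafseg.nn import SGD

        net = M.build_model(nano_cfg, seed=1)
        x = Tensor(small_scene.image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        targets = [M._targets_from_labels(small_scene.labels, (16, 16))]
        tcfg = TrainConfig(epochs=1, close_mosaic=0)
        opt = SGD(net.parameters(), lr=0.01, momentum=0.9)
        losses = []
        for _ in range(40):
            outs, proto = net(x)
            loss, _ = M.compute_loss(outs, proto, targets, nano_cfg, tcfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        # assignment grows as confidence rises, so the trajectory is not
        # monotone; the best achieved loss must still clearly undercut the start
        assert min(losses) < 0.5 * losses[0]


class TestNms:
    def test_overlapping_detections_deduplicated(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]], float)
        keep = M.nms(boxes, np.array([0.9, 0.8, 0.7]), iou_threshold=0.5)
        assert keep.tolist() == [0, 2]

    def test_disjoint_detections_kept(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30]], float)
        keep = M.nms(boxes, np.array([0.5, 0.9]), iou_threshold=0.5)
        assert sorted(keep.tolist()) == [0, 1]


class TestPredict:
    def test_score_threshold_one_gives_empty_map(self, nano_model, small_scene):
        cfg_strict = ModelConfig(variant="standard", scale="n", image_size=64, conf_threshold=1.0)
        nano_model.cfg = cfg_strict
        try:
            pred = M.predict_instances(nano_model, small_scene.image)
        finally:
            nano_model.cfg = ModelConfig(variant="standard", scale="n", image_size=64)
        assert pred.labels.max() == 0
        assert pred.boxes.shape == (0, 4)

    def test_deterministic_for_fixed_input(self, nano_model, small_scene):
        a = M.predict_instances(nano_model, small_scene.image)
        b = M.predict_instances(nano_model, small_scene.image)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.scores, b.scores)

    def test_instances_sorted_and_consistent(self, nano_model, small_scene):
        pred = M.predict_instances(nano_model, small_scene.image)
        assert np.all(np.diff(pred.scores) <= 0)
        n = pred.boxes.shape[0]
        ids = np.unique(pred.labels)
        assert ids[ids > 0].size == n  # one id per surviving detection
        # every foreground pixel belongs to exactly one instance by construction
        assert pred.labels.min() >= 0


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, nano_model, small_scene):
        p = tmp_path / "m.npz"
        M.save_checkpoint(nano_model, p)
        restored = M.load_checkpoint(p)
        a = M.predict_instances(nano_model, small_scene.image)
        b = M.predict_instances(restored, small_scene.image)
        assert np.array_equal(a.labels, b.labels)


class TestTrainLoop:
    def test_two_epoch_smoke_all_variants(self, scene_samples):
        """Ghost and BiFPN train under the identical loop, config-only switch."""
        tcfg = TrainConfig(epochs=2, batch_size=4, close_mosaic=0, val_interval=2, seed=0)
        for variant in ("standard", "bifpn", "ghost"):
            cfg = ModelConfig(variant=variant, scale="n", image_size=64)
            net = M.build_model(cfg, seed=0)
            logbook = M.train(net, scene_samples[:6], scene_samples[6:], tcfg)
            assert len(logbook.epochs) == 2
            assert np.isfinite(logbook.epochs[-1]["loss"])

    def test_close_mosaic_equal_epochs_never_uses_mosaic(self, scene_samples):
        tcfg = TrainConfig(epochs=2, batch_size=4, close_mosaic=2, val_interval=5, seed=0)
        cfg = ModelConfig(variant="standard", scale="n", image_size=64)
        net = M.build_model(cfg, seed=0)
        logbook = M.train(net, scene_samples[:4], [], tcfg)
        assert all(not e["mosaic"] for e in logbook.epochs)

    def test_empty_dataset_rejected(self):
        cfg = ModelConfig(variant="standard", scale="n", image_size=64)
        net = M.build_model(cfg, seed=0)
        with pytest.raises(ValueError):
            M.train(net, [], [], TrainConfig(epochs=1, close_mosaic=0))

    def test_close_mosaic_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=5, close_mosaic=10)
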