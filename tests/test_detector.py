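"""Splits, model construction, training loop, ensembling, decoding, NMS."""

import numpy as np
import pytest

from marinesed.detector import (
    Detection,
    EarlyStopping,
    TrainConfig,
    TrainingSample,
    average_maps,
    decode,
    ensemble_predict,
    grouped_stratified_split,
    kfold_split,
    nms,
    train_fold,
)
from marinesed.model import C2f, ModelConfig, PredictionMap, build_model
from marinesed import nn

TINY_CFG = ModelConfig(
    input_bins=16, input_frames=64, stem_channels=8, channels=(8, 8, 8), classes=4
)


class TestGroupedSplit:
    def test_recording_ids_disjoint(self, corpus):
        train_c, test_c = grouped_stratified_split(corpus, 0.6, seed=0)
        train_recs = {s.recording_id for s in train_c.segments}
        test_recs = {s.recording_id for s in test_c.segments}
        assert train_recs & test_recs == set()
        assert len(train_c.segments) + len(test_c.segments) == len(corpus.segments)

    def test_per_class_fraction_near_target(self, corpus):
        train_c, _ = grouped_stratified_split(corpus, 0.6, seed=1)
        for species in corpus.classes:
            n_total = len(corpus.by_class(species))
            n_train = len(train_c.by_class(species))
            assert 0.5 <= n_train / n_total <= 0.7

    def test_same_seed_same_split(self, corpus):
        a = grouped_stratified_split(corpus, 0.6, seed=5)
        b = grouped_stratified_split(corpus, 0.6, seed=5)
        assert [s.recording_id for s in a[0].segments] == [
            s.recording_id for s in b[0].segments
        ]

    def test_single_recording_class_goes_to_train(self):
        from marinesed.fixtures import gen_corpus

        c = gen_corpus(n_per_class=3, n_recordings_per_class=1, seed=0)
        train_c, test_c = grouped_stratified_split(c, 0.6, seed=0)
        assert len(train_c.segments) == len(c.segments)
        assert len(test_c.segments) == 0


class TestKfold:
    def test_partition_into_balanced_folds(self):
        assignment = kfold_split(10, k=5, seed=0)
        sizes = np.bincount(assignment, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_each_sample_validates_once(self):
        assignment = kfold_split(23, k=5, seed=1)
        assert assignment.size == 23
        assert set(assignment) == set(range(5))
        assert np.bincount(assignment).max() - np.bincount(assignment).min() <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, k=5)


class TestBuildModel:
    def test_three_scales_with_configured_cells(self):
        model = build_model(TINY_CFG, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 16, 64))
        maps = model.forward(x)
        assert [m.data.shape for m in maps] == [
            (2, TINY_CFG.head_channels, 16),
            (2, TINY_CFG.head_channels, 8),
            (2, TINY_CFG.head_channels, 4),
        ]

    def test_same_seed_same_init(self):
        a = build_model(TINY_CFG, seed=3)
        b = build_model(TINY_CFG, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_different_init(self):
        a = build_model(TINY_CFG, seed=3)
        b = build_model(TINY_CFG, seed=4)
        assert any(
            not np.array_equal(pa.data, pb.data)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_c2f_bypass_ablation_changes_output(self):
        rng = np.random.default_rng(0)
        block = C2f(8, 8, rng=np.random.default_rng(1))
        x = nn.Tensor(rng.normal(size=(1, 8, 16)))
        full = block(x).data.copy()
        block.disable_bypass = True
        ablated = block(x).data
        assert full.shape == ablated.shape
        assert not np.allclose(full, ablated)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(backbone="efficientnet_b3")


def _toy_samples(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = rng.normal(size=(16, 64)) * 0.1
        out.append(TrainingSample(x=x, events=[(0, 1.0, 2.2)], window_s=5.0))
    return out


class TestTrainFold:
    def test_smoke_run_records_history(self):
        model = build_model(TINY_CFG, seed=0)
        tc = TrainConfig(batch_size=4, max_epochs=2, patience=1, folds=2, seed=0)
        model, hist = train_fold(model, _toy_samples(8), _toy_samples(4, 1), tc)
        assert len(hist) == 2
        assert all(np.isfinite(h["train_loss"]) for h in hist)

    def test_best_checkpoint_tracks_min_val_loss(self):
        model = build_model(TINY_CFG, seed=1)
        tc = TrainConfig(batch_size=4, max_epochs=4, patience=3, folds=2, seed=0)
        model, hist = train_fold(model, _toy_samples(8), _toy_samples(4, 1), tc)
        best = min(h["val_loss"] for h in hist)
        from marinesed.detector import _eval_loss

        assert _eval_loss(model, _toy_samples(4, 1), TINY_CFG, 4) == pytest.approx(
            best, rel=1e-9
        )

    def test_empty_sets_rejected(self):
        model = build_model(TINY_CFG, seed=0)
        tc = TrainConfig(max_epochs=2, patience=1)
        with pytest.raises(ValueError):
            train_fold(model, [], _toy_samples(2), tc)


class TestEarlyStopping:
    def test_stops_after_exact_patience_on_plateau(self):
        stopper = EarlyStopping(patience=3)
        losses = [1.0, 0.8, 0.8, 0.8, 0.8, 0.5]
        stopped_at = None
        for epoch, v in enumerate(losses):
            if stopper.update(v, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 4  # best at epoch 1, then 3 stale epochs
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        seq = [1.0, 0.9, 0.95, 0.85, 0.9, 0.95]
        decisions = [stopper.update(v, e) for e, v in enumerate(seq)]
        assert decisions == [False, False, False, False, False, True]


def _const_map(value=0.5, cells=(4,), n_classes=4, window=5.0):
    return PredictionMap(
        obj=[np.full(c, value) for c in cells],
        cls=[np.full((n_classes, c), value) for c in cells],
        center_s=[np.linspace(0.5, window - 0.5, c) for c in cells],
        width_s=[np.full(c, 1.0) for c in cells],
        window_s=window,
    )


class TestEnsemble:
    def test_identical_maps_idempotent(self):
        m = _const_map(0.7)
        avg = average_maps([m, m, m])
        np.testing.assert_allclose(avg.obj[0], m.obj[0], rtol=1e-12)
        np.testing.assert_allclose(avg.cls[0], m.cls[0], rtol=1e-12)

    def test_two_maps_average(self):
        a, b = _const_map(0.2), _const_map(0.8)
        avg = average_maps([a, b])
        np.testing.assert_allclose(avg.obj[0], 0.5)

    def test_order_invariant(self):
        maps = [_const_map(v) for v in (0.1, 0.5, 0.9)]
        fwd = average_maps(maps)
        rev = average_maps(maps[::-1])
        np.testing.assert_allclose(fwd.obj[0], rev.obj[0])

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_maps([_const_map(cells=(4,)), _const_map(cells=(8,))])

    def test_ensemble_predict_equals_single_model_when_duplicated(self):
        model = build_model(TINY_CFG, seed=0)
        x = np.random.default_rng(0).normal(size=(16, 64)) * 0.1
        single = model.predict(x, 5.0)
        ens = ensemble_predict([model, model], x, 5.0)
        np.testing.assert_allclose(ens.obj[0], single.obj[0])


class TestDecode:
    def _hot_cell_map(self):
        obj = np.zeros(8)
        cls = np.zeros((4, 8))
        obj[3] = 0.9
        cls[2, 3] = 0.8
        center = np.full(8, 2.5)
        width = np.full(8, 0.5)
        center[3], width[3] = 1.5, 1.0  # encodes the interval [1.0, 2.0] s
        return PredictionMap([obj], [cls], [center], [width], 5.0)

    def test_hand_built_map_decodes_expected_detection(self):
        dets = decode(self._hot_cell_map(), conf_threshold=0.5)
        assert len(dets) == 1
        (d,) = dets
        assert d.class_id == 2
        assert d.confidence == pytest.approx(0.72)
        assert d.t_start_s == pytest.approx(1.0, abs=5.0 / 8)
        assert d.t_end_s == pytest.approx(2.0, abs=5.0 / 8)

    def test_threshold_one_empty(self):
        assert decode(_const_map(0.9), conf_threshold=1.0) == []

    def test_threshold_zero_one_detection_per_cell(self):
        pmap = _const_map(0.5, cells=(4, 2))
        assert len(decode(pmap, conf_threshold=0.0)) == 6

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        pmap = PredictionMap(
            obj=[rng.random(16)],
            cls=[rng.random((4, 16))],
            center_s=[rng.uniform(0, 5, 16)],
            width_s=[rng.uniform(0.1, 2, 16)],
            window_s=5.0,
        )
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            dets = {
                (d.class_id, d.t_start_s, d.t_end_s, d.confidence)
                for d in decode(pmap, thr)
            }
            if prev is not None:
                assert dets <= prev
            prev = dets


class TestNms:
    def test_duplicate_keeps_highest_confidence(self):
        a = Detection(0, 1.0, 2.0, 0.9)
        b = Detection(0, 1.0, 2.0, 0.8)
        assert nms([a, b]) == [a]

    def test_disjoint_all_kept(self):
        dets = [Detection(0, 0.0, 1.0, 0.9), Detection(0, 2.0, 3.0, 0.8)]
        assert len(nms(dets)) == 2

    def test_chain_keeps_first_and_third(self):
        # A suppresses B (IoU 0.6), C is disjoint from A but overlapped B
        a = Detection(0, 0.0, 2.0, 0.9)
        b = Detection(0, 0.5, 2.5, 0.8)  # IoU(a,b) = 1.5/2.5 = 0.6 > 0.5
        c = Detection(0, 2.1, 4.0, 0.7)
        assert nms([a, b, c]) == [a, c]

    def test_cross_class_never_suppresses(self):
        a = Detection(0, 1.0, 2.0, 0.9)
        b = Detection(1, 1.0, 2.0, 0.8)
        assert len(nms([a, b])) == 2

    def test_order_invariant_with_distinct_confidences(self):
        rng = np.random.default_rng(0)
        dets = [
            Detection(int(rng.integers(2)), t0 := rng.uniform(0, 4), t0 + rng.uniform(0.2, 1.5), conf)
            for conf in np.linspace(0.1, 0.9, 12)
        ]
        a = nms(dets)
        b = nms(dets[::-1])
        assert {(d.class_id, d.t_start_s, d.confidence) for d in a} == {
            (d.class_id, d.t_start_s, d.confidence) for d in b
        }

    def test_agrees_with_independent_reimplementation(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            dets = []
            for _ in range(rng.integers(2, 10)):
                t0 = rng.uniform(0, 4)
                dets.append(
                    Detection(
                        int(rng.integers(3)),
                        t0,
                        t0 + rng.uniform(0.2, 2.0),
                        float(rng.random()),
                    )
                )
            kept = nms(dets, 0.5)

            def iou(a, b):
                inter = max(0.0, min(a.t_end_s, b.t_end_s) - max(a.t_start_s, b.t_start_s))
                return inter / ((a.t_end_s - a.t_start_s) + (b.t_end_s - b.t_start_s) - inter)

            survivors = []
            for d in sorted(dets, key=lambda d: (-d.confidence, d.t_start_s, d.class_id)):
                if not any(
                    s.class_id == d.class_id and iou(s, d) > 0.5 for s in survivors
                ):
                    survivors.append(d)
            assert kept == survivors
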