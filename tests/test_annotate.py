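"""Adaptive-threshold annotation and YOLO serialization."""

import numpy as np
import pytest

from marinesed.annotate import (
    AnnotationFailure,
    AnnotationSet,
    BoundingBox,
    adaptive_threshold,
    annotate_nonoverlap,
    annotate_overlap,
    estimate_background,
    freq_bounds,
    read_yolo,
    species_box_stats,
    write_yolo,
)
from marinesed.mixer import plan_nonoverlap, plan_overlap, render
from marinesed.spectro import Spectrogram, StftParams, stft_spectrogram, to_db

RATE = 40_000


def db_spec(values):
    return Spectrogram(np.asarray(values, dtype=float), "dB", RATE, StftParams())


class TestBackgroundAndThreshold:
    def test_constant_matrix_background(self):
        assert estimate_background(db_spec(np.full((10, 10), -7.0))) == -7.0

    def test_median_ignores_outlier_cells(self):
        v = np.zeros((10, 10))
        v[0, 0] = -80.0
        assert estimate_background(db_spec(v)) == 0.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(-40, 5, size=(50, 50))
        assert estimate_background(db_spec(v + 5)) == pytest.approx(
            estimate_background(db_spec(v)) + 5
        )
        assert adaptive_threshold(db_spec(v + 5)) == pytest.approx(
            adaptive_threshold(db_spec(v)) + 5
        )

    def test_mad_degenerate_gives_3db_margin(self):
        assert adaptive_threshold(db_spec(np.full((5, 5), -10.0))) == -7.0

    def test_large_mad_dominates(self):
        # thirds at -2/0/+2 -> median 0, MAD 2 -> threshold 0 + 5
        v = np.repeat([-2.0, 0.0, 2.0], 300).reshape(30, 30)
        assert adaptive_threshold(db_spec(v)) == pytest.approx(5.0)

    def test_small_mad_floors_at_3db(self):
        v = np.repeat([-1.0, 0.0, 1.0], 300).reshape(30, 30)  # MAD 1 -> max(3, 2.5)
        assert adaptive_threshold(db_spec(v)) == pytest.approx(3.0)

    def test_wrong_scale_rejected(self):
        lin = Spectrogram(np.ones((4, 4)), "linear", RATE, StftParams())
        with pytest.raises(ValueError):
            estimate_background(lin)


class TestFreqBounds:
    def test_recovers_planted_band(self):
        v = np.full((513, 100), -40.0)
        v[100:201, 20:60] = -20.0
        lo, hi = freq_bounds(db_spec(v), 20, 60, threshold=-30.0)
        assert (lo, hi) == (100, 200)

    def test_single_hot_bin(self):
        v = np.full((513, 50), -40.0)
        v[50, :] = 0.0
        assert freq_bounds(db_spec(v), 0, 50, threshold=-10.0) == (50, 50)

    def test_all_background_is_a_failure(self):
        v = np.full((513, 50), -40.0)
        with pytest.raises(AnnotationFailure):
            freq_bounds(db_spec(v), 0, 50, threshold=-30.0)

    def test_threshold_shift_leaves_selected_bins_unchanged(self):
        rng = np.random.default_rng(1)
        v = rng.normal(-40, 2, size=(513, 60))
        v[200:240, :] += 25.0
        s = db_spec(v)
        sel = freq_bounds(s, 0, 60, adaptive_threshold(s))
        s2 = db_spec(v + 11.0)
        assert freq_bounds(s2, 0, 60, adaptive_threshold(s2)) == sel


class TestAnnotateNonoverlap:
    def test_boxes_separate_low_sweep_from_high_clicks(self, corpus, class_map):
        # find a mixture containing both the low FM sweep and the click train
        for seed in range(40):
            m = plan_nonoverlap(corpus, rng_seed=seed)
            species = {e.species for e in m.events}
            if {"fm_sweep", "click_train"} <= species:
                break
        else:
            pytest.fail("no seed produced the wanted class pair")
        r = render(m, corpus, rng_seed=seed)
        s = to_db(stft_spectrogram(r.waveform))
        ann = annotate_nonoverlap(s, m, class_map)
        by_class = {b.class_id: b for b in ann.boxes}
        sweep = by_class[class_map["fm_sweep"]]
        click = by_class[class_map["click_train"]]
        assert sweep.f_high_hz < click.f_low_hz

    def test_temporal_bounds_pass_through(self, corpus, class_map):
        m = plan_nonoverlap(corpus, rng_seed=3)
        r = render(m, corpus, rng_seed=3)
        s = to_db(stft_spectrogram(r.waveform))
        ann = annotate_nonoverlap(s, m, class_map)
        starts = {round(b.t_start_s, 9) for b in ann.boxes}
        assert starts <= {round(e.start_s, 9) for e in m.events}

    def test_band_edges_recovered_within_two_bins(self, corpus, class_map):
        # planted-band fixture at spectrogram level
        hz_per_bin = RATE / 1024
        v = np.full((513, 782), -40.0) + np.random.default_rng(2).normal(
            0, 1, size=(513, 782)
        )
        v[150:251, 100:300] += 30.0
        from marinesed.mixer import EventPlacement, MixtureManifest

        t0 = 100 * 256 / RATE
        t1 = 300 * 256 / RATE
        m = MixtureManifest([EventPlacement("fm_sweep", 0, t0, t1)], mode="nonoverlap")
        ann = annotate_nonoverlap(db_spec(v), m, class_map)
        (box,) = ann.boxes
        assert abs(box.f_low_hz - 150 * hz_per_bin) <= 2 * hz_per_bin
        assert abs(box.f_high_hz - 251 * hz_per_bin) <= 2 * hz_per_bin


class TestSpeciesStats:
    def _ann(self, boxes):
        return AnnotationSet(boxes, 5.0, RATE)

    def test_mean_height(self, class_map):
        boxes = [
            BoundingBox(0, 0.0, 1.0, 100.0, 200.0),
            BoundingBox(0, 1.5, 2.5, 100.0, 400.0),
        ]
        cm = {"fm_sweep": 0}
        stats = species_box_stats([self._ann(boxes)], cm)
        assert stats.mean_height_hz["fm_sweep"] == pytest.approx(200.0)
        assert stats.counts["fm_sweep"] == 2

    def test_single_box_stats_equal_that_box(self):
        b = BoundingBox(0, 0.0, 1.0, 300.0, 700.0)
        stats = species_box_stats([self._ann([b])], {"fm_sweep": 0})
        assert stats.mean_height_hz["fm_sweep"] == 400.0
        assert stats.mean_center_hz["fm_sweep"] == 500.0

    def test_permutation_invariant(self):
        boxes = [
            BoundingBox(0, 0.0, 1.0, 100.0, 200.0),
            BoundingBox(0, 1.5, 2.5, 50.0, 450.0),
            BoundingBox(0, 3.0, 4.0, 20.0, 120.0),
        ]
        cm = {"fm_sweep": 0}
        a = species_box_stats([self._ann(boxes)], cm)
        b = species_box_stats([self._ann(boxes[::-1])], cm)
        assert a == b

    def test_missing_class_is_an_error(self):
        b = BoundingBox(0, 0.0, 1.0, 100.0, 200.0)
        with pytest.raises(ValueError, match="click_train"):
            species_box_stats([self._ann([b])], {"fm_sweep": 0, "click_train": 1})


class TestAnnotateOverlap:
    def test_boxes_use_species_means(self, corpus, class_map):
        from marinesed.annotate import SpeciesBoxStats

        stats = SpeciesBoxStats(
            mean_height_hz={c: 400.0 for c in class_map},
            mean_center_hz={c: 300.0 for c in class_map},
            counts={c: 5 for c in class_map},
        )
        m = plan_overlap(corpus, rng_seed=1)
        r = render(m, corpus, rng_seed=1)
        s = to_db(stft_spectrogram(r.waveform))
        ann = annotate_overlap(s, m, stats, class_map)
        assert len(ann.boxes) == len(m.events)
        for b in ann.boxes:
            assert b.source == "species_mean"
            assert (b.f_low_hz, b.f_high_hz) == (100.0, 500.0)

    def test_clipping_truncates_at_low_edge(self, corpus, class_map):
        from marinesed.annotate import SpeciesBoxStats

        stats = SpeciesBoxStats(
            mean_height_hz={c: 400.0 for c in class_map},
            mean_center_hz={c: 100.0 for c in class_map},
            counts={c: 1 for c in class_map},
        )
        m = plan_overlap(corpus, rng_seed=2)
        r = render(m, corpus, rng_seed=2)
        s = to_db(stft_spectrogram(r.waveform))
        ann = annotate_overlap(s, m, stats, class_map)
        for b in ann.boxes:
            assert (b.f_low_hz, b.f_high_hz) == (0.0, 300.0)


class TestYoloSerialization:
    def test_full_image_box(self):
        ann = AnnotationSet([BoundingBox(2, 0.0, 5.0, 0.0, 20_000.0)], 5.0, RATE)
        (line,) = write_yolo(ann, 782, 513)
        cid, xc, yc, w, h = line.split()
        assert cid == "2"
        assert [float(v) for v in (xc, yc, w, h)] == [0.5, 0.5, 1.0, 1.0]

    def test_half_width_box_normalization(self):
        # frames [0, 391] of 782 -> x_center 0.25, width 0.5
        t_end = 391 / 782 * 5.0
        ann = AnnotationSet([BoundingBox(0, 0.0, t_end, 0.0, 20_000.0)], 5.0, RATE)
        (line,) = write_yolo(ann, 782, 513)
        _, xc, _, w, _ = (float(v) for v in line.split())
        assert xc == pytest.approx(0.25, abs=1e-6)
        assert w == pytest.approx(0.5, abs=1e-6)

    def test_round_trip_100_random_boxes(self):
        rng = np.random.default_rng(4)
        boxes = []
        for _ in range(100):
            t0, t1 = np.sort(rng.uniform(0, 5.0, 2))
            f0, f1 = np.sort(rng.uniform(0, 20_000.0, 2))
            if t1 - t0 < 1e-3 or f1 - f0 < 1.0:
                continue
            boxes.append(BoundingBox(int(rng.integers(4)), t0, t1, f0, f1))
        ann = AnnotationSet(boxes, 5.0, RATE)
        lines = write_yolo(ann, 782, 513)
        back = read_yolo(lines, 5.0, RATE, 782, 513)
        dt = 5.0 / 782
        df = 20_000.0 / 513
        for a, b in zip(ann.boxes, back.boxes):
            assert a.class_id == b.class_id
            assert abs(a.t_start_s - b.t_start_s) <= dt
            assert abs(a.t_end_s - b.t_end_s) <= dt
            assert abs(a.f_low_hz - b.f_low_hz) <= df
            assert abs(a.f_high_hz - b.f_high_hz) <= df

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_yolo(["0 0.5 0.5 0.2 0.2", "bogus line"], 5.0, RATE, 782, 513)
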