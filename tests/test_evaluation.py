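from __future__ import annotations

import pytest

from panofrac.annotations import Annotation, BoundingBox, REGION_SCHEME
from panofrac.detection import Detection
from panofrac.evaluation import (
    MatchResult,
    iou,
    match_detections,
    prf1,
    region_report,
)
from conftest import random_annotations
from oracle_utils import match_ref


def _pred(ann: Annotation, conf: float, jitter: float = 0.0) -> Detection:
    b = ann.box
    return Detection(
        BoundingBox(
            min(max(b.cx + jitter, b.w / 2), 1 - b.w / 2), b.cy, b.w, b.h
        ),
        ann.class_id,
        conf,
    )


class TestIou:
    def test_identical_boxes(self):
        b = BoundingBox(0.4, 0.6, 0.2, 0.3)
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        a = BoundingBox(0.2, 0.2, 0.1, 0.1)
        b = BoundingBox(0.8, 0.8, 0.1, 0.1)
        assert iou(a, b) == 0.0

    def test_half_side_offset_gives_one_third(self):
        # squares of side 0.4 offset by half a side: inter 0.08, union 0.24
        a = BoundingBox(0.3, 0.5, 0.4, 0.4)
        b = BoundingBox(0.5, 0.5, 0.4, 0.4)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric(self, rng):
        from conftest import random_box

        for _ in range(20):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0


class TestMatchDetections:
    def test_perfect_predictions(self, rng):
        truths = random_annotations(rng, 6)
        preds = [_pred(t, 0.9) for t in truths]
        m = match_detections(preds, truths)
        assert (m.tp, m.fp, m.fn) == (6, 0, 0)

    def test_no_predictions(self, rng):
        truths = random_annotations(rng, 5)
        m = match_detections([], truths)
        assert (m.tp, m.fp, m.fn) == (0, 0, 5)

    def test_matches_reference_matcher_on_random_instances(self, rng):
        for _ in range(20):
            truths = random_annotations(rng, 8, n_classes=2)
            preds = [
                _pred(t, float(rng.uniform(0.1, 1)), jitter=float(rng.normal(0, 0.05)))
                for t in truths[:6]
            ] + [
                Detection(t.box, t.class_id, float(rng.uniform(0.1, 1)))
                for t in random_annotations(rng, 4, n_classes=2)
            ]
            for fracture_level in (True, False):
                m = match_detections(preds, truths, 0.5, fracture_level)
                tp, fp, fn, pairs = match_ref(preds, truths, 0.5, fracture_level)
                assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
                assert {(pi, tj) for pi, tj, _ in m.matched_pairs} == pairs

    def test_duplicate_hits_ignored_at_fracture_level(self):
        truth = Annotation(BoundingBox(0.5, 0.5, 0.2, 0.2), 0, source_id=0)
        dup = [
            Detection(BoundingBox(0.5, 0.5, 0.2, 0.2), 0, 0.9),
            Detection(BoundingBox(0.51, 0.5, 0.2, 0.2), 0, 0.8),
        ]
        frak = match_detections(dup, [truth], fracture_level=True)
        boxl = match_detections(dup, [truth], fracture_level=False)
        assert (frak.tp, frak.fp) == (1, 0)
        assert (boxl.tp, boxl.fp) == (1, 1)

    def test_raising_threshold_never_increases_tp(self, rng):
        truths = random_annotations(rng, 8)
        preds = [
            _pred(t, float(rng.uniform()), jitter=float(rng.normal(0, 0.04)))
            for t in truths
        ]
        tps = [
            match_detections(preds, truths, thr).tp
            for thr in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert tps == sorted(tps, reverse=True)

    def test_threshold_one_requires_exact_coincidence(self, rng):
        truths = random_annotations(rng, 5)
        preds = [_pred(t, 0.9) for t in truths[:2]] + [
            _pred(t, 0.9, jitter=0.02) for t in truths[2:]
        ]
        m = match_detections(preds, truths, 1.0)
        assert m.tp == 2

    def test_class_agnostic_mode_ignores_labels(self):
        truth = Annotation(BoundingBox(0.5, 0.5, 0.2, 0.2), 3, source_id=0)
        pred = Detection(BoundingBox(0.5, 0.5, 0.2, 0.2), 1, 0.9)
        assert match_detections([pred], [truth]).tp == 0
        assert match_detections([pred], [truth], class_agnostic=True).tp == 1

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_threshold=1.2)


class TestPrf1:
    def test_perfect_counts(self):
        assert prf1(5, 0, 0) == (1.0, 1.0, 1.0)

    def test_zero_tp_convention(self):
        assert prf1(0, 3, 4) == (0.0, 0.0, 0.0)
        assert prf1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(30):
            tp, fp, fn = (int(v) for v in rng.integers(0, 40, 3))
            p, r, f = prf1(tp, fp, fn)
            assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f <= 1.0
            if p > 0 and r > 0:
                assert f == pytest.approx(2 * p * r / (p + r))
                assert min(p, r) <= f <= max(p, r)

    def test_harmonic_mean_of_moderate_scores(self):
        # counts giving precision 0.570 and recall 0.714 to 3 decimals
        p, r, f = prf1(570, 430, 228)
        assert p == pytest.approx(0.570, abs=5e-4)
        assert r == pytest.approx(0.714, abs=5e-4)
        assert f == pytest.approx(0.634, abs=1e-3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf1(-1, 0, 0)


class TestRegionReport:
    def test_all_matched_means_no_undiagnosed(self, rng):
        truths = random_annotations(rng, 6)
        preds = [_pred(t, 0.9) for t in truths]
        m = match_detections(preds, truths)
        rep = region_report(m, preds, truths, REGION_SCHEME)
        assert all(v == 0 for v in rep.undiagnosed.values())
        assert sum(rep.diagnosed.values()) == m.tp

    def test_single_unmatched_condyle(self):
        cid = REGION_SCHEME.labels.index("condyle")
        truths = [Annotation(BoundingBox(0.5, 0.5, 0.1, 0.1), cid, source_id=0)]
        m = match_detections([], truths)
        rep = region_report(m, [], truths, REGION_SCHEME)
        assert rep.undiagnosed["condyle"] == 1
        assert sum(rep.undiagnosed.values()) == 1

    def test_per_label_counts_sum_to_global(self, rng):
        for _ in range(10):
            truths = random_annotations(rng, 10)
            preds = [
                _pred(t, float(rng.uniform()), jitter=float(rng.normal(0, 0.06)))
                for t in truths[: int(rng.integers(3, 10))]
            ]
            m = match_detections(preds, truths)
            rep = region_report(m, preds, truths, REGION_SCHEME)
            assert sum(rep.diagnosed.values()) == m.tp
            assert sum(rep.undiagnosed.values()) == m.fn

    def test_scheme_mismatch_rejected(self):
        from panofrac.annotations import SHAPE_SCHEME

        truths = [Annotation(BoundingBox(0.5, 0.5, 0.1, 0.1), 5, source_id=0)]
        with pytest.raises(ValueError):
            region_report(
                match_detections([], truths), [], truths, SHAPE_SCHEME
            )

    def test_match_result_consistency_enforced(self):
        with pytest.raises(ValueError):
            MatchResult(tp=2, fp=0, fn=0, matched_pairs=())
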