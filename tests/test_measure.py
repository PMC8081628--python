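import numpy as np
import pytest

from kneemetry import landmarks as lm
from kneemetry import measure
from kneemetry.errors import DegenerateMeasurementError
from kneemetry.imageio_roi import GrayImage
from kneemetry.phantom import PhantomSpec, PhantomTruth, make_phantom


def landmark_set_from_truth(truth: PhantomTruth) -> lm.LandmarkSet:
    tip = lambda p: lm.TipTop(p, 0, 5)  # noqa: E731
    sl, sr = sorted([truth.spine_lateral, truth.spine_medial],
                    key=lambda p: p.x)
    return lm.LandmarkSet(
        up_left=truth.up_left, up_right=truth.up_right,
        femur_axis_x=truth.femur_axis_x,
        spine_left=tip(sl), spine_right=tip(sr),
        plateau_left=truth.plateau_left, plateau_right=truth.plateau_right,
        baseline=truth.baseline,
        condyle_baseline=lm.Line(truth.up_left, truth.up_right),
    )


class TestPointLineDistance:
    def test_point_on_line(self):
        line = lm.Line(lm.Point(0, 0.0), lm.Point(10, 10.0))
        assert measure.point_line_distance(lm.Point(5, 5.0), line) == 0.0

    def test_horizontal_line(self):
        line = lm.Line(lm.Point(0, 0.0), lm.Point(10, 0.0))
        assert measure.point_line_distance(lm.Point(3, 5.0), line) == 5.0

    def test_diagonal(self):
        line = lm.Line(lm.Point(0, 1.0), lm.Point(1, 0.0))
        d = measure.point_line_distance(lm.Point(0, 0.0), line)
        assert d == pytest.approx(1 / np.sqrt(2))


class TestComputeMeasurement:
    def test_worked_ratio_from_truth_landmarks(self, worked_phantom):
        _, _, truth = worked_phantom
        ls = landmark_set_from_truth(truth)
        m = measure.compute_measurement(ls, truth.laterality)
        assert m.ratio == pytest.approx(1.325, abs=1e-9)

    def test_equal_distances_give_unity(self):
        p = lm.Point
        ls = lm.LandmarkSet(
            up_left=p(50, 140.0), up_right=p(150, 140.0), femur_axis_x=100.0,
            spine_left=lm.TipTop(p(90, 140.0), 0, 3),
            spine_right=lm.TipTop(p(110, 140.0), 0, 3),
            plateau_left=p(10, 100.0), plateau_right=p(190, 100.0),
            baseline=lm.Line(p(10, 100.0), p(190, 100.0)),
            condyle_baseline=lm.Line(p(50, 140.0), p(150, 140.0)),
        )
        m = measure.compute_measurement(ls, "lateral_left")
        assert m.ratio == pytest.approx(1.0)

    def test_vertical_distances_to_horizontal_baseline(self):
        p = lm.Point
        ls = lm.LandmarkSet(
            up_left=p(50, 140.0), up_right=p(150, 138.0), femur_axis_x=100.0,
            spine_left=lm.TipTop(p(120, 130.0), 0, 3),
            spine_right=lm.TipTop(p(130, 128.0), 0, 3),
            plateau_left=p(10, 100.0), plateau_right=p(190, 100.0),
            baseline=lm.Line(p(10, 100.0), p(190, 100.0)),
            condyle_baseline=lm.Line(p(50, 140.0), p(150, 138.0)),
        )
        m = measure.compute_measurement(ls, "lateral_left", spacing_mm=0.2)
        assert m.ljsd_px == pytest.approx(40.0)
        assert m.hlts_px == pytest.approx(30.0)
        assert m.ratio == pytest.approx(40.0 / 30.0)
        assert m.ljsd_mm == pytest.approx(8.0)

    def test_degenerate_hlts_rejected(self):
        p = lm.Point
        ls = lm.LandmarkSet(
            up_left=p(50, 140.0), up_right=p(150, 140.0), femur_axis_x=100.0,
            spine_left=lm.TipTop(p(90, 100.2), 0, 3),
            spine_right=lm.TipTop(p(110, 100.2), 0, 3),
            plateau_left=p(10, 100.0), plateau_right=p(190, 100.0),
            baseline=lm.Line(p(10, 100.0), p(190, 100.0)),
            condyle_baseline=lm.Line(p(50, 140.0), p(150, 140.0)),
        )
        with pytest.raises(DegenerateMeasurementError):
            measure.compute_measurement(ls, "lateral_left")


class TestRunPipeline:
    def test_default_phantom_recovers_ratio(self, default_phantom):
        _, img, truth = default_phantom
        rep = measure.run_pipeline(img, laterality=truth.laterality)
        assert rep.status == "success"
        assert abs(rep.measurement.ratio - truth.ratio) / truth.ratio <= 0.10
        assert (rep.measurement is not None) == rep.success

    def test_constant_image_fails_detection(self):
        img = GrayImage(np.full((256, 256), 80, dtype=np.uint8))
        rep = measure.run_pipeline(img)
        assert rep.status == "fail_detection"
        assert rep.measurement is None

    def test_spineless_phantom_fails_at_spines(self):
        spec = PhantomSpec()
        img, truth = make_phantom(spec, 1, _render_spines=False)
        rep = measure.run_pipeline(img, laterality=truth.laterality)
        assert rep.status == "fail_spines"

    def test_landmarks_reported_in_full_image_frame(self, default_phantom):
        _, img, truth = default_phantom
        rep = measure.run_pipeline(img, laterality=truth.laterality)
        assert abs(rep.landmarks.up_left.x - truth.up_left.x) <= 5
        assert abs(rep.landmarks.up_left.h - truth.up_left.h) <= 3

    def test_report_json_stable_fields(self, default_phantom):
        _, img, truth = default_phantom
        rep = measure.run_pipeline(img, laterality=truth.laterality)
        d = rep.to_dict()
        for key in ("source_id", "status", "detection", "enhancement",
                    "canny_params_used", "landmarks", "measurement"):
            assert key in d

    def test_ratio_invariant_to_uniform_rescaling(self):
        base = PhantomSpec()
        s = 1.5
        scaled = PhantomSpec(
            width=int(base.width * s), height=int(base.height * s),
            baseline_height=base.baseline_height * s,
            plateau_halfwidth=base.plateau_halfwidth * s,
            shaft_halfwidth=base.shaft_halfwidth * s,
            condyle_radius_lat=base.condyle_radius_lat * s,
            condyle_radius_med=base.condyle_radius_med * s,
            notch_depth=base.notch_depth * s,
            ljsd_true=base.ljsd_true * s, hlts_true=base.hlts_true * s,
            hmts_true=base.hmts_true * s,
            spine_offset_lat=base.spine_offset_lat * s,
            spine_offset_med=base.spine_offset_med * s,
            spine_halfwidth=base.spine_halfwidth * s,
        )
        img1, t1 = make_phantom(base, 1)
        img2, t2 = make_phantom(scaled, 1)
        r1 = measure.run_pipeline(img1, laterality=t1.laterality)
        r2 = measure.run_pipeline(img2, laterality=t2.laterality)
        assert r1.success and r2.success
        assert abs(r1.measurement.ratio - r2.measurement.ratio) <= (
            0.03 * r1.measurement.ratio)


class TestEvaluateSuite:
    def make_reports(self, ratios):
        reports = []
        for r in ratios:
            rep = measure.Report(source_id="x", status="success")
            rep.measurement = measure.Measurement(
                ljsd_px=r * 10, hlts_px=10.0, ratio=r,
                laterality="lateral_left")
            reports.append(rep)
        return reports

    def test_exact_recovery(self):
        truths = [{"truth": {"ratio": r}} for r in (0.5, 0.8, 1.2)]
        summary = measure.evaluate_suite(
            truths, self.make_reports([0.5, 0.8, 1.2]))
        assert summary.success_rate == 1.0
        assert summary.bias == 0.0
        assert summary.rmse == 0.0
        assert summary.p_value == 1.0  # zero-variance differences
        assert summary.warnings

    def test_constant_offset(self):
        truths = [{"truth": {"ratio": r}} for r in (1.0, 1.5, 2.0)]
        summary = measure.evaluate_suite(
            truths, self.make_reports([1.1, 1.6, 2.1]))
        assert summary.bias == pytest.approx(0.1)
        assert summary.rmse == pytest.approx(0.1)

    def test_paired_t_statistic_hand_computed(self):
        """Pairs (1,1.1), (2,2.2), (3,2.9): diffs {0.1, 0.2, -0.1}, mean
        0.0667, sd 0.1528 => t = 0.7559 (hand-checked)."""
        truths = [{"truth": {"ratio": r}} for r in (1.0, 2.0, 3.0)]
        summary = measure.evaluate_suite(
            truths, self.make_reports([1.1, 2.2, 2.9]))
        assert summary.t_stat == pytest.approx(0.7559, abs=1e-3)

    def test_out_of_tolerance_counts_as_failure(self):
        truths = [{"truth": {"ratio": 1.0}}, {"truth": {"ratio": 1.0}}]
        summary = measure.evaluate_suite(
            truths, self.make_reports([1.0, 1.5]), success_tol=0.15)
        assert summary.n_success == 1

    def test_too_few_successes_omit_stats(self):
        truths = [{"truth": {"ratio": 1.0}}]
        summary = measure.evaluate_suite(truths, self.make_reports([1.0]))
        assert summary.mean_ratio is None
        assert summary.warnings
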