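"""LJSD / HLTS measurement, pipeline orchestration and suite evaluation.

LJSD (lateral joint space distance) is the perpendicular distance from the
lateral femoral condyle feature point to the tibial-plateau baseline; HLTS
(height of the lateral tibial spine) the perpendicular distance from the
lateral spine tip top to the same baseline.  Their ratio is the final output:
it is markedly elevated in knees with a discoid lateral meniscus.

`run_pipeline` chains detection -> crop -> enhancement (with the low-contrast
retry) -> Canny parameter-group retry -> landmark stages -> measurement, and
never raises: every failure is captured in the Report status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import edgemap, enhance, landmarks as lm
from .config import RunConfig, DEFAULT_CONFIG
from .errors import (
    DegenerateMeasurementError,
    DetectionFailure,
    LandmarkFailure,
)
from .imageio_roi import (
    BBox,
    DetectionResult,
    GrayImage,
    Laterality,
    LateralSide,
    detect_joint_roi,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Measurement:
    ljsd_px: float
    hlts_px: float
    ratio: float
    laterality: str
    ljsd_mm: Optional[float] = None
    hlts_mm: Optional[float] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Report:
    source_id: str
    status: str  # success | fail_detection | fail_pofb | fail_condyles |
    #              fail_spines | fail_plateau | fail_baseline
    detection: Optional[DetectionResult] = None
    enhancement: Optional[enhance.EnhancementTrace] = None
    canny_params_used: Optional[Tuple[float, float]] = None
    landmarks: Optional[lm.LandmarkSet] = None
    measurement: Optional[Measurement] = None
    warnings: List[str] = dataclasses.field(default_factory=list)
    image_height: int = 0
    # femur-boundary polyline in full-image raster coordinates (overlay aid)
    boundary_xy: Optional[List[Tuple[int, float]]] = None

    @property
    def success(self) -> bool:
        return self.status == "success"

    def to_dict(self) -> dict:
        d = {
            "source_id": self.source_id,
            "status": self.status,
            "warnings": list(self.warnings),
            "canny_params_used": self.canny_params_used,
        }
        if self.detection is not None:
            d["detection"] = {
                "bbox": self.detection.bbox.to_dict(),
                "confidence": self.detection.confidence,
                "method": self.detection.method,
            }
        if self.enhancement is not None:
            d["enhancement"] = {
                "steps_applied": self.enhancement.steps_applied,
                "edge_count_first_pass": self.enhancement.edge_count_first_pass,
                "retried": self.enhancement.retried,
                "params": self.enhancement.params,
            }
        if self.landmarks is not None:
            H = self.image_height

            def pt(p: lm.Point):
                x, y = p.to_raster(H)
                return {"x": x, "y": y}

            lms = self.landmarks
            d["landmarks"] = {
                "up_left": pt(lms.up_left),
                "up_right": pt(lms.up_right),
                "femur_axis_x": lms.femur_axis_x,
                "spine_left": pt(lms.spine_left.point),
                "spine_right": pt(lms.spine_right.point),
                "plateau_left": pt(lms.plateau_left),
                "plateau_right": pt(lms.plateau_right),
                "baseline": [pt(lms.baseline.p1), pt(lms.baseline.p2)],
            }
        if self.measurement is not None:
            d["measurement"] = self.measurement.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclasses.dataclass
class EvalSummary:
    n: int
    n_success: int
    success_rate: float
    mean_ratio: Optional[float] = None
    sd_ratio: Optional[float] = None
    bias: Optional[float] = None
    rmse: Optional[float] = None
    t_stat: Optional[float] = None
    p_value: Optional[float] = None
    warnings: List[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def point_line_distance(p: lm.Point, line: lm.Line) -> float:
    """Perpendicular Euclidean distance from a point to an (infinite) line."""
    dx = line.p2.x - line.p1.x
    dh = line.p2.h - line.p1.h
    num = abs(dh * (p.x - line.p1.x) - dx * (p.h - line.p1.h))
    return num / math.hypot(dx, dh)


def compute_measurement(
    landmark_set: lm.LandmarkSet,
    laterality: Laterality | LateralSide | str,
    spacing_mm: Optional[float] = None,
) -> Measurement:
    """Measure LJSD, HLTS and their ratio from a complete landmark set.

    The laterality selects which condyle point and spine tip are the lateral
    ones (lateral_left -> up_left and spine_left).
    """
    side = laterality.value if isinstance(laterality, Laterality) else laterality
    side = LateralSide(side)
    if side is LateralSide.lateral_left:
        condyle, spine = landmark_set.up_left, landmark_set.spine_left.point
    else:
        condyle, spine = landmark_set.up_right, landmark_set.spine_right.point
    ljsd = point_line_distance(condyle, landmark_set.baseline)
    hlts = point_line_distance(spine, landmark_set.baseline)
    if hlts <= 0.5:
        raise DegenerateMeasurementError(
            f"HLTS of {hlts:.3f} px is below the measurable limit"
        )
    return Measurement(
        ljsd_px=ljsd,
        hlts_px=hlts,
        ratio=ljsd / hlts,
        laterality=side.value,
        ljsd_mm=ljsd * spacing_mm if spacing_mm else None,
        hlts_mm=hlts * spacing_mm if spacing_mm else None,
    )


# ---------------------------------------------------------------------------
# sub-pixel landmark refinement
# ---------------------------------------------------------------------------

def _refine_height(px: np.ndarray, p: lm.Point, search: int = 2,
                   curvature: float = 0.0) -> lm.Point:
    """Refine a landmark height to sub-pixel precision.

    The vertical intensity-gradient profile around the detected edge pixel is
    interpolated with a parabola (the gradient of a blurred step is Gaussian,
    so its peak marks the boundary).  For landmarks on curved contours the
    blurred iso-contour is additionally displaced toward its centre of
    curvature by ~sigma^2 * |a| (level-set erosion of a smooth extremum);
    with the local blur sigma estimated from the gradient width and the
    profile curvature ``a`` supplied by the landmark stage, that bias is
    subtracted out.
    """
    H, W = px.shape
    x = int(round(p.x))
    y0 = int(round((H - 1) - p.h))
    if not (0 <= x < W):
        return p
    lo, hi = max(1, y0 - search), min(H - 2, y0 + search)
    if hi < lo:
        return p
    ys = np.arange(lo, hi + 1)
    col = px[:, x].astype(np.float64)
    g = np.abs(col[ys + 1] - col[ys - 1]) / 2.0
    k = int(np.argmax(g))
    yb = int(ys[k])
    wlo, whi = max(1, yb - 4), min(H - 2, yb + 4)
    yw = np.arange(wlo, whi + 1)
    gw = np.abs(col[yw + 1] - col[yw - 1]) / 2.0
    gw = gw - gw.min()
    y_ref = float(yb)
    sigma2 = 0.0
    if gw.sum() > 1e-9:
        mu = float((gw * yw).sum() / gw.sum())
        sigma2 = float((gw * (yw - mu) ** 2).sum() / gw.sum())
    # peak position from the local 3-point parabola (robust to gradient
    # energy of nearby structures entering the wider sigma window)
    if 1 <= yb < H - 2:
        gm = abs(col[yb] - col[yb - 2]) / 2.0
        gp = abs(col[yb + 2] - col[yb]) / 2.0
        g0 = abs(col[yb + 1] - col[yb - 1]) / 2.0
        denom = gm - 2.0 * g0 + gp
        if denom < -1e-9:
            delta = 0.5 * (gm - gp) / denom
            y_ref = yb + float(np.clip(delta, -1.0, 1.0))
    h_ref = (H - 1) - y_ref
    if curvature != 0.0 and sigma2 > 0.0:
        # the gradient ridge of a blurred curved edge is displaced toward the
        # centre of curvature by ~sigma^2 * kappa (= 2 sigma^2 |a|)
        h_ref += float(np.clip(-2.0 * sigma2 * curvature, -1.5, 1.5))
    return lm.Point(p.x, float(h_ref))


def _refine_condyle(px: np.ndarray, cf, p: lm.Point) -> lm.Point:
    """Condyle bottom: parabola vertex of the boundary profile (the arc is
    nearly flat, so the raw pixel minimum wanders by several columns), then
    gradient-based height refinement at the vertex column."""
    x0 = int(round(p.x))
    lo = np.searchsorted(cf.xs, x0 - 8, side="left")
    hi = np.searchsorted(cf.xs, x0 + 8, side="right")
    xs, hs = cf.xs[lo:hi].astype(float), cf.hs[lo:hi]
    if xs.size < 5:
        return _refine_height(px, p)
    a, b, c = np.polyfit(xs - x0, hs, 2)
    if a <= 1e-6:
        return _refine_height(px, p, curvature=float(a))
    xv = float(np.clip(-b / (2 * a), -8.0, 8.0))
    hv = a * xv ** 2 + b * xv + c
    ref = _refine_height(px, lm.Point(x0 + xv, hv), curvature=float(a))
    return lm.Point(x0 + xv, ref.h)


def _refine_corner(px: np.ndarray, cf, p: lm.Point, inward: int) -> lm.Point:
    """Plateau corner: fit the plateau line on the inboard side (the steep
    drop's pixel staircase is biased, so it is never fitted), locate the
    column where the profile departs from that line, and anchor the absolute
    height with a sub-pixel gradient probe on the clean plateau edge."""
    xi = int(round(p.x))
    rel = (cf.xs.astype(float) - xi) * inward
    inner = (rel >= 4) & (rel <= 16)
    if inner.sum() < 5:
        return _refine_height(px, p)
    xs_in, hs_in = cf.xs[inner].astype(float), cf.hs[inner]
    s, b = np.polyfit(xs_in, hs_in, 1)
    resid = np.abs(hs_in - (s * xs_in + b))
    good = resid <= 1.5  # the tangent may sit mid-corner; trim leaked pixels
    if 5 <= good.sum() < xs_in.size:
        s, b = np.polyfit(xs_in[good], hs_in[good], 1)
    if abs(s) > 0.35:  # not a near-horizontal plateau; bail out
        return _refine_height(px, p)

    # calibrate the line's absolute offset with a sub-pixel gradient probe
    probe_x = None
    for r in (6, 8, 10):
        if cf.has(xi + r * inward):
            probe_x = xi + r * inward
            break
    if probe_x is None:
        return _refine_height(px, p)
    probe = _refine_height(px, lm.Point(float(probe_x), s * probe_x + b))
    if abs(probe.h - (s * probe_x + b)) <= 1.0:
        b = probe.h - s * probe_x

    # fit the steep drop on clearly off-plateau pixels only (the rounded
    # corner region between the two lines is excluded by construction)
    steep = (rel >= -12) & (rel <= 3) & (
        (cf.hs - (s * cf.xs.astype(float) + b)) < -2.5)
    if steep.sum() >= 3:
        s2, b2 = np.polyfit(cf.xs[steep].astype(float), cf.hs[steep], 1)
        if abs(s2 - s) > 1.0:
            xc = (b2 - b) / (s - s2)
            hc = s * xc + b
            if abs(xc - xi) <= 6.0 and abs(hc - p.h) <= 6.0:
                return lm.Point(float(xc), float(hc))
    # no usable drop line: take the outermost column still on the plateau,
    # walking outward from just inboard of the tangent
    corner_x = float(xi)
    for r in range(3, -9, -1):
        x = xi + r * inward
        if not cf.has(x):
            continue
        if abs(cf.value(x) - (s * x + b)) <= 0.8:
            corner_x = float(x)
        elif r < 3:
            break
    return lm.Point(corner_x, float(s * corner_x + b))


def _refine_landmarks(px: np.ndarray, ls: lm.LandmarkSet) -> lm.LandmarkSet:
    ctx = ls.refine_ctx or {}
    bd_cf = ctx.get("boundary_profile")
    if bd_cf is not None:
        up_left = _refine_condyle(px, bd_cf, ls.up_left)
        up_right = _refine_condyle(px, bd_cf, ls.up_right)
    else:
        up_left = _refine_height(px, ls.up_left)
        up_right = _refine_height(px, ls.up_right)
    sl = lm.TipTop(
        _refine_height(px, ls.spine_left.point,
                       curvature=ls.spine_left.curvature),
        ls.spine_left.edge_id, ls.spine_left.window_K, ls.spine_left.curvature)
    sr = lm.TipTop(
        _refine_height(px, ls.spine_right.point,
                       curvature=ls.spine_right.curvature),
        ls.spine_right.edge_id, ls.spine_right.window_K,
        ls.spine_right.curvature)
    cl, cr = ctx.get("corner_left_cf"), ctx.get("corner_right_cf")
    pl = (_refine_corner(px, cl, ls.plateau_left, +1) if cl is not None
          else _refine_height(px, ls.plateau_left))
    pr = (_refine_corner(px, cr, ls.plateau_right, -1) if cr is not None
          else _refine_height(px, ls.plateau_right))
    return lm.LandmarkSet(
        up_left=up_left,
        up_right=up_right,
        femur_axis_x=(up_left.x + up_right.x) / 2.0,
        spine_left=sl,
        spine_right=sr,
        plateau_left=pl,
        plateau_right=pr,
        baseline=lm.Line(pl, pr),
        condyle_baseline=lm.Line(up_left, up_right),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _shift_point(p: lm.Point, dx: float, dh: float) -> lm.Point:
    return lm.Point(p.x + dx, p.h + dh)


def _landmarks_to_full_image(
    ls: lm.LandmarkSet, bbox: BBox, crop_h: int, full_h: int
) -> lm.LandmarkSet:
    """Map crop-frame landmarks (height coords) into the full-image frame."""
    dx = float(bbox.x0)
    # crop h -> raster y -> full raster y -> full h
    dh = float((full_h - 1) - bbox.y0 - (crop_h - 1))

    def mv(p: lm.Point) -> lm.Point:
        return _shift_point(p, dx, dh)

    return lm.LandmarkSet(
        up_left=mv(ls.up_left),
        up_right=mv(ls.up_right),
        femur_axis_x=ls.femur_axis_x + dx,
        spine_left=lm.TipTop(mv(ls.spine_left.point), ls.spine_left.edge_id,
                             ls.spine_left.window_K),
        spine_right=lm.TipTop(mv(ls.spine_right.point), ls.spine_right.edge_id,
                              ls.spine_right.window_K),
        plateau_left=mv(ls.plateau_left),
        plateau_right=mv(ls.plateau_right),
        baseline=lm.Line(mv(ls.baseline.p1), mv(ls.baseline.p2)),
        condyle_baseline=lm.Line(mv(ls.condyle_baseline.p1),
                                 mv(ls.condyle_baseline.p2)),
    )


def _attempt_landmarks(
    edges: edgemap.EdgeSet,
    roi_width: int,
    config: RunConfig,
    warn_sink: list,
) -> lm.LandmarkSet:
    boundary = lm.find_pofb(
        edges,
        roi_width,
        span_frac=config.landmarks_pofb_span_frac,
        aspect=config.landmarks_pofb_aspect,
        gap_frac=config.landmarks_pofb_gap_frac,
        min_span_frac=config.landmarks_pofb_min_span_frac,
    )
    up_left, up_right, axis_x = lm.condyle_points(
        boundary, smooth_window=config.landmarks_smooth_window
    )
    condyle_baseline = lm.Line(up_left, up_right)
    d = up_right.x - up_left.x
    K = max(3, int(round(config.landmarks_K_frac * d)))
    tips = lm.find_tip_tops(
        edges, boundary, K, exclude_edge_ids=boundary.member_edge_ids
    )
    spine_left, spine_right = lm.select_spines(
        tips, up_left, up_right, axis_x,
        sep_min_frac=config.landmarks_sep_min_frac,
        sep_max_frac=config.landmarks_sep_max_frac,
        sym_tol=config.landmarks_sym_tol,
    )
    plateau_left, corner_left_cf = lm.plateau_border_point(
        edges, "left", boundary, condyle_baseline, axis_x,
        steep_deg=config.landmarks_steep_deg,
        stop_deg=config.landmarks_stop_deg,
        cap_frac=config.landmarks_shift_cap_frac,
        warn_sink=warn_sink,
        return_edge=True,
    )
    plateau_right, corner_right_cf = lm.plateau_border_point(
        edges, "right", boundary, condyle_baseline, axis_x,
        steep_deg=config.landmarks_steep_deg,
        stop_deg=config.landmarks_stop_deg,
        cap_frac=config.landmarks_shift_cap_frac,
        warn_sink=warn_sink,
        return_edge=True,
    )
    baseline = lm.plateau_baseline(plateau_left, plateau_right)
    refine_ctx = {
        "boundary_profile": boundary.profile,
        "corner_left_cf": corner_left_cf,
        "corner_right_cf": corner_right_cf,
    }
    return lm.LandmarkSet(
        refine_ctx=refine_ctx,
        up_left=up_left,
        up_right=up_right,
        femur_axis_x=axis_x,
        spine_left=spine_left,
        spine_right=spine_right,
        plateau_left=plateau_left,
        plateau_right=plateau_right,
        baseline=baseline,
        condyle_baseline=condyle_baseline,
    )


def run_pipeline(
    image: GrayImage,
    config: Optional[RunConfig] = None,
    laterality: Laterality | LateralSide | str = LateralSide.lateral_left,
    provided_bbox: Optional[BBox] = None,
    detector=None,
) -> Report:
    """Run the full two-phase measurement pipeline on one radiograph.

    Never raises; all failures are recorded in ``Report.status``.  Landmark
    coordinates in the report are mapped back to full-image coordinates.
    """
    config = config or DEFAULT_CONFIG
    side = laterality if isinstance(laterality, Laterality) else Laterality(
        LateralSide(laterality), "flag"
    )
    report = Report(source_id=getattr(image, "source_id", ""), status="fail_detection",
                    image_height=image.height)
    try:
        det = detect_joint_roi(
            image, provided_bbox, detector, margin_frac=config.roi_margin_frac
        )
    except DetectionFailure as exc:
        report.warnings.append(str(exc))
        return report
    report.detection = det
    bbox = det.bbox
    crop = image.pixels[bbox.y0:bbox.y1, bbox.x0:bbox.x1]
    crop_h = crop.shape[0]

    enhanced, trace = enhance.enhance_with_retry(crop, config)
    report.enhancement = trace
    report.warnings.extend(trace.warnings)

    last_stage = "pofb"
    result = None
    for edges in edgemap.detect_edges_with_retry(
        enhanced,
        groups=config.edges_canny_groups,
        min_len=config.edges_min_len,
        max_vertical_run=config.edges_max_vertical_run,
    ):
        try:
            ls = _attempt_landmarks(edges, crop.shape[1], config, report.warnings)
            if config.measure_subpixel:
                ls = _refine_landmarks(enhanced, ls)
            meas = compute_measurement(ls, side, image.spacing_mm)
            result = (ls, meas, edges.canny_params)
            break
        except LandmarkFailure as exc:
            last_stage = exc.stage
            report.canny_params_used = edges.canny_params
            continue
        except DegenerateMeasurementError as exc:
            last_stage = "baseline"
            report.warnings.append(str(exc))
            report.canny_params_used = edges.canny_params
            continue

    if result is None:
        report.status = f"fail_{last_stage}"
        return report

    ls, meas, params = result
    report.canny_params_used = params
    bd = (ls.refine_ctx or {}).get("boundary_profile")
    if bd is not None:
        report.boundary_xy = [
            (int(x) + bbox.x0, float((crop_h - 1) - hh + bbox.y0))
            for x, hh in zip(bd.xs.tolist(), bd.hs.tolist())
        ]
    report.landmarks = _landmarks_to_full_image(ls, bbox, crop_h, image.height)
    report.measurement = meas
    report.status = "success"
    return report


# ---------------------------------------------------------------------------
# suite evaluation
# ---------------------------------------------------------------------------

def _truth_ratio(entry) -> float:
    if isinstance(entry, dict):
        truth = entry.get("truth", entry)
        return float(truth["ratio"] if isinstance(truth, dict) else truth.ratio)
    return float(entry.ratio if hasattr(entry, "ratio") else entry)


def evaluate_suite(
    manifest: Sequence,
    reports: Sequence[Report],
    success_tol: float = 0.15,
) -> EvalSummary:
    """Score a suite of reports against ground truth.

    An image counts as a success iff its pipeline status is success *and* the
    measured ratio is within ``success_tol`` relative error of truth (mere
    completion with a wild value is not clinically usable).  Mean/SD, bias and
    RMSE are computed over the successful measurements; measured-vs-truth
    ratios are compared with a paired-samples t test (two-tailed).
    """
    entries = manifest["entries"] if isinstance(manifest, dict) else manifest
    if len(entries) != len(reports):
        raise ValueError("manifest entries and reports must align 1:1")
    truths, measured = [], []
    n_success = 0
    for entry, rep in zip(entries, reports):
        t = _truth_ratio(entry)
        if rep.success and rep.measurement is not None:
            m = rep.measurement.ratio
            if t > 0 and abs(m - t) / t <= success_tol:
                n_success += 1
                truths.append(t)
                measured.append(m)
    n = len(entries)
    summary = EvalSummary(
        n=n, n_success=n_success,
        success_rate=n_success / n if n else 0.0,
    )
    if n_success < 2:
        summary.warnings.append(
            "fewer than 2 successes; summary statistics omitted"
        )
        return summary
    meas = np.array(measured)
    tr = np.array(truths)
    diffs = meas - tr
    summary.mean_ratio = float(meas.mean())
    summary.sd_ratio = float(meas.std(ddof=1))
    summary.bias = float(diffs.mean())
    summary.rmse = float(np.sqrt((diffs ** 2).mean()))
    if np.allclose(diffs.std(ddof=1), 0.0):
        summary.t_stat = 0.0
        summary.p_value = 1.0
        summary.warnings.append(
            "zero variance of paired differences; p reported as 1.0"
        )
    else:
        from scipy import stats

        t_stat, p_val = stats.ttest_rel(meas, tr)
        summary.t_stat = float(t_stat)
        summary.p_value = float(p_val)
    return summary
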