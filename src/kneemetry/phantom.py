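"""Synthetic AP knee-radiograph phantoms with exact ground-truth landmarks.

The phantom is a 2-D silhouette model (filled analytic regions plus Gaussian
blur), not a projected 3-D bone: the measurement algorithm consumes only 2-D
edges, so the generator needs to reproduce the *edge geometry* of an AP knee:

* a bright femur whose lower border is two convex condylar arcs meeting at an
  intercondylar notch, flaring wider than the shaft;
* a darker joint-space band;
* a bright tibia whose upper border is a near-horizontal plateau carrying two
  smooth spine bumps, dropping steeply at the plateau corners into the shaft;
* a soft-tissue envelope, optional bone-texture stripes, Gaussian and
  salt-and-pepper noise, and global contrast compression.

Ground truth (condyle points, spine tips, plateau corners, baseline, LJSD,
HLTS, ratio, joint box) is defined *analytically from the spec*, never
re-detected, so it is independent of the algorithm under test.  Heights obey
the same y-up convention as the measurement code; geometry is built in a
canonical lateral-on-left frame and mirrored for right-lateral images.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .imageio_roi import BBox, GrayImage, LateralSide
from .landmarks import Line, Point

# ---------------------------------------------------------------------------
# fixed anatomical proportions of the silhouette model (pixels or fractions)
# ---------------------------------------------------------------------------

CONDYLE_SEP_FRAC = 1.3     # condylar distance d / plateau_halfwidth
ARC_EXTENT_FRAC = 0.55     # half-extent of each condylar arc / its radius
FLANK_RISE_FRAC = 0.35     # outer-flank rise of the femur border / mean radius
FLANK_RUN = 24             # columns of the outer flank
FLARE_DEPTH = 40           # femoral flare block height above the flank top
CORNER_DROP_SLOPE = 4.0    # px of drop per column beyond the plateau corner
CORNER_RUN = 14            # columns of the steep corner drop
TIBIA_FLARE_DEPTH = 40     # tibial flare block height below the corner drop
SOFT_MARGIN = 18           # soft-tissue envelope beyond the bone silhouette
MEDIAL_EXTRA_LJSD = 3.0    # medial condyle sits slightly higher than lateral
STRIPE_AMPLITUDE = 8.0     # bone-texture stripe amplitude (intensity)
STRIPE_PERIOD = 9.0        # stripe period in columns

RATIO_TRUNC = (0.3, 1.8)   # anatomically renderable ratio range


# ---------------------------------------------------------------------------
# spec and truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomSpec:
    """Generative parameters of one phantom (pixels unless noted).

    ``spine_offset_lat``/``spine_offset_med`` are signed offsets from the
    femoral axis in the canonical lateral-on-left frame (lateral negative);
    ``spine_halfwidth`` is the Gaussian half-width (sigma) of a spine bump.
    ``context_margin`` documents the non-joint margin fraction the canvas was
    sized for (used by `sample_spec`); the joint is always rendered centered.
    """

    width: int = 512
    height: int = 512
    laterality: str = "lateral_left"
    baseline_height: float = 245.0
    baseline_tilt: float = 0.0       # degrees, |tilt| <= 5
    plateau_halfwidth: float = 110.0
    shaft_halfwidth: float = 45.0
    condyle_radius_lat: float = 85.0
    condyle_radius_med: float = 85.0
    notch_depth: float = 26.0
    ljsd_true: float = 28.0
    hlts_true: float = 40.0
    hmts_true: float = 32.0
    spine_offset_lat: float = -14.0
    spine_offset_med: float = 16.0
    spine_halfwidth: float = 11.0
    intensity_background: int = 25
    intensity_soft: int = 70
    intensity_bone: int = 190
    blur_sigma: float = 1.2
    gaussian_noise_sd: float = 0.0
    salt_pepper_frac: float = 0.0
    contrast_compression: float = 1.0
    texture_stripes: bool = False
    context_margin: float = 0.35

    def validate(self) -> None:
        if self.ljsd_true <= 0 or self.hlts_true <= 0 or self.hmts_true <= 0:
            raise ValidationError("ljsd_true, hlts_true, hmts_true must be > 0")
        ratio = self.ljsd_true / self.hlts_true
        if not (0.2 <= ratio <= 2.5):
            raise ValidationError(
                f"ljsd_true/hlts_true = {ratio:.3f} outside [0.2, 2.5]"
            )
        if abs(self.baseline_tilt) > 5:
            raise ValidationError("|baseline_tilt| must be <= 5 degrees")
        for name in ("spine_offset_lat", "spine_offset_med"):
            if abs(getattr(self, name)) >= self.plateau_halfwidth:
                raise ValidationError(f"{name} must lie inside the plateau span")
        if not (self.spine_offset_lat < self.spine_offset_med):
            raise ValidationError("spine_offset_lat must be < spine_offset_med")
        if not (
            0 <= self.intensity_background < self.intensity_soft
            < self.intensity_bone <= 255
        ):
            raise ValidationError(
                "need intensity_background < intensity_soft < intensity_bone <= 255"
            )
        if not (0.0 <= self.salt_pepper_frac <= 0.05):
            raise ValidationError("salt_pepper_frac must lie in [0, 0.05]")
        if not (0.0 < self.contrast_compression <= 1.0):
            raise ValidationError("contrast_compression must lie in (0, 1]")
        if self.width < 64 or self.height < 64:
            raise ValidationError("canvas must be at least 64x64")
        geo = _geometry(self)
        if geo["x_soft_l"] < 1 or geo["x_soft_r"] > self.width - 2:
            raise ValidationError("joint silhouette does not fit the canvas width")
        if geo["block_top"] > self.height - 3 or geo["t_block_bottom"] < 2:
            raise ValidationError("joint silhouette does not fit the canvas height")
        if _min_joint_gap(self, geo) < 3.0:
            raise ValidationError(
                "femur-tibia gap pinches below 3 px; the tibial spine would "
                "cross the femur boundary (crossover images are out of scope)"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PhantomTruth:
    """Exact landmark ground truth of a rendered phantom (height coords)."""

    up_left: Point
    up_right: Point
    spine_lateral: Point
    spine_medial: Point
    plateau_left: Point
    plateau_right: Point
    baseline: Line
    femur_axis_x: float
    ljsd: float
    hlts: float
    ratio: float
    joint_bbox: BBox
    laterality: str

    def __post_init__(self):
        if abs(self.ratio - self.ljsd / self.hlts) > 1e-9:
            raise ValidationError("truth ratio inconsistent with ljsd/hlts")

    def to_dict(self) -> dict:
        def pt(p: Point):
            return {"x": p.x, "h": p.h}

        return {
            "up_left": pt(self.up_left),
            "up_right": pt(self.up_right),
            "spine_lateral": pt(self.spine_lateral),
            "spine_medial": pt(self.spine_medial),
            "plateau_left": pt(self.plateau_left),
            "plateau_right": pt(self.plateau_right),
            "baseline": [pt(self.baseline.p1), pt(self.baseline.p2)],
            "femur_axis_x": self.femur_axis_x,
            "ljsd": self.ljsd,
            "hlts": self.hlts,
            "ratio": self.ratio,
            "joint_bbox": self.joint_bbox.to_dict(),
            "laterality": self.laterality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        pt = lambda q: Point(q["x"], q["h"])  # noqa: E731
        return cls(
            up_left=pt(d["up_left"]),
            up_right=pt(d["up_right"]),
            spine_lateral=pt(d["spine_lateral"]),
            spine_medial=pt(d["spine_medial"]),
            plateau_left=pt(d["plateau_left"]),
            plateau_right=pt(d["plateau_right"]),
            baseline=Line(pt(d["baseline"][0]), pt(d["baseline"][1])),
            femur_axis_x=d["femur_axis_x"],
            ljsd=d["ljsd"],
            hlts=d["hlts"],
            ratio=d["ratio"],
            joint_bbox=BBox(**d["joint_bbox"]),
            laterality=d["laterality"],
        )


# ---------------------------------------------------------------------------
# analytic geometry (canonical lateral-on-left frame, height coordinates)
# ---------------------------------------------------------------------------

def _geometry(spec: PhantomSpec) -> dict:
    cx = spec.width / 2.0
    phi = math.radians(spec.baseline_tilt)
    tanphi, cosphi = math.tan(phi), math.cos(phi)

    def bl(x):
        return spec.baseline_height + (np.asarray(x, dtype=float) - cx) * tanphi

    d = CONDYLE_SEP_FRAC * spec.plateau_halfwidth
    xL, xR = cx - d / 2.0, cx + d / 2.0
    rL, rM = spec.condyle_radius_lat, spec.condyle_radius_med
    aL, aM = ARC_EXTENT_FRAC * rL, ARC_EXTENT_FRAC * rM
    hL = float(bl(xL)) + spec.ljsd_true / cosphi
    hR = float(bl(xR)) + (spec.ljsd_true + MEDIAL_EXTRA_LJSD) / cosphi
    flank_top = max(hL, hR) + FLANK_RISE_FRAC * (rL + rM) / 2.0
    x_arc_l, x_arc_r = xL - aL, xR + aM  # outer arc ends
    xfl, xfr = x_arc_l - FLANK_RUN, x_arc_r + FLANK_RUN
    e_l = hL + rL - math.sqrt(rL ** 2 - aL ** 2)   # arc height at outer end
    e_r = hR + rM - math.sqrt(rM ** 2 - aM ** 2)
    n_l = hL + rL - math.sqrt(rL ** 2 - aL ** 2)   # inner end (symmetric arc)
    n_r = hR + rM - math.sqrt(rM ** 2 - aM ** 2)
    notch_l, notch_r = xL + aL, xR - aM
    notch_peak = max(n_l, n_r) + spec.notch_depth
    # the flare block must contain the notch apex for deep notches
    block_top = max(flank_top + FLARE_DEPTH, notch_peak + 10.0)

    def f(x):
        """Femur lower border; NaN outside [xfl, xfr]."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, np.nan)
        m = (x >= xfl) & (x < x_arc_l)
        out[m] = e_l + (flank_top - e_l) * ((x_arc_l - x[m]) / FLANK_RUN) ** 2
        m = (x >= x_arc_l) & (x <= xL + aL)
        out[m] = hL + rL - np.sqrt(np.maximum(rL ** 2 - (x[m] - xL) ** 2, 0.0))
        m = (x > notch_l) & (x < notch_r)
        t = (x[m] - notch_l) / (notch_r - notch_l)
        out[m] = n_l + (n_r - n_l) * t + spec.notch_depth * np.sin(np.pi * t)
        m = (x >= xR - aM) & (x <= x_arc_r)
        out[m] = hR + rM - np.sqrt(np.maximum(rM ** 2 - (x[m] - xR) ** 2, 0.0))
        m = (x > x_arc_r) & (x <= xfr)
        out[m] = e_r + (flank_top - e_r) * ((x[m] - x_arc_r) / FLANK_RUN) ** 2
        return out

    xs_lat = cx + spec.spine_offset_lat
    xs_med = cx + spec.spine_offset_med
    apex_lat = float(bl(xs_lat)) + spec.hlts_true / cosphi
    apex_med = float(bl(xs_med)) + spec.hmts_true / cosphi
    xc_l, xc_r = cx - spec.plateau_halfwidth, cx + spec.plateau_halfwidth
    corner_h_l, corner_h_r = float(bl(xc_l)), float(bl(xc_r))
    xtl, xtr = xc_l - CORNER_RUN, xc_r + CORNER_RUN
    corner_end = min(corner_h_l, corner_h_r) - CORNER_DROP_SLOPE * CORNER_RUN
    t_block_bottom = corner_end - TIBIA_FLARE_DEPTH

    def g(x, render_spines: bool = True):
        """Tibia upper border; NaN outside [xtl, xtr]."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, np.nan)
        m = (x >= xc_l) & (x <= xc_r)
        base = bl(x[m])
        val = base.copy()
        if render_spines:
            for xs, apex in ((xs_lat, apex_lat), (xs_med, apex_med)):
                amp = apex - bl(xs)
                bump = bl(x[m]) + amp * np.exp(
                    -((x[m] - xs) ** 2) / (2.0 * spec.spine_halfwidth ** 2)
                )
                val = np.maximum(val, bump)
        out[m] = val
        m = (x >= xtl) & (x < xc_l)
        out[m] = corner_h_l - CORNER_DROP_SLOPE * (xc_l - x[m])
        m = (x > xc_r) & (x <= xtr)
        out[m] = corner_h_r - CORNER_DROP_SLOPE * (x[m] - xc_r)
        return out

    x_soft_l = min(xfl, xtl) - SOFT_MARGIN
    x_soft_r = max(xfr, xtr) + SOFT_MARGIN
    return {
        "cx": cx, "bl": bl, "d": d, "xL": xL, "xR": xR, "hL": hL, "hR": hR,
        "flank_top": flank_top, "block_top": block_top,
        "xfl": xfl, "xfr": xfr, "f": f, "g": g,
        "xs_lat": xs_lat, "xs_med": xs_med,
        "apex_lat": apex_lat, "apex_med": apex_med,
        "xc_l": xc_l, "xc_r": xc_r,
        "corner_h_l": corner_h_l, "corner_h_r": corner_h_r,
        "xtl": xtl, "xtr": xtr, "t_block_bottom": t_block_bottom,
        "x_soft_l": x_soft_l, "x_soft_r": x_soft_r,
    }


def _min_joint_gap(spec: "PhantomSpec", geo: Optional[dict] = None) -> float:
    """Smallest vertical femur-tibia distance over the joint columns."""
    geo = geo or _geometry(spec)
    xs = np.arange(int(geo["xtl"]), int(geo["xtr"]) + 1, dtype=float)
    f = geo["f"](xs)
    g = geo["g"](xs)
    both = np.isfinite(f) & np.isfinite(g)
    if not both.any():
        return float("inf")
    return float(np.min(f[both] - g[both]))


def _mirror_point(p: Point, width: int) -> Point:
    return Point((width - 1) - p.x, p.h)


def _truth_from_geometry(spec: PhantomSpec, geo: dict) -> PhantomTruth:
    up_left = Point(geo["xL"], geo["hL"])
    up_right = Point(geo["xR"], geo["hR"])
    spine_lat = Point(geo["xs_lat"], geo["apex_lat"])
    spine_med = Point(geo["xs_med"], geo["apex_med"])
    pl = Point(geo["xc_l"], geo["corner_h_l"])
    pr = Point(geo["xc_r"], geo["corner_h_r"])
    H, W = spec.height, spec.width
    x0 = int(math.floor(geo["x_soft_l"] - 2))
    x1 = int(math.ceil(geo["x_soft_r"] + 2)) + 1
    y0 = int(math.floor((H - 1) - (geo["block_top"] + 4)))
    y1 = int(math.ceil((H - 1) - (geo["t_block_bottom"] - 4))) + 1
    bbox = BBox(max(0, x0), max(0, y0), min(W, x1), min(H, y1))
    truth = PhantomTruth(
        up_left=up_left, up_right=up_right,
        spine_lateral=spine_lat, spine_medial=spine_med,
        plateau_left=pl, plateau_right=pr,
        baseline=Line(pl, pr),
        femur_axis_x=(geo["xL"] + geo["xR"]) / 2.0,
        ljsd=float(spec.ljsd_true), hlts=float(spec.hlts_true),
        ratio=float(spec.ljsd_true) / float(spec.hlts_true),
        joint_bbox=bbox, laterality=spec.laterality,
    )
    if spec.laterality == LateralSide.lateral_right.value:
        W = spec.width
        bbox = truth.joint_bbox
        truth = PhantomTruth(
            up_left=_mirror_point(truth.up_right, W),
            up_right=_mirror_point(truth.up_left, W),
            spine_lateral=_mirror_point(truth.spine_lateral, W),
            spine_medial=_mirror_point(truth.spine_medial, W),
            plateau_left=_mirror_point(truth.plateau_right, W),
            plateau_right=_mirror_point(truth.plateau_left, W),
            baseline=Line(_mirror_point(truth.plateau_right, W),
                          _mirror_point(truth.plateau_left, W)),
            femur_axis_x=(W - 1) - truth.femur_axis_x,
            ljsd=truth.ljsd, hlts=truth.hlts, ratio=truth.ratio,
            joint_bbox=BBox(W - bbox.x1, bbox.y0, W - bbox.x0, bbox.y1),
            laterality=spec.laterality,
        )
    return truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _apply_salt_pepper(px: np.ndarray, frac: float, rng) -> np.ndarray:
    if frac <= 0:
        return px
    hit = rng.random(px.shape) < frac
    salt = rng.random(px.shape) < 0.5
    out = px.copy()
    out[hit & salt] = 255
    out[hit & ~salt] = 0
    return out


def make_phantom(
    spec: PhantomSpec, seed: int, _render_spines: bool = True
) -> Tuple[GrayImage, PhantomTruth]:
    """Render a phantom radiograph and its exact ground truth.

    Same (spec, seed) yields a bit-identical image; noise affects pixels only,
    never the truth.  ``_render_spines=False`` suppresses the tibial-spine
    bumps (geometry ablation for failure-path testing); the truth record still
    describes the intact spec.
    """
    spec.validate()
    geo = _geometry(spec)
    H, W = spec.height, spec.width
    rng = np.random.default_rng(seed)

    xcols = np.arange(W, dtype=float)
    hgrid = (H - 1) - np.arange(H, dtype=float)[:, None]  # height of each row
    f_arr = geo["f"](xcols)[None, :]
    g_arr = geo["g"](xcols, render_spines=_render_spines)[None, :]
    shaft = (np.abs(xcols - geo["cx"]) <= spec.shaft_halfwidth)[None, :]

    # vertical anti-aliasing: per-pixel coverage of the bone region, so the
    # 50%-intensity crossing of every articular border sits exactly on the
    # analytic boundary the ground truth quotes
    def up(b):  # coverage of {h >= b}
        return np.clip(hgrid + 0.5 - b, 0.0, 1.0)

    def down(b):  # coverage of {h <= b}
        return np.clip(b - hgrid + 0.5, 0.0, 1.0)

    zero = np.zeros((H, W))
    fv = np.where(np.isfinite(f_arr), f_arr, np.inf)
    gv = np.where(np.isfinite(g_arr), g_arr, -np.inf)
    femur_cov = np.maximum(up(fv) * down(geo["block_top"]),
                           np.where(shaft, up(geo["block_top"]), zero))
    tibia_cov = np.maximum(down(gv) * up(geo["t_block_bottom"]),
                           np.where(shaft, down(geo["t_block_bottom"]), zero))
    bone_cov = np.maximum(femur_cov, tibia_cov)

    soft = ((xcols >= geo["x_soft_l"]) & (xcols <= geo["x_soft_r"]))[None, :]
    canvas = np.where(np.broadcast_to(soft, (H, W)),
                      float(spec.intensity_soft),
                      float(spec.intensity_background))
    canvas = canvas * (1.0 - bone_cov) + float(spec.intensity_bone) * bone_cov
    bone = bone_cov > 0.5

    # trabecular lucencies: short dark streaks inside each bone, parallel to
    # the articular borders.  Radiographs always carry such interior texture;
    # the streaks keep the enhancement stage's edge census realistic without
    # adding long contours that could compete with the bone borders.
    streak_centers = (
        [geo["xL"] - 0.30 * spec.condyle_radius_lat,
         geo["xL"] + 0.30 * spec.condyle_radius_lat,
         geo["xR"] - 0.30 * spec.condyle_radius_med,
         geo["xR"] + 0.30 * spec.condyle_radius_med],
        [geo["cx"] - 0.55 * spec.plateau_halfwidth,
         geo["cx"] - 0.25 * spec.plateau_halfwidth,
         geo["cx"] + 0.25 * spec.plateau_halfwidth,
         geo["cx"] + 0.55 * spec.plateau_halfwidth],
    )
    for is_femur, centers in zip((True, False), streak_centers):
        for c in centers:
            c = c + rng.uniform(-6.0, 6.0)
            half = 0.5 * (26.0 + rng.uniform(-4.0, 4.0))
            x0, x1 = int(round(c - half)), int(round(c + half))
            x0, x1 = max(0, x0), min(W - 1, x1)
            if x1 <= x0:
                continue
            cols = np.arange(x0, x1 + 1)
            # tibial streaks follow the plateau line, not the spine bumps:
            # subchondral texture stays under the plateau in real knees
            border = (geo["f"](cols.astype(float)) if is_femur
                      else np.asarray(geo["bl"](cols.astype(float))))
            for xi, bref in zip(cols, border):
                if not np.isfinite(bref):
                    continue
                lo = bref + 6.0 if is_femur else bref - 10.0
                hi = bref + 10.0 if is_femur else bref - 6.0
                rows = (hgrid[:, 0] >= lo) & (hgrid[:, 0] <= hi) & bone[:, xi]
                canvas[rows, xi] = float(spec.intensity_soft)

    if spec.texture_stripes:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        stripes = STRIPE_AMPLITUDE * np.sin(
            2.0 * math.pi * xcols / STRIPE_PERIOD + phase
        )
        canvas[bone] += np.broadcast_to(stripes[None, :], (H, W))[bone]

    if spec.blur_sigma > 0:
        canvas = gaussian_filter(canvas, sigma=spec.blur_sigma)

    if spec.contrast_compression < 1.0:
        m = canvas.mean()
        canvas = m + spec.contrast_compression * (canvas - m)

    if spec.gaussian_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.gaussian_noise_sd, size=(H, W))

    px = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    px = _apply_salt_pepper(px, spec.salt_pepper_frac, rng)

    if spec.laterality == LateralSide.lateral_right.value:
        px = px[:, ::-1].copy()

    truth = _truth_from_geometry(spec, geo)
    image = GrayImage(px, None, f"phantom(seed={seed})")
    return image, truth


def degrade(
    image,
    salt_pepper_frac: float = 0.0,
    contrast_compression: float = 1.0,
    stripes: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Degrade an existing image: optional global texture stripes, affine
    contrast compression toward the image mean, then salt-and-pepper noise.
    Output is clamped to [0, 255]; all arguments at their defaults yield an
    identical copy."""
    if not (0.0 <= salt_pepper_frac <= 0.05):
        raise ValidationError("salt_pepper_frac must lie in [0, 0.05]")
    if not (0.0 < contrast_compression <= 1.0):
        raise ValidationError("contrast_compression must lie in (0, 1]")
    px = np.asarray(getattr(image, "pixels", image)).astype(np.float64)
    rng = np.random.default_rng(seed)
    if stripes:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        xcols = np.arange(px.shape[1], dtype=float)
        px = px + STRIPE_AMPLITUDE * np.sin(
            2.0 * math.pi * xcols / STRIPE_PERIOD + phase
        )[None, :]
    if contrast_compression < 1.0:
        m = px.mean()
        px = m + contrast_compression * (px - m)
    out = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return _apply_salt_pepper(out, salt_pepper_frac, rng)


# ---------------------------------------------------------------------------
# suite generation
# ---------------------------------------------------------------------------

GROUP_PARAMS = {
    # generating ratio distributions (automatic-measurement cohort statistics)
    "control": (0.7, 0.2),
    "discoid": (1.0, 0.3),
}

_MILD = {"noise": 2.0, "sp": 0.0, "contrast": (1.0, 1.0), "stripes": False}
_DEGRADED = {"noise": 5.0, "sp": 0.005, "contrast": (0.6, 1.0), "stripes": None}


def _truncated_normal(rng, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ValidationError("truncated normal rejection failed; check mean/sd")


def sample_spec(
    rng,
    ratio: float,
    context_margin: float = 0.35,
    noise_sd: float = 2.0,
    salt_pepper: float = 0.0,
    contrast: float = 1.0,
    stripes: bool = False,
    laterality: Optional[str] = None,
) -> PhantomSpec:
    """Draw one anatomically plausible spec realizing the given true ratio.

    The true HLTS is uniform on [30, 50] px and LJSD = ratio * HLTS; the other
    shape parameters vary over realistic ranges.  The canvas is sized so that
    a non-joint margin of ``context_margin`` x joint size surrounds the joint.
    """
    hlts = rng.uniform(30.0, 50.0)
    ljsd = ratio * hlts
    hmts = hlts * rng.uniform(0.72, 0.88)
    phw = rng.uniform(100.0, 120.0)
    r_lat = phw * rng.uniform(0.68, 0.80)
    r_med = phw * rng.uniform(0.68, 0.80)
    tilt = rng.uniform(-3.0, 3.0)
    notch_hw = (CONDYLE_SEP_FRAC / 2.0 - ARC_EXTENT_FRAC * max(r_lat, r_med) / phw) * phw
    off_lat = -rng.uniform(0.30, 0.50) * notch_hw
    off_med = rng.uniform(0.30, 0.50) * notch_hw
    # tall spines must not become needles: keep the apex curvature radius
    # above ~2 px (kappa = amp/sigma^2 <= 0.45) by widening the separation
    # so the merge guard below does not over-narrow the bumps
    sep_need = 2.2 * math.sqrt(max(hlts, hmts) / 0.45)
    sep = off_med - off_lat
    if sep < sep_need:
        scale = min(sep_need / sep, 1.05 * notch_hw / sep)
        off_lat *= scale
        off_med *= scale
    # cap the bump width so each spine's flanks fade out before the notch
    # walls: the bump tail at the notch edge must leave a clear joint gap
    spine_hw = rng.uniform(10.0, 13.0)
    arc_sag = 1.0 - math.sqrt(1.0 - ARC_EXTENT_FRAC ** 2)
    for off, amp in ((off_lat, hlts), (off_med, hmts)):
        dist = notch_hw - abs(off)
        target = max(ljsd + arc_sag * min(r_lat, r_med) - 6.0, 2.0)
        sig_max = dist / math.sqrt(2.0 * math.log(max(amp / target, 1.05)))
        spine_hw = min(spine_hw, sig_max)
    # two distinct spine peaks: the bumps must not merge into one mesa
    spine_hw = min(spine_hw, (off_med - off_lat) / 2.2)
    spine_hw = max(spine_hw, 5.0)
    notch_depth = max(26.0, (max(hlts, hmts) - ljsd - 9.0) / 0.55)
    blur = rng.uniform(0.9, 1.4)
    if laterality is None:
        laterality = (
            "lateral_left" if rng.random() < 0.5 else "lateral_right"
        )

    def build(depth: float) -> PhantomSpec:
        d = CONDYLE_SEP_FRAC * phw
        joint_w = (
            d + 2 * ARC_EXTENT_FRAC * max(r_lat, r_med) + 2 * FLANK_RUN
            + 2 * SOFT_MARGIN
        )
        rise = FLANK_RISE_FRAC * (r_lat + r_med) / 2
        top_rel = ljsd + MEDIAL_EXTRA_LJSD + max(rise + FLARE_DEPTH,
                                                 0.17 * max(r_lat, r_med)
                                                 + depth + 10.0)
        bot_rel = CORNER_DROP_SLOPE * CORNER_RUN + TIBIA_FLARE_DEPTH
        tilt_slack = (phw + CORNER_RUN) * math.tan(math.radians(abs(tilt))) + 4
        joint_h = top_rel + bot_rel + 2 * tilt_slack
        width = int(math.ceil(joint_w * (1.0 + 2.0 * context_margin)))
        height = int(math.ceil(joint_h * (1.0 + 2.0 * context_margin)))
        width, height = max(width, 64), max(height, 64)
        # place the joint block's vertical midpoint at the canvas centre
        baseline_height = height / 2.0 + (bot_rel - top_rel) / 2.0
        return PhantomSpec(
            width=width, height=height, laterality=laterality,
            baseline_height=float(baseline_height), baseline_tilt=float(tilt),
            plateau_halfwidth=float(phw), shaft_halfwidth=float(phw * 0.40),
            condyle_radius_lat=float(r_lat), condyle_radius_med=float(r_med),
            notch_depth=float(depth),
            ljsd_true=float(ljsd), hlts_true=float(hlts), hmts_true=float(hmts),
            spine_offset_lat=float(off_lat), spine_offset_med=float(off_med),
            spine_halfwidth=float(spine_hw),
            blur_sigma=float(blur),
            gaussian_noise_sd=float(noise_sd),
            salt_pepper_frac=float(salt_pepper),
            contrast_compression=float(contrast),
            texture_stripes=bool(stripes),
            context_margin=float(context_margin),
        )

    # deepen the notch until the joint gap clears the femur everywhere:
    # in-scope radiographs never show the spines crossing the femur border,
    # and the joint space must stay resolvable at the imaging blur scale
    # (the Canny chain breaks when two borders run closer than ~2.5 sigma).
    # If deepening alone cannot help (pinch under the arcs), narrow the bumps.
    gap_target = 9.0
    spec = build(notch_depth)
    for _ in range(40):
        gap = _min_joint_gap(spec)
        if gap >= gap_target:
            break
        prev = gap
        notch_depth += max(gap_target - gap, 0.0) + 0.5
        spec = build(notch_depth)
        if _min_joint_gap(spec) <= prev + 0.25 and spine_hw > 4.0:
            spine_hw *= 0.9
            spec = build(notch_depth)
    return spec


def iter_suite(
    group: str,
    n: int,
    seed: int,
    generating_mean: Optional[float] = None,
    generating_sd: Optional[float] = None,
    context_margin: float = 0.35,
):
    """Yield ``(spec, image, truth)`` for a seeded phantom suite.

    control / discoid draw true ratios from the group's generating normal
    distribution (truncated to the renderable range); mixed flips a fair coin
    per image between the two groups and applies the standard degradations
    (Gaussian noise sd 5, salt-and-pepper 0.5%, contrast 0.6-1.0, stripes).
    """
    if n < 1:
        raise ValidationError("suite size n must be >= 1")
    if generating_sd is not None and generating_sd < 0:
        raise ValidationError("generating_sd must be >= 0")
    if group not in ("control", "discoid", "mixed"):
        raise ValidationError("group must be control, discoid or mixed")
    rng = np.random.default_rng(seed)
    lo, hi = RATIO_TRUNC
    for _ in range(n):
        if group == "mixed":
            sub = "control" if rng.random() < 0.5 else "discoid"
            mean, sd = GROUP_PARAMS[sub]
            deg = _DEGRADED
        else:
            mean, sd = GROUP_PARAMS[group]
            deg = _MILD
        if generating_mean is not None:
            mean = generating_mean
        if generating_sd is not None:
            sd = generating_sd
        ratio = _truncated_normal(rng, mean, sd, lo, hi)
        stripes = deg["stripes"]
        if stripes is None:
            stripes = bool(rng.random() < 0.5)
        spec = sample_spec(
            rng,
            ratio,
            context_margin=context_margin,
            noise_sd=deg["noise"],
            salt_pepper=deg["sp"],
            contrast=float(rng.uniform(*deg["contrast"])),
            stripes=stripes,
        )
        render_seed = int(rng.integers(0, 2 ** 31 - 1))
        image, truth = make_phantom(spec, render_seed)
        yield spec, image, truth


def make_suite(
    group: str,
    n: int,
    seed: int,
    generating_mean: Optional[float] = None,
    generating_sd: Optional[float] = None,
    out_dir=None,
) -> dict:
    """Generate a phantom suite; write PNGs + a JSON manifest if ``out_dir``.

    Returns the manifest: generator parameters plus one entry per image with
    its file name (when written) and full ground truth.
    """
    entries: List[dict] = []
    images = []
    for i, (spec, image, truth) in enumerate(
        iter_suite(group, n, seed, generating_mean, generating_sd)
    ):
        entries.append({
            "file": f"phantom_{i:04d}.png",
            "truth": truth.to_dict(),
            "ljsd_true": spec.ljsd_true,
            "hlts_true": spec.hlts_true,
            "laterality": spec.laterality,
        })
        images.append(image)
    manifest = {
        "group": group,
        "n": n,
        "seed": seed,
        "generating_mean": generating_mean,
        "generating_sd": generating_sd,
        "entries": entries,
    }
    if out_dir is not None:
        from PIL import Image as PILImage

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for entry, image in zip(entries, images):
            PILImage.fromarray(image.pixels).save(out / entry["file"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        manifest["images"] = images
    return manifest


def make_detection_suite(
    n: int, seed: int, margin_range: Tuple[float, float] = (0.3, 0.7)
):
    """Yield ``(image, truth)`` phantoms with randomized context margins,
    for exercising the ROI detection stage."""
    rng = np.random.default_rng(seed)
    lo, hi = RATIO_TRUNC
    for _ in range(n):
        sub = "control" if rng.random() < 0.5 else "discoid"
        mean, sd = GROUP_PARAMS[sub]
        ratio = _truncated_normal(rng, mean, sd, lo, hi)
        margin = float(rng.uniform(*margin_range))
        spec = sample_spec(rng, ratio, context_margin=margin)
        render_seed = int(rng.integers(0, 2 ** 31 - 1))
        yield make_phantom(spec, render_seed)
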