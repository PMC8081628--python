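"""Landmark extraction on traced edges: femur boundary, condylar feature
points, tibial-spine tip tops, tibial-plateau border points and the plateau
baseline.

Everything operates in height coordinates (h up, see `edgemap`).  The stages
mirror the published measurement procedure:

* POFB ("part of the whole femur boundary"): long horizontal edges with no
  qualifying edge above them, merged into the joint's upper boundary.
* Condylar feature points: the two deepest local minima of the boundary
  profile, separated by the intercondylar notch; their midpoint defines the
  femoral axis.
* Tip tops: interior local maxima of an edge profile within a +/-K column
  window; candidates above the femur boundary or at edge end points are
  removed; a symmetric, well-separated pair becomes the tibial spines.
* Plateau border points: contour points maximizing the rotated-ruler score
  B(x) = F(x) cos45 -/+ x sin45 below the femoral condyle baseline, then
  shifted inward off steep segments to the plateau inflection.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .edgemap import ColumnFunction, EdgeSet, column_profile
from .errors import LandmarkFailure, ValidationError

logger = logging.getLogger(__name__)

_COS45 = math.cos(math.radians(45.0))
_SIN45 = math.sin(math.radians(45.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Point:
    """Image point: x column, h height (y-up)."""

    x: float
    h: float

    def to_raster(self, image_height: int) -> Tuple[float, float]:
        return (self.x, (image_height - 1) - self.h)


@dataclasses.dataclass(frozen=True)
class Line:
    p1: Point
    p2: Point

    def __post_init__(self):
        if self.p1.x == self.p2.x and self.p1.h == self.p2.h:
            raise ValidationError("Line requires two distinct points")

    def h_at(self, x: float) -> float:
        """Height of the line at column x (undefined for vertical lines)."""
        if self.p2.x == self.p1.x:
            raise ValidationError("vertical line has no h(x)")
        t = (x - self.p1.x) / (self.p2.x - self.p1.x)
        return self.p1.h + t * (self.p2.h - self.p1.h)


@dataclasses.dataclass
class UpperBoundary:
    """Merged femur boundary: contiguous column profile plus member edges."""

    profile: ColumnFunction
    member_edge_ids: Tuple[int, ...]

    def value(self, x: int) -> float:
        return self.profile.value(x)

    @property
    def x_min(self) -> int:
        return self.profile.x_min

    @property
    def x_max(self) -> int:
        return self.profile.x_max


@dataclasses.dataclass(frozen=True)
class TipTop:
    point: Point
    edge_id: int
    window_K: int
    curvature: float = 0.0  # quadratic coefficient of the local profile fit


def profile_curvature(cf: ColumnFunction, x: int, window: int = 4) -> float:
    """Quadratic coefficient a of the local fit F ~ a x^2 + b x + c around x.

    Used to correct sub-pixel edge localization at curved landmarks: Gaussian
    blur displaces an iso-intensity contour toward its centre of curvature by
    about sigma^2 |a|, so the measured extremum is biased by that amount.
    """
    lo = np.searchsorted(cf.xs, x - window, side="left")
    hi = np.searchsorted(cf.xs, x + window, side="right")
    xs, hs = cf.xs[lo:hi].astype(float), cf.hs[lo:hi]
    if xs.size < 5:
        return 0.0
    return float(np.polyfit(xs - x, hs, 2)[0])


@dataclasses.dataclass
class LandmarkSet:
    up_left: Point
    up_right: Point
    femur_axis_x: float
    spine_left: TipTop
    spine_right: TipTop
    plateau_left: Point
    plateau_right: Point
    baseline: Line
    condyle_baseline: Line
    # context for sub-pixel refinement (boundary / corner-edge profiles);
    # spine-tip curvatures live on the TipTops themselves
    refine_ctx: Optional[dict] = None

    def __post_init__(self):
        if not (self.up_left.x < self.up_right.x):
            raise ValidationError("up_left must lie left of up_right")
        if not (self.spine_left.point.x < self.spine_right.point.x):
            raise ValidationError("spine_left must lie left of spine_right")
        if not (self.plateau_left.x < self.plateau_right.x):
            raise ValidationError("plateau_left must lie left of plateau_right")
        for t in (self.spine_left, self.spine_right):
            if not (self.up_left.x < t.point.x < self.up_right.x):
                raise ValidationError("spine x must lie between condyle points")


# ---------------------------------------------------------------------------
# POFB / femur boundary
# ---------------------------------------------------------------------------

def find_pofb(
    edges: EdgeSet,
    roi_width: int,
    span_frac: float = 0.2,
    aspect: float = 3.0,
    gap_frac: float = 0.10,
    min_span_frac: float = 0.30,
) -> UpperBoundary:
    """Identify the femur boundary from the traced edges.

    An edge qualifies as POFB material iff its column span is at least
    ``span_frac`` of the ROI width *and* at least ``aspect`` times its height
    span ("significantly longer in the horizontal direction").  A qualifying
    edge is POFB iff no other qualifying edge lies above it over more than
    half of its column span.  All POFB edges are merged left-to-right into a
    single profile; gaps up to ``gap_frac`` of the ROI width are bridged
    linearly and the widest contiguous block is kept.
    """
    if not edges.polylines:
        raise LandmarkFailure("pofb", "no edges to analyze")
    H = edges.image_dims[0]
    profiles = [column_profile(p, H) for p in edges.polylines]

    def qualifies(cf: ColumnFunction) -> bool:
        hspan = float(cf.hs.max() - cf.hs.min())
        return cf.span >= span_frac * roi_width and cf.span >= aspect * hspan

    qual = [cf for cf in profiles if qualifies(cf)]
    pofb: List[ColumnFunction] = []
    for cf in qual:
        covered_above = 0
        for other in qual:
            if other is cf:
                continue
            common = np.intersect1d(cf.xs, other.xs, assume_unique=True)
            if common.size == 0:
                continue
            fi = np.searchsorted(cf.xs, common)
            oi = np.searchsorted(other.xs, common)
            above = int(np.count_nonzero(other.hs[oi] > cf.hs[fi]))
            covered_above = max(covered_above, above)
        if covered_above <= 0.5 * cf.span:
            pofb.append(cf)
    if not pofb:
        raise LandmarkFailure("pofb", "no edge satisfies the POFB rules")

    # merge left-to-right; where two POFB edges overlap in a column, keep the
    # lower one - the upper boundary of the *joint* is the femur's lowest
    # silhouette (flare-top edges may also satisfy the POFB rules).
    merged: dict = {}
    members: List[int] = []
    for cf in pofb:
        members.extend(cf.source_edge_ids)
        for x, hh in zip(cf.xs.tolist(), cf.hs.tolist()):
            if x not in merged or hh < merged[x]:
                merged[x] = hh
    xs = np.array(sorted(merged), dtype=np.int64)
    hs = np.array([merged[int(x)] for x in xs])

    # bridge small gaps linearly
    max_gap = gap_frac * roi_width
    fx, fh = [int(xs[0])], [float(hs[0])]
    for i in range(1, xs.size):
        gap = int(xs[i]) - fx[-1] - 1
        if 0 < gap <= max_gap:
            x0, h0 = fx[-1], fh[-1]
            x1, h1 = int(xs[i]), float(hs[i])
            for x in range(x0 + 1, x1):
                fh.append(h0 + (h1 - h0) * (x - x0) / (x1 - x0))
                fx.append(x)
        elif gap > max_gap:
            fx.append(None)  # break marker
            fh.append(None)
        fx.append(int(xs[i]))
        fh.append(float(hs[i]))

    # keep the widest contiguous block
    blocks, cur_x, cur_h = [], [], []
    for x, hh in zip(fx, fh):
        if x is None:
            if cur_x:
                blocks.append((cur_x, cur_h))
            cur_x, cur_h = [], []
        else:
            cur_x.append(x)
            cur_h.append(hh)
    if cur_x:
        blocks.append((cur_x, cur_h))
    bx, bh = max(blocks, key=lambda b: len(b[0]))
    if len(bx) < min_span_frac * roi_width:
        raise LandmarkFailure(
            "pofb",
            f"merged boundary spans {len(bx)} columns "
            f"(< {min_span_frac:.0%} of ROI width {roi_width})",
        )
    profile = ColumnFunction(np.array(bx), np.array(bh), tuple(sorted(set(members))))
    return UpperBoundary(profile, tuple(sorted(set(members))))


# ---------------------------------------------------------------------------
# condylar feature points
# ---------------------------------------------------------------------------

def _local_minima(vals: np.ndarray) -> List[int]:
    """Indices of interior local minima, plateau runs collapsing to midpoints."""
    n = vals.size
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        if j < n - 1 and vals[i - 1] > vals[i] and vals[j + 1] > vals[j]:
            out.append((i + j) // 2)
        i = j + 1
    return out


def condyle_points(
    boundary: UpperBoundary,
    smooth_window: int = 5,
    min_sep_frac: float = 0.10,
) -> Tuple[Point, Point, float]:
    """Locate the condylar lowest points and the femoral axis.

    The profile is smoothed (moving average) to locate the two deepest height
    valleys; profiles shorter than 15 columns are used raw.  The intercondylar
    notch is the highest interior point between the valleys; the up-left /
    up-right points are the raw minimum-height points of the left and right
    segments (ties broken toward the notch).
    """
    xs, hs = boundary.profile.xs, boundary.profile.hs
    n = xs.size
    if n < 5:
        raise LandmarkFailure("condyles", "boundary too short")
    if n >= 15 and smooth_window > 1:
        kernel = np.ones(smooth_window)
        sm = np.convolve(hs, kernel, mode="same") / np.convolve(
            np.ones(n), kernel, mode="same"
        )
    else:
        sm = hs.astype(np.float64)

    minima = _local_minima(sm)
    span = int(xs[-1] - xs[0] + 1)
    best_pair, best_depth = None, None
    for ai in range(len(minima)):
        for bi in range(ai + 1, len(minima)):
            a, b = minima[ai], minima[bi]
            if xs[b] - xs[a] < min_sep_frac * span:
                continue
            depth = sm[a] + sm[b]
            if best_depth is None or depth < best_depth:
                best_depth, best_pair = depth, (a, b)
    if best_pair is None:
        raise LandmarkFailure(
            "condyles", "fewer than two separated height minima on the boundary"
        )
    a, b = best_pair
    interior = slice(a + 1, b)
    notch_rel = int(np.argmax(sm[interior]))
    # collapse ties toward the segment centre
    ties = np.flatnonzero(sm[interior] == sm[interior][notch_rel])
    notch = a + 1 + int(ties[len(ties) // 2])

    left = hs[: notch]
    right = hs[notch + 1:]
    li = int(np.flatnonzero(left == left.min())[-1])          # tie -> toward notch
    ri = notch + 1 + int(np.flatnonzero(right == right.min())[0])
    up_left = Point(float(xs[li]), float(hs[li]))
    up_right = Point(float(xs[ri]), float(hs[ri]))
    axis_x = (up_left.x + up_right.x) / 2.0
    return up_left, up_right, axis_x


# ---------------------------------------------------------------------------
# tip tops (spine candidates)
# ---------------------------------------------------------------------------

def find_tip_tops(
    edges: EdgeSet,
    boundary: Optional[UpperBoundary],
    K: int,
    exclude_edge_ids: Sequence[int] = (),
    min_prominence: float = 3.0,
) -> List[TipTop]:
    """Interior local maxima of each edge profile within a +/-K column window.

    A column X qualifies iff F(X) equals the maximum of F over the in-domain
    columns of [X-K, X+K] and X is not a domain end point.  Runs of qualifying
    ties collapse to their midpoint; a run wider than the full window (2K+1)
    is a ridge, not a tip, and a run must rise at least ``min_prominence``
    above the lowest profile value within its window span (pixel-jitter bumps
    on flat texture edges are not anatomy).  Tip tops above the femur
    boundary, or outside its column domain, are discarded; edges listed in
    ``exclude_edge_ids`` (e.g. the boundary's own members) are skipped.
    """
    if K < 1:
        raise ValidationError("window K must be >= 1")
    excluded = set(exclude_edge_ids)
    H = edges.image_dims[0]
    tips: List[TipTop] = []
    for poly in edges.polylines:
        if poly.id in excluded:
            continue
        cf = column_profile(poly, H)
        xs, hs = cf.xs, cf.hs
        n = xs.size
        if n < 3:
            continue
        qualifying = np.zeros(n, dtype=bool)
        for i in range(1, n - 1):
            lo = np.searchsorted(xs, xs[i] - K, side="left")
            hi = np.searchsorted(xs, xs[i] + K, side="right")
            if hs[i] >= hs[lo:hi].max():
                qualifying[i] = True
        i = 0
        while i < n:
            if not qualifying[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and qualifying[j + 1]
                and hs[j + 1] == hs[i]
                and xs[j + 1] == xs[j] + 1
            ):
                j += 1
            mid = (i + j) // 2
            x, hh = int(xs[mid]), float(hs[mid])
            # a flat run wider than the whole window qualifies trivially in
            # its interior; that is a ridge, not a tip
            keep = (j - i + 1) <= 2 * K + 1
            if keep:
                lo2 = np.searchsorted(xs, xs[i] - K, side="left")
                hi2 = np.searchsorted(xs, xs[j] + K, side="right")
                keep = hh - hs[lo2:hi2].min() >= min_prominence
            if boundary is not None:
                if not (boundary.x_min <= x <= boundary.x_max) or not (
                    boundary.profile.has(x)
                ):
                    keep = False
                elif hh > boundary.value(x):
                    keep = False
            if keep:
                tips.append(TipTop(Point(float(x), hh), poly.id, K,
                                   profile_curvature(cf, x)))
            i = j + 1
    return tips


def select_spines(
    tips: Sequence[TipTop],
    up_left: Point,
    up_right: Point,
    femur_axis_x: float,
    sep_min_frac: float = 0.05,
    sep_max_frac: float = 0.6,
    sym_tol: float = 0.15,
) -> Tuple[TipTop, TipTop]:
    """Choose the tibial-spine pair among tip-top candidates.

    A pair must be separated by [sep_min, sep_max] fractions of the condylar
    distance d, lie strictly between the condyle points, and be approximately
    symmetric about the femoral axis (midpoint within ``sym_tol``*d).  Among
    qualifying pairs the one with the greatest *lower* tip wins; ties break
    toward the most axis-symmetric midpoint.
    """
    d = up_right.x - up_left.x
    if d <= 0:
        raise ValidationError("condyle points must be ordered")
    best = None
    key = None
    for i in range(len(tips)):
        for j in range(len(tips)):
            t1, t2 = tips[i], tips[j]
            if not (t1.point.x < t2.point.x):
                continue
            sep = t2.point.x - t1.point.x
            if not (sep_min_frac * d <= sep <= sep_max_frac * d):
                continue
            if not (up_left.x < t1.point.x and t2.point.x < up_right.x):
                continue
            mid_off = abs((t1.point.x + t2.point.x) / 2.0 - femur_axis_x)
            if mid_off > sym_tol * d:
                continue
            # pixel-quantized heights tie often; prefer the higher pair
            # overall before falling back to the symmetry tie-break
            cand_key = (min(t1.point.h, t2.point.h),
                        t1.point.h + t2.point.h, -mid_off,
                        -t1.point.x, -t2.point.x)
            if key is None or cand_key > key:
                key, best = cand_key, (t1, t2)
    if best is None:
        raise LandmarkFailure("spines", "no qualifying tibial-spine pair")
    return best


# ---------------------------------------------------------------------------
# plateau border points
# ---------------------------------------------------------------------------

def _slope_angle_deg(cf: ColumnFunction, x: int, window: int = 3) -> float:
    """Local slope angle (degrees) from a least-squares fit over +/-window."""
    lo = np.searchsorted(cf.xs, x - window, side="left")
    hi = np.searchsorted(cf.xs, x + window, side="right")
    xs, hs = cf.xs[lo:hi], cf.hs[lo:hi]
    if xs.size < 2:
        return 0.0
    slope = np.polyfit(xs.astype(float), hs, 1)[0]
    return math.degrees(math.atan(abs(float(slope))))


def shift_border_point(
    edge: ColumnFunction,
    tangent: Point,
    femur_axis_x: float,
    steep_deg: float = 70.0,
    stop_deg: float = 45.0,
    cap_frac: float = 0.25,
    warn_sink: Optional[list] = None,
) -> Point:
    """Shift a tangent point inward off a steep segment to the inflection.

    If the local slope at the tangent exceeds ``steep_deg`` the point walks
    along its edge toward the femoral axis until the slope drops to
    ``stop_deg`` or less; the walk is capped at ``cap_frac`` of the edge's
    column span (cap reached -> the cap point is returned with a warning).
    """
    x0 = int(round(tangent.x))
    if _slope_angle_deg(edge, x0) <= steep_deg:
        return tangent
    idx = int(np.searchsorted(edge.xs, x0))
    idx = min(max(idx, 0), edge.xs.size - 1)
    step = 1 if femur_axis_x > tangent.x else -1
    max_steps = max(1, int(cap_frac * edge.span))
    last = tangent
    for k in range(1, max_steps + 1):
        i = idx + step * k
        if i < 0 or i >= edge.xs.size:
            break
        x = int(edge.xs[i])
        last = Point(float(x), float(edge.hs[i]))
        if _slope_angle_deg(edge, x) <= stop_deg:
            return last
    msg = (
        f"border-point shift capped after {max_steps} columns without "
        f"reaching slope <= {stop_deg} deg"
    )
    logger.warning(msg)
    if warn_sink is not None:
        warn_sink.append(msg)
    return last


def plateau_border_point(
    edges: EdgeSet,
    side: str,
    boundary: UpperBoundary,
    condyle_baseline: Line,
    femur_axis_x: float,
    steep_deg: float = 70.0,
    stop_deg: float = 45.0,
    cap_frac: float = 0.25,
    warn_sink: Optional[list] = None,
    return_edge: bool = False,
):
    """Locate one tibial-plateau border point by the rotated-ruler score.

    Candidates are edge-profile points strictly below the femur boundary
    (below the condyle baseline where the boundary is undefined) and not above
    the condyle baseline.  The tangent point maximizes
    B_left(x) = (F(x) - x) * cos45 or B_right(x) = (F(x) + x) * cos45
    (ties break to the outermost x) and is then shifted off steep segments.
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    H = edges.image_dims[0]
    sign = -1.0 if side == "left" else 1.0
    best_score, best_point, best_cf = None, None, None
    for poly in edges.polylines:
        cf = column_profile(poly, H)
        xs = cf.xs
        hs = cf.hs
        cb = np.array([condyle_baseline.h_at(float(x)) for x in xs])
        in_bd = (xs >= boundary.x_min) & (xs <= boundary.x_max)
        below = np.empty(xs.size, dtype=bool)
        for i, x in enumerate(xs):
            if in_bd[i] and boundary.profile.has(int(x)):
                below[i] = hs[i] < boundary.value(int(x))
            else:
                below[i] = hs[i] < cb[i]
        ok = below & (hs <= cb)
        if not ok.any():
            continue
        # B(x) = F(x) cos45 -/+ x sin45; at 45 deg the common factor cos45
        # drops out, and h -/+ x keeps integer ties exact for the tie-break
        score = hs + sign * xs
        score = np.where(ok, score, -np.inf)
        i = int(np.argmax(score))
        # tie-break to outermost x
        ties = np.flatnonzero(score == score[i])
        i = int(ties[0]) if side == "left" else int(ties[-1])
        if best_score is None or score[i] > best_score or (
            score[i] == best_score
            and (xs[i] < best_point.x if side == "left" else xs[i] > best_point.x)
        ):
            best_score = float(score[i])
            best_point = Point(float(xs[i]), float(hs[i]))
            best_cf = cf
    if best_point is None:
        raise LandmarkFailure("plateau", f"no {side} border-point candidates")
    shifted = shift_border_point(
        best_cf, best_point, femur_axis_x, steep_deg, stop_deg, cap_frac, warn_sink
    )
    return (shifted, best_cf) if return_edge else shifted


def plateau_baseline(left: Point, right: Point) -> Line:
    """Line through the two (post-shift) plateau border points."""
    if not (left.x < right.x):
        if left.x == right.x and left.h == right.h:
            raise LandmarkFailure("baseline", "coincident border points")
        raise LandmarkFailure("baseline", "border points not ordered left < right")
    return Line(left, right)
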