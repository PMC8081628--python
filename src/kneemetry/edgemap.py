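"""Canny edge detection, contour tracing and per-column height profiles.

All landmark mathematics downstream runs in *height* coordinates
``h = (image_height - 1) - y`` (y-up), so that tibial-spine apices are local
*maxima* and the 45-degree ruler score is geometrically consistent.  The
conversion is applied exactly once, here, when a traced polyline is turned
into its per-column profile; rendering converts back to raster.

Tracing realizes the notion of a "single edge" as a near-simple curve that is
approximately a function of x: 8-connected components are split at junction
pixels (degree > 2) keeping the longest path plus long branches, and
additionally at strictly vertical runs longer than ``max_vertical_run`` pixels
(bone-shaft borders), so each polyline has a meaningful column profile.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _sk_canny

from .errors import ValidationError

# The hysteresis thresholds of the reference procedure are quoted in the
# 3x3-Sobel gradient convention of classic implementations; skimage's
# Gaussian-derivative gradient is smaller by the Sobel kernel gain.
_SOBEL_GAIN = 8.0
CANNY_SIGMA = 1.4

_NEIGHBORS = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EdgePolyline:
    """Ordered 8-connected chain of edge pixels, raster coordinates."""

    id: int
    points: List[Tuple[int, int]]  # (x, y)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValidationError("EdgePolyline needs at least 2 points")

    @property
    def x_min(self) -> int:
        return min(p[0] for p in self.points)

    @property
    def x_max(self) -> int:
        return max(p[0] for p in self.points)

    @property
    def y_min(self) -> int:
        return min(p[1] for p in self.points)

    @property
    def y_max(self) -> int:
        return max(p[1] for p in self.points)


@dataclasses.dataclass
class ColumnFunction:
    """Per-column height profile h = F(x) of one or more edges.

    ``xs`` is sorted and unique; the domain may have gaps.  Heights follow the
    y-up convention; the topmost pixel of a column is its representative.
    """

    xs: np.ndarray
    hs: np.ndarray
    source_edge_ids: Tuple[int, ...] = ()

    def __post_init__(self):
        self.xs = np.asarray(self.xs, dtype=np.int64)
        self.hs = np.asarray(self.hs, dtype=np.float64)
        if self.xs.size != self.hs.size:
            raise ValidationError("xs and hs must have equal length")

    @property
    def x_min(self) -> int:
        return int(self.xs[0])

    @property
    def x_max(self) -> int:
        return int(self.xs[-1])

    @property
    def span(self) -> int:
        return self.x_max - self.x_min + 1 if self.xs.size else 0

    def value(self, x: int) -> float:
        i = np.searchsorted(self.xs, x)
        if i == self.xs.size or self.xs[i] != x:
            raise KeyError(f"column {x} not in domain")
        return float(self.hs[i])

    def has(self, x: int) -> bool:
        i = np.searchsorted(self.xs, x)
        return i < self.xs.size and self.xs[i] == x


@dataclasses.dataclass
class EdgeSet:
    polylines: List[EdgePolyline]
    image_dims: Tuple[int, int]  # (height, width)
    canny_params: Tuple[float, float]

    def __len__(self) -> int:
        return len(self.polylines)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def canny_edges(image, low: float, high: float) -> np.ndarray:
    """Standard Canny edge map (Gaussian sigma 1.4, hysteresis (low, high))."""
    if not (0 < low < high):
        raise ValidationError("canny thresholds require 0 < low < high")
    px = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    return _sk_canny(
        px,
        sigma=CANNY_SIGMA,
        low_threshold=low / _SOBEL_GAIN,
        high_threshold=high / _SOBEL_GAIN,
    )


def _longest_path(nodes: set, adj: Dict[Tuple[int, int], list]) -> list:
    """Approximate longest simple path via double BFS (exact on trees)."""

    def bfs(start):
        parent = {start: None}
        order = [start]
        qi = 0
        while qi < len(order):
            cur = order[qi]
            qi += 1
            for nb in adj[cur]:
                if nb in nodes and nb not in parent:
                    parent[nb] = cur
                    order.append(nb)
        far = order[-1]
        path = [far]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        path.reverse()
        return far, path

    start = min(nodes)
    far, _ = bfs(start)
    _, path = bfs(far)
    return path


def _split_vertical_runs(points: list, max_run: int) -> List[list]:
    """Split a chain where it runs strictly vertically for > max_run pixels."""
    pieces: List[list] = []
    cur: list = []
    i = 0
    n = len(points)
    while i < n:
        j = i
        while j + 1 < n and points[j + 1][0] == points[i][0]:
            j += 1
        run_len = j - i + 1
        if run_len > max_run:
            if cur:
                pieces.append(cur)
                cur = []
            pieces.append(points[i:j + 1])
        else:
            cur.extend(points[i:j + 1])
        i = j + 1
    if cur:
        pieces.append(cur)
    return pieces


def _split_x_reversals(points: list, tol: int = 4) -> List[list]:
    """Split a chain where its x direction reverses by >= tol columns.

    A chain that doubles back (e.g. runs along a bone border, around a
    silhouette corner and back along another border) is not a function of x;
    splitting at the confirmed turning point restores near-monotone pieces.
    Jitter smaller than ``tol`` columns (rounded corners) is tolerated.
    """
    xs = [p[0] for p in points]
    n = len(xs)
    out: List[list] = []
    start = 0
    direction = 0
    ext_i = 0
    k = 1
    while k < n:
        if direction == 0:
            if xs[k] != xs[start]:
                direction = 1 if xs[k] > xs[start] else -1
                ext_i = k
        else:
            if (xs[k] - xs[ext_i]) * direction >= 0:
                ext_i = k
            elif (xs[ext_i] - xs[k]) * direction >= tol:
                out.append(points[start:ext_i + 1])
                start = ext_i + 1
                direction = 0
                ext_i = start
                k = start
        k += 1
    out.append(points[start:])
    return [p for p in out if len(p) >= 2]


def trace_polylines(edge_grid: np.ndarray, min_len: int = 10,
                    max_vertical_run: int = 12) -> EdgeSet:
    """Trace a binary edge grid into ordered polylines (deterministic).

    8-connected components are reduced to their longest path plus branches of
    at least ``min_len`` pixels; chains are further split at strictly vertical
    runs longer than ``max_vertical_run``; pieces shorter than ``min_len`` are
    discarded.  Ids are assigned in raster order of the polyline extents.
    """
    grid = np.asarray(edge_grid).astype(bool)
    h, w = grid.shape
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    chains: List[list] = []
    if n:
        all_yx = np.argwhere(labels > 0)
        lab_of = labels[all_yx[:, 0], all_yx[:, 1]]
        for comp_idx in range(1, n + 1):
            comp = all_yx[lab_of == comp_idx]
            if comp.shape[0] < min_len:
                continue
            nodes = {(int(y), int(x)) for y, x in comp}
            adj = {
                p: sorted(
                    (p[0] + dy, p[1] + dx)
                    for dy, dx in _NEIGHBORS
                    if (p[0] + dy, p[1] + dx) in nodes
                )
                for p in nodes
            }
            pending = [nodes]
            while pending:
                piece = pending.pop(0)
                if len(piece) < min_len:
                    continue
                path = _longest_path(piece, adj)
                chains.append(path)
                rest = piece - set(path)
                # split the remainder into connected sub-pieces
                while rest:
                    seed = min(rest)
                    stack, sub = [seed], {seed}
                    while stack:
                        cur = stack.pop()
                        for nb in adj[cur]:
                            if nb in rest and nb not in sub:
                                sub.add(nb)
                                stack.append(nb)
                    rest -= sub
                    if len(sub) >= min_len:
                        pending.append(sub)

    polylines: List[EdgePolyline] = []
    for path in chains:
        pts = [(x, y) for (y, x) in path]
        if pts[-1] < pts[0]:
            pts.reverse()
        for piece in _split_vertical_runs(pts, max_vertical_run):
            for sub in _split_x_reversals(piece):
                if len(sub) >= min_len:
                    polylines.append(EdgePolyline(0, sub))

    polylines.sort(key=lambda p: (p.y_min, p.x_min, p.y_max, p.x_max, len(p.points)))
    for i, p in enumerate(polylines):
        p.id = i
    return EdgeSet(polylines, (h, w), (0.0, 0.0))


def column_profile(edge: EdgePolyline, image_height: int) -> ColumnFunction:
    """Per-column profile F(x) = max height (anatomically topmost pixel)."""
    best: Dict[int, float] = {}
    hmax = image_height - 1
    for x, y in edge.points:
        hgt = float(hmax - y)
        if x not in best or hgt > best[x]:
            best[x] = hgt
    xs = np.array(sorted(best), dtype=np.int64)
    hs = np.array([best[int(x)] for x in xs], dtype=np.float64)
    return ColumnFunction(xs, hs, (edge.id,))


def detect_edges_with_retry(
    image,
    groups: Sequence[Tuple[float, float]] = ((20.0, 80.0), (20.0, 90.0)),
    min_len: int = 10,
    max_vertical_run: int = 12,
) -> Iterator[EdgeSet]:
    """Yield one traced EdgeSet per Canny parameter group, in order.

    The pipeline consumes the next group only when a downstream landmark stage
    fails; the parameters actually used are recorded in the Report.
    """
    if not groups:
        raise ValidationError("canny parameter groups must be non-empty")
    for low, high in groups:
        grid = canny_edges(image, low, high)
        es = trace_polylines(grid, min_len=min_len, max_vertical_run=max_vertical_run)
        es.canny_params = (float(low), float(high))
        yield es
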