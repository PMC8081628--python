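"""Radiograph reading, knee-joint ROI detection and laterality resolution.

The original two-phase procedure locates the knee joint with a trained
object detector before any measurement.  No learned detector is bundled
here; instead the contract is kept pluggable:

* a caller-provided bounding box always wins,
* an arbitrary external detector hook (any callable returning
  ``(BBox, confidence)``) can be injected,
* otherwise a classical intensity-profile fallback proposes the ROI.

The fallback exploits the universal appearance of an AP knee radiograph:
a dark joint-space band flanked above (femoral condyles) and below (tibial
plateau) by the brightest bone bands in the image.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from pathlib import Path
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DetectionFailure, FormatError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class LateralSide(str, enum.Enum):
    """Which image side holds the anatomically lateral compartment."""

    lateral_left = "lateral_left"
    lateral_right = "lateral_right"


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """2-D 8-bit radiograph in raster coordinates (x right, y down)."""

    pixels: np.ndarray  # uint8, shape (height, width)
    spacing_mm: Optional[float] = None
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("GrayImage.pixels must be 2-D")
        if px.dtype != np.uint8:
            raise ValidationError("GrayImage.pixels must be uint8")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValidationError("GrayImage must be at least 32x32")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass(frozen=True)
class BBox:
    """Half-open pixel box [x0, x1) x [y0, y1), raster coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValidationError("BBox requires x0 < x1 and y0 < y1")
        if min(self.x0, self.y0) < 0:
            raise ValidationError("BBox coordinates must be non-negative")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def iou(self, other: "BBox") -> float:
        ix0, iy0 = max(self.x0, other.x0), max(self.y0, other.y0)
        ix1, iy1 = min(self.x1, other.x1), min(self.y1, other.y1)
        inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union else 0.0

    def expand(self, frac: float, width: int, height: int) -> "BBox":
        """Grow by ``frac`` of each dimension, clipped to the image."""
        mx = int(round(self.width * frac))
        my = int(round(self.height * frac))
        return BBox(
            max(0, self.x0 - mx),
            max(0, self.y0 - my),
            min(width, self.x1 + mx),
            min(height, self.y1 + my),
        )

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    bbox: BBox
    confidence: float
    method: str  # provided | profile_fallback | external

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("confidence must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class Laterality:
    value: LateralSide
    provenance: str  # flag | metadata | default


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linearly map an arbitrary-range array onto [0, 255] (endpoints exact)."""
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def _read_dicom(path: Path, spacing_override: Optional[float]):
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1":
        arr = arr.max() - arr
    spacing = spacing_override
    if spacing is None:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = float(ps[0])
    meta = {"Laterality": str(getattr(ds, "Laterality", "")) or None}
    return _to_uint8(arr), spacing, meta


def read_image(path, spacing_override: Optional[float] = None) -> GrayImage:
    """Read a PNG/TIFF/DICOM radiograph as an 8-bit grayscale image.

    Multi-channel inputs are converted to luminance; DICOM rescale is applied
    and the dynamic range linearly mapped to 8 bits; ``spacing_mm`` is filled
    from metadata when available.  DICOM laterality metadata, if present, is
    attached as ``image.meta_laterality`` for `resolve_laterality`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    meta_lat = None
    try:
        if suffix in (".dcm", ".dicom", ""):
            arr, spacing, meta = _read_dicom(path, spacing_override)
            meta_lat = meta.get("Laterality")
        else:
            from PIL import Image

            with Image.open(path) as im:
                if im.mode in ("I", "I;16", "I;16B", "F"):
                    arr = _to_uint8(np.asarray(im))
                else:
                    arr = np.asarray(im.convert("L"))
            spacing = spacing_override
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    img = GrayImage(np.ascontiguousarray(arr, dtype=np.uint8), spacing, str(path))
    object.__setattr__(img, "meta_laterality", meta_lat)
    return img


# ---------------------------------------------------------------------------
# ROI detection
# ---------------------------------------------------------------------------

# Anatomical proportions of an AP knee joint used to size the fallback box.
# The joint block (condylar flare through tibial flare) is wider than tall.
_BOX_ASPECT = 0.78          # box height / box width
_BOX_SHIFT_UP = 0.43        # fraction of box height above the joint-space band
_COL_THR = 0.35             # bright-column threshold (fraction of col range);
#                             low enough to include the soft-tissue envelope
_MIN_VALLEY_DEPTH = 0.15    # of the intensity range, for a credible band
_MIN_RANGE = 8              # intensity levels of structure required


def profile_roi_proposer(image: GrayImage) -> BBox:
    """Propose the knee-joint box from intensity profiles (deterministic).

    Finds the darkest horizontal band flanked above and below by bright bone
    bands, takes the bright-column span near that band as the joint width and
    sizes the box by the anatomical height/width proportion of an AP knee.
    """
    px = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    h, w = px.shape
    rng_span = float(px.max() - px.min())
    if rng_span < _MIN_RANGE:
        raise DetectionFailure("image has no intensity structure")

    p = gaussian_filter1d(px.mean(axis=1), sigma=3.0)
    above = np.maximum.accumulate(p)
    below = np.maximum.accumulate(p[::-1])[::-1]
    # depth of p[r] below the best bright band on each side
    depth = np.minimum(np.concatenate(([p[0]], above[:-1])),
                       np.concatenate((below[1:], [p[-1]]))) - p
    r0 = int(np.argmax(depth))
    if depth[r0] < _MIN_VALLEY_DEPTH * (p.max() - p.min() + 1e-9):
        raise DetectionFailure("no dark band flanked by bright bands")

    # contiguous band of rows around the valley
    level = p[r0] + 0.5 * depth[r0]
    top = r0
    while top > 0 and p[top - 1] < level:
        top -= 1
    bot = r0
    while bot < h - 1 and p[bot + 1] < level:
        bot += 1
    band_h = max(bot - top + 1, 3)

    # bright-column span in the neighbourhood of the band
    r_lo = max(0, top - 3 * band_h)
    r_hi = min(h, bot + 3 * band_h + 1)
    q = gaussian_filter1d(px[r_lo:r_hi].mean(axis=0), sigma=3.0)
    thr = q.min() + _COL_THR * (q.max() - q.min())
    bright = np.flatnonzero(q >= thr)
    if bright.size < 8:
        raise DetectionFailure("no bright column span near the dark band")
    x0, x1 = int(bright[0]), int(bright[-1]) + 1

    # the flanks (within the joint columns) must be the brightest structures
    fl = max(1, int(round(1.5 * band_h)))
    above_reg = px[max(0, top - fl):top, x0:x1]
    below_reg = px[bot + 1:min(h, bot + 1 + fl), x0:x1]
    if above_reg.size == 0 or below_reg.size == 0:
        raise DetectionFailure("dark band touches the image border")
    img_mean = float(px.mean())
    for reg in (above_reg, below_reg):
        if float(reg.mean()) < img_mean + 0.05 * rng_span:
            raise DetectionFailure(
                "bands flanking the joint space are not bright bone"
            )

    box_w = x1 - x0
    box_h = int(round(_BOX_ASPECT * box_w))
    rc = (top + bot) / 2.0
    y0 = int(round(rc - _BOX_SHIFT_UP * box_h))
    y1 = y0 + box_h
    y0, y1 = max(0, y0), min(h, y1)
    if y1 - y0 < 8:
        raise DetectionFailure("proposed joint box degenerate")
    return BBox(x0, y0, x1, y1)


def detect_joint_roi(
    image: GrayImage,
    provided_bbox: Optional[BBox] = None,
    detector: Optional[Callable[[GrayImage], Tuple[BBox, float]]] = None,
    margin_frac: float = 0.05,
) -> DetectionResult:
    """Locate the knee joint.  Precedence: provided box > external hook >
    intensity-profile fallback.  The returned box is expanded by ``margin_frac``
    and clipped to the image so the tibial-plateau corners stay inside the crop.
    """
    h, w = image.height, image.width
    if provided_bbox is not None:
        return DetectionResult(provided_bbox.expand(margin_frac, w, h), 1.0, "provided")
    if detector is not None:
        bbox, conf = detector(image)
        return DetectionResult(
            bbox.expand(margin_frac, w, h), float(np.clip(conf, 0.0, 1.0)), "external"
        )
    bbox = profile_roi_proposer(image)
    return DetectionResult(bbox.expand(margin_frac, w, h), 0.5, "profile_fallback")


# ---------------------------------------------------------------------------
# laterality
# ---------------------------------------------------------------------------

# On a standard AP radiograph the patient's right side appears on the image
# left; the lateral compartment of a right knee is therefore on the image left.
AP_DICOM_LATERALITY_MAP = {
    "R": LateralSide.lateral_left,
    "L": LateralSide.lateral_right,
}


def resolve_laterality(
    flag: Optional[LateralSide | str] = None,
    metadata: Optional[str] = None,
    default: LateralSide = LateralSide.lateral_left,
    metadata_map: Optional[dict] = None,
) -> Laterality:
    """Resolve which image side is lateral: flag > DICOM metadata > default."""
    mapping = AP_DICOM_LATERALITY_MAP if metadata_map is None else metadata_map
    meta_side = mapping.get(metadata) if metadata else None
    if flag is not None:
        side = LateralSide(flag)
        if meta_side is not None and meta_side != side:
            logger.warning(
                "laterality flag %s contradicts DICOM metadata %s; flag wins",
                side.value, meta_side.value,
            )
        return Laterality(side, "flag")
    if meta_side is not None:
        return Laterality(meta_side, "metadata")
    return Laterality(LateralSide(default), "default")
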