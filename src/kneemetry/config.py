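"""Pipeline configuration.

All tunables of the measurement pipeline live in one flat record.  Defaults
reproduce the constants of the published procedure this package implements:
Canny hysteresis retry groups (20, 80) then (20, 90), ruler angle 45 degrees,
border-shift steepness threshold 70 degrees.  Config files are flat
``key = value`` text; dotted keys map to underscored attribute names
(``edges.canny_groups`` -> ``edges_canny_groups``).  Unknown keys are rejected.
"""

from __future__ import annotations

import ast
import dataclasses
from pathlib import Path
from typing import Tuple

from .errors import ValidationError

# YOLOv3 detector hyperparameters reported for the original learned
# segmentation stage.  The network itself is not shipped (see imageio_roi);
# the values are retained as documented metadata only.
REFERENCE_DETECTOR_HYPERPARAMS = {
    "batch_size": 5,
    "learning_rate": 0.001,
    "epochs": 100,
    "momentum": 0.9,
}


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    # enhancement
    enhance_median_ksize: int = 3
    enhance_bm3d_sigma: float = 10.0
    enhance_min_edges: int = 10
    enhance_min_edge_len: int = 20
    # edge detection / tracing
    edges_canny_groups: Tuple[Tuple[float, float], ...] = ((20.0, 80.0), (20.0, 90.0))
    edges_min_len: int = 10
    edges_max_vertical_run: int = 12
    # landmark geometry
    landmarks_K_frac: float = 0.05
    landmarks_steep_deg: float = 70.0
    landmarks_stop_deg: float = 45.0
    landmarks_sym_tol: float = 0.15
    landmarks_sep_min_frac: float = 0.05
    landmarks_sep_max_frac: float = 0.6
    landmarks_pofb_aspect: float = 3.0
    landmarks_pofb_span_frac: float = 0.2
    landmarks_pofb_gap_frac: float = 0.10
    landmarks_pofb_min_span_frac: float = 0.30
    landmarks_smooth_window: int = 5
    landmarks_shift_cap_frac: float = 0.25
    # detection
    roi_margin_frac: float = 0.05
    # measurement
    measure_success_tol: float = 0.15
    measure_subpixel: bool = True
    # run
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        if self.enhance_median_ksize % 2 == 0 or self.enhance_median_ksize < 3:
            raise ValidationError("enhance.median_ksize must be odd and >= 3")
        if self.enhance_bm3d_sigma <= 0:
            raise ValidationError("enhance.bm3d_sigma must be > 0")
        if not self.edges_canny_groups:
            raise ValidationError("edges.canny_groups must be non-empty")
        for low, high in self.edges_canny_groups:
            if not (0 < low < high):
                raise ValidationError(
                    f"canny group ({low}, {high}): need 0 < low < high"
                )

    # -- flat key=value round-trip ------------------------------------------

    @classmethod
    def _field_names(cls):
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` config file; unknown keys are rejected."""
        kwargs = {}
        names = cls._field_names()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            attr = key.replace(".", "_")
            if attr not in names:
                raise ValidationError(f"{path}:{lineno}: unknown config key '{key}'")
            kwargs[attr] = ast.literal_eval(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            key = f.name.replace("_", ".", 1) if "_" in f.name else f.name
            lines.append(f"{key} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = RunConfig()
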