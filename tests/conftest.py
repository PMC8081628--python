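import numpy as np
import pytest

from kneemetry.edgemap import EdgePolyline, EdgeSet
from kneemetry.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom (control-range geometry, ratio 0.7)."""
    spec = PhantomSpec()
    image, truth = make_phantom(spec, seed=1)
    return spec, image, truth


@pytest.fixture(scope="session")
def worked_phantom():
    """Phantom realizing the worked-example geometry LJSD/HLTS = 1.325."""
    spec = PhantomSpec(ljsd_true=53.0, hlts_true=40.0)
    image, truth = make_phantom(spec, seed=1)
    return spec, image, truth


def edge_set_from_profiles(profiles, dims=(600, 600)):
    """Build an EdgeSet whose column profiles equal the given {x: h} maps.

    Each profile becomes one polyline with two pixels per column (the upper
    one realizes the requested height), so per-column max-height semantics
    are exercised.
    """
    H = dims[0]
    polylines = []
    for i, prof in enumerate(profiles):
        pts = []
        for x in sorted(prof):
            y = (H - 1) - int(prof[x])
            pts.extend([(x, y), (x, y + 1)])
        polylines.append(EdgePolyline(i, pts))
    return EdgeSet(polylines, dims, (20.0, 80.0))
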