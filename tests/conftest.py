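import math

import numpy as np
import pytest

from lcshift.grid import build_grid_242
from lcshift.types import LandmarkRecord, VfExam


@pytest.fixture(scope="session")
def grid():
    return build_grid_242()


def regular_polygon(n=24, r=750.0, center=(0.0, 0.0)):
    return tuple(
        (center[0] + r * math.cos(2 * math.pi * k / n),
         center[1] + r * math.sin(2 * math.pi * k / n))
        for k in range(n)
    )


def make_record(
    trunk=(300.0, 0.0),
    margin=None,
    fovea=(-3000.0, 0.0),
    laterality="right",
    **kw,
):
    return LandmarkRecord(
        eye_id=kw.pop("eye_id", "e1"),
        laterality=laterality,
        bmo_margin=margin if margin is not None else regular_polygon(),
        fovea=fovea,
        trunk=trunk,
        **kw,
    )


def make_exam(levels_by_pos=None, grid=None, eye_id="e1", visit=0, **kw):
    """Build a VfExam from a {(x_deg, y_deg): category-level} dict."""
    grid = grid or build_grid_242()
    levels_by_pos = levels_by_pos or {}
    levels = []
    for p in grid.scoreable:
        levels.append(int(levels_by_pos.get((p.x_deg, p.y_deg), 0)))
    defaults = dict(
        md_db=-5.0,
        psd_prob=0.5,
        ght="within",
        fixation_loss_rate=0.05,
        false_pos_rate=0.05,
        false_neg_rate=0.05,
    )
    defaults.update(kw)
    return VfExam(eye_id=eye_id, visit=visit, pd_levels=tuple(levels), **defaults)


def random_simple_polygon(rng: np.random.Generator, n=16, r_mean=800.0):
    """Star-shaped (hence simple) polygon with jittered radii and angles."""
    theta = np.sort(rng.uniform(0, 2 * math.pi, n))
    # enforce minimum angular gaps so no two vertices collide
    theta = (theta + np.linspace(0, 2 * math.pi, n, endpoint=False)) / 2.0
    radii = rng.uniform(0.4, 1.6, n) * r_mean
    return tuple((float(r * math.cos(t)), float(r * math.sin(t))) for r, t in zip(radii, theta))
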