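"""Shared fixtures: geometric primitives and small, fast phantom runs.

Phantom tracking fixtures are module-scoped and sized well below the
production defaults (96-pixel grids, 9 frames, 48 tracked points) so the
whole suite stays fast; the full-size composite run lives in the
acceptance tests only.
"""

from __future__ import annotations

import numpy as np
import pytest

from cinestrain import (
    ClosedContour,
    PhantomSpec,
    generate_phantom,
    track_wall,
)


def make_annulus_masks(n, r_in, r_out, center=None):
    """Dirichlet masks for a circular annulus on an n x n grid.

    The clamped sets use the half-pixel convention: a pixel belongs to the
    inner (outer) Dirichlet region when its centre lies within half a
    pixel of the continuum disk, which centres the effective discrete
    boundary on the true circle.
    """
    yy, xx = np.indices((n, n))
    c = (n - 1) / 2 if center is None else center
    r = np.hypot(xx - c, yy - c)
    b_lo = r <= r_in + 0.5
    b_hi = r >= r_out - 0.5
    domain = ~(b_lo | b_hi)
    return domain | b_lo | b_hi, b_lo, b_hi, r


def circle_contour(radius, center=(63.5, 63.5), n=180) -> ClosedContour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ClosedContour(
        np.column_stack([
            center[0] + radius * np.cos(th),
            center[1] + radius * np.sin(th),
        ])
    )


def small_spec(**overrides) -> PhantomSpec:
    """A fast phantom: 96 px grid, 0.05 mm/px, 9 frames peaking at 5."""
    kw = dict(
        image_size=96,
        spacing=0.05,
        n_frames=9,
        systolic_frame=5,
        translation=(0.0, 0.0),
        rotation_deg=0.0,
        torsion_deg=0.0,
        shear=0.0,
        lambda_min=1.0,
        mu_max=1.0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def tracked_for(spec: PhantomSpec, n_points: int = 48):
    seq = generate_phantom(spec)
    tracked = track_wall(
        seq.contours, n_points=n_points, frame_window=(1, spec.n_frames)
    )
    return spec, seq, tracked


@pytest.fixture(scope="module")
def zero_motion_run():
    return tracked_for(small_spec())


@pytest.fixture(scope="module")
def compression_run():
    return tracked_for(small_spec(lambda_min=0.8, mu_max=1.3))


@pytest.fixture(scope="module")
def rigid_run():
    # translation + rotation only: every strain curve must stay ~0
    return tracked_for(small_spec(translation=(0.15, 0.1), rotation_deg=5.0))
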