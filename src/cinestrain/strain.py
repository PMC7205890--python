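"""Lagrangian strain from Laplace-tracked wall points over the cardiac cycle.

Wall points are tracked frame to frame by solving the Laplace equation
between the contours of successive frames and following streamlines
(endocardium and epicardium independently).  The mid wall is initialized
on the gamma = 0.5 equipotential of the frame-1 endo<->epi field and then
carried as a fixed fractional position along each tracked endo-epi pair.

Strain follows the Green-Lagrange convention by default: for a material
segment of reference length L0 deformed to L,

    E = (L^2 - L0^2) / (2 L0^2),

which coincides with engineering strain (L - L0)/L0 to first order in the
displacement.  Circumferential strain uses the chord between the tracked
neighbours of each point; radial strain uses the distance between paired
points of two layers.  The first frame of the analysis window (frames
1-17 by default, where the mouse strain cycle completes) is the zero
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConfigurationError, GapError
from .laplace import ContourField

logger = logging.getLogger(__name__)

LAYERS = ("endo", "mid", "epi")
#: default analysis window (1-based, inclusive): the strain cycle of the
#: mouse heart completes within the first 17 cine frames
DEFAULT_FRAME_WINDOW = (1, 17)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrackedWall:
    """Positions of N wall points on three layers across T frames.

    ``positions[layer]`` has shape (T, N, 2) in pixel coordinates; frame
    index 0 corresponds to the first frame of ``frame_window``.
    """

    positions: dict[str, np.ndarray]
    spacing: float = 1.0
    frame_window: tuple[int, int] = DEFAULT_FRAME_WINDOW

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def n_points(self) -> int:
        return next(iter(self.positions.values())).shape[1]

    def layer(self, name: str) -> np.ndarray:
        return self.positions[name]


@dataclass
class StrainTensor2D:
    """Green-Lagrange strain components in a local 2D frame."""

    e_x1: float
    e_x2: float
    e_x1x2: float

    @property
    def e_x2x1(self) -> float:  # symmetric by construction
        return self.e_x1x2

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.e_x1, self.e_x1x2], [self.e_x1x2, self.e_x2]])


@dataclass
class StrainCurve:
    """Strain value per frame plus labelling metadata.

    ``sector_id`` 0 denotes the global (all points) curve.
    """

    values: np.ndarray
    direction: str
    layer: str
    sector_id: int = 0
    convention: str = "green-lagrange"
    n_points: int = 0
    defined: bool = True

    def normalized(self) -> np.ndarray:
        m = np.max(np.abs(self.values))
        return self.values / m if m > 0 else self.values.copy()


@dataclass
class SlopeMetrics:
    """Systolic slope S1, diastolic slope S2 and the peak of a curve.

    Slopes are two-point secants (strain per frame): S1 from the first
    analysis frame to the peak, S2 from the peak to the last frame.
    """

    s1: float
    s2: float | None
    peak: float
    peak_frame: int
    s2_defined: bool = True


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def track_wall(
    contours,
    n_points: int = 100,
    frame_window: tuple[int, int] = DEFAULT_FRAME_WINDOW,
    spacing: float = 1.0,
    **field_kw,
) -> TrackedWall:
    """Track endo/mid/epi wall points over the cycle.

    Parameters
    ----------
    contours : sequence of (endo, epi) ClosedContour pairs, one per frame
        (1-based frame f is ``contours[f-1]``); a None entry raises GapError.
    n_points : number of tracked points per layer.
    frame_window : (first, last) 1-based inclusive analysis frames.
    field_kw : forwarded to the Laplace ContourField (supersample, tol, ...).
    """
    first, last = frame_window
    if first < 1 or last > len(contours):
        raise GapError(
            f"frame window {frame_window} outside available frames 1-{len(contours)}"
        )
    window = contours[first - 1 : last]
    if len(window) < 2:
        raise GapError("tracking needs at least 2 frames")
    for i, pair in enumerate(window):
        if pair is None or pair[0] is None or pair[1] is None:
            raise GapError(f"missing contours at frame {first + i}")

    endo0_contour, epi0_contour = window[0]
    endo_pts = endo0_contour.resample(n_points)

    # frame-1 wall field: pairs endo->epi and locates the gamma=0.5 mid wall
    wall_field = ContourField(endo0_contour, epi0_contour, **field_kw)
    epi_pts, _, mid_pts = wall_field.map_points(endo_pts, record_mid=True)

    # fractional mid position along each endo-epi pair, frozen at frame 1
    chord = np.linalg.norm(epi_pts - endo_pts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_frac = np.where(
            chord > 1e-12,
            np.linalg.norm(mid_pts - endo_pts, axis=1) / chord,
            0.5,
        )

    T = len(window)
    endo = np.empty((T, n_points, 2))
    epi = np.empty((T, n_points, 2))
    mid = np.empty((T, n_points, 2))
    endo[0], epi[0], mid[0] = endo_pts, epi_pts, mid_pts

    for t in range(T - 1):
        endo_field = ContourField(window[t][0], window[t + 1][0], **field_kw)
        endo[t + 1], _, _ = endo_field.map_points(endo[t])
        epi_field = ContourField(window[t][1], window[t + 1][1], **field_kw)
        epi[t + 1], _, _ = epi_field.map_points(epi[t])
        mid[t + 1] = endo[t + 1] + w_frac[:, None] * (epi[t + 1] - endo[t + 1])

    return TrackedWall(
        positions={"endo": endo, "mid": mid, "epi": epi},
        spacing=spacing,
        frame_window=frame_window,
    )


# ---------------------------------------------------------------------------
# strain
# ---------------------------------------------------------------------------

def lagrangian_tensor(ref_triple, def_triple) -> StrainTensor2D:
    """Green-Lagrange tensor from a local point triple before/after motion.

    The triple is (origin, point along x1, point along x2); the reference
    difference vectors span the local frame, F maps them onto the deformed
    ones, and E = (F^T F - I)/2.
    """
    ref = np.asarray(ref_triple, dtype=float)
    dfm = np.asarray(def_triple, dtype=float)
    u = np.column_stack([ref[1] - ref[0], ref[2] - ref[0]])
    v = np.column_stack([dfm[1] - dfm[0], dfm[2] - dfm[0]])
    if abs(np.linalg.det(u)) < 1e-12 * max(1.0, np.abs(u).max() ** 2):
        raise DegenerateConfigurationError("reference triple is collinear")
    f = v @ np.linalg.inv(u)
    e = 0.5 * (f.T @ f - np.eye(2))
    return StrainTensor2D(e_x1=e[0, 0], e_x2=e[1, 1], e_x1x2=0.5 * (e[0, 1] + e[1, 0]))


def _length_strain(l_t: np.ndarray, l_0: np.ndarray, convention: str) -> np.ndarray:
    if convention == "green-lagrange":
        return (l_t**2 - l_0**2) / (2.0 * l_0**2)
    if convention == "engineering":
        return (l_t - l_0) / l_0
    raise ValueError(f"unknown strain convention {convention!r}")


def _neighbor_lengths(pos: np.ndarray) -> np.ndarray:
    """Chord length between the two circular neighbours of each point;
    pos has shape (T, N, 2) and the result (T, N)."""
    nxt = np.roll(pos, -1, axis=1)
    prv = np.roll(pos, 1, axis=1)
    return np.linalg.norm(nxt - prv, axis=2)


def pointwise_circumferential(
    tracked: TrackedWall, layer: str, convention: str = "green-lagrange"
) -> np.ndarray:
    """Per-point circumferential strain, shape (T, N); frame 0 is zero."""
    lengths = _neighbor_lengths(tracked.layer(layer))
    return _length_strain(lengths, lengths[0][None, :], convention)

def pointwise_radial(
    tracked: TrackedWall, layer_pair=("endo", "mid"), convention: str = "green-lagrange"
) -> np.ndarray:
    """Per-point radial strain from inter-layer pair distances, shape (T, N)."""
    a = tracked.layer(layer_pair[0])
    b = tracked.layer(layer_pair[1])
    d = np.linalg.norm(b - a, axis=2)
    d0 = d[0][None, :]
    if np.any(d0 <= 1e-12):
        raise DegenerateConfigurationError("zero reference inter-layer distance")
    return _length_strain(d, d0, convention)


def circumferential_strain(
    tracked: TrackedWall, layer: str = "mid", convention: str = "green-lagrange"
) -> StrainCurve:
    """Global circumferential strain curve for one wall layer (mean over
    pointwise strains; negative during systole)."""
    pw = pointwise_circumferential(tracked, layer, convention)
    return StrainCurve(
        values=pw.mean(axis=1),
        direction="circumferential",
        layer=layer,
        convention=convention,
        n_points=tracked.n_points,
    )


def radial_strain(
    tracked: TrackedWall,
    layer_pair=("endo", "mid"),
    convention: str = "green-lagrange",
) -> StrainCurve:
    """Global radial strain curve between two layers ("inner" radial is
    endo-mid, "outer" is mid-epi; positive during systolic thickening)."""
    if tuple(layer_pair) not in {("endo", "mid"), ("mid", "epi")}:
        raise ValueError("layer_pair must be (endo, mid) or (mid, epi)")
    pw = pointwise_radial(tracked, layer_pair, convention)
    return StrainCurve(
        values=pw.mean(axis=1),
        direction="radial",
        layer="-".join(layer_pair),
        convention=convention,
        n_points=tracked.n_points,
    )


def sector_strain(
    tracked: TrackedWall,
    level: str = "mid-cavity",
    reference_angle: float = 0.0,
    layer: str = "mid",
    direction: str = "circumferential",
    layer_pair=("endo", "mid"),
    convention: str = "green-lagrange",
    min_points: int = 3,
) -> list[StrainCurve]:
    """Per-sector strain curves (6 at basal/mid-cavity, 4 apical).

    Points are binned by angle about the frame-1 cavity centroid,
    counterclockwise from ``reference_angle``; bin membership is frozen at
    frame 1.  Undersized sectors are flagged undefined.
    """
    from .ventriculo import assign_sectors, sectors_at_level

    if direction == "circumferential":
        pw = pointwise_circumferential(tracked, layer, convention)
        ref_pts = tracked.layer(layer)[0]
        label = layer
    elif direction == "radial":
        pw = pointwise_radial(tracked, layer_pair, convention)
        ref_pts = tracked.layer(layer_pair[0])[0]
        label = "-".join(layer_pair)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    centroid = tracked.layer("endo")[0].mean(axis=0)
    ids = assign_sectors(ref_pts, centroid, level, reference_angle)
    curves = []
    for sid in sectors_at_level(level):
        sel = ids == sid
        if sel.sum() < min_points:
            logger.warning("sector %d has %d point(s); flagged undefined",
                           sid, int(sel.sum()))
            curves.append(StrainCurve(
                values=np.full(tracked.n_frames, np.nan),
                direction=direction, layer=label, sector_id=sid,
                convention=convention, n_points=int(sel.sum()), defined=False,
            ))
            continue
        curves.append(StrainCurve(
            values=pw[:, sel].mean(axis=1),
            direction=direction, layer=label, sector_id=sid,
            convention=convention, n_points=int(sel.sum()),
        ))
    return curves


# ---------------------------------------------------------------------------
# slope metrics
# ---------------------------------------------------------------------------

def slope_metrics(curve, least_squares: bool = False) -> SlopeMetrics:
    """S1/S2 secant slopes and peak of a strain curve.

    The peak is the extremum of \\|strain\\| (serving both the negative
    circumferential and positive radial curves); S1 is the secant from the
    first frame to the peak and S2 from the peak to the last analysis
    frame.  With ``least_squares=True`` slopes are least-squares fits over
    the same frame ranges instead.  A peak on the window boundary leaves
    S2 (or S1) undefined and flagged.
    """
    values = curve.values if isinstance(curve, StrainCurve) else np.asarray(curve, float)
    if len(values) < 3:
        raise ValueError("slope metrics need a curve with at least 3 frames")
    k = int(np.argmax(np.abs(values)))
    peak = float(values[k])

    def slope(i0: int, i1: int) -> float:
        if least_squares:
            xs = np.arange(i0, i1 + 1)
            return float(np.polyfit(xs, values[i0 : i1 + 1], 1)[0])
        return float((values[i1] - values[i0]) / (i1 - i0))

    s1 = slope(0, k) if k > 0 else 0.0
    if k == len(values) - 1 or k == 0:
        logger.warning("monotone curve: peak on the window boundary, S2 undefined")
        return SlopeMetrics(s1=s1, s2=None, peak=peak, peak_frame=k + 1,
                            s2_defined=False)
    return SlopeMetrics(
        s1=s1, s2=slope(k, len(values) - 1), peak=peak, peak_frame=k + 1
    )
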