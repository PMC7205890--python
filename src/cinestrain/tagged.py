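"""Template tracking of myocardial points in tagged-MRI sequences.

Tagged MRI imprints a saturation grid on the myocardium; following the
grid's deformation reveals tissue motion.  Each seeded point is tracked
frame to frame by taking the 3x3 intensity template around its current
position in frame n and finding the 3x3 patch of maximum normalized
(Pearson) cross-correlation inside the 5x5 search window of frame n+1,
i.e. integer displacements of at most +-1 pixel per axis per frame for
the default window sizes.  Pearson correlation makes the match invariant
to the overall intensity drift of fading tags.  Strain curves are then
assembled from the tracked points with the same Lagrangian formulas used
for the cine pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .strain import StrainCurve, _length_strain

logger = logging.getLogger(__name__)

DEFAULT_TEMPLATE = 3
DEFAULT_SEARCH = 5


@dataclass
class TaggedSequence:
    """Grayscale frame stack with isotropic pixel spacing (mm/px)."""

    frames: np.ndarray  # (T, H, W)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("tagged sequence needs >= 2 frames of equal shape")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PointTrack:
    """Integer-pixel trajectory of one tracked point.

    ``scores[t]`` is the winning correlation for the step t -> t+1; a
    track that drifts too close to the border is truncated and flagged.
    """

    positions: np.ndarray        # (T, 2) int, (x, y)
    scores: np.ndarray           # (T-1,) in [-1, 1] (nan where degenerate)
    truncated: bool = False
    truncated_at: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def _best_displacement(
    template: np.ndarray, window: np.ndarray, radius: int
) -> tuple[int, int, float, np.ndarray]:
    """Argmax-correlation displacement inside the search window.

    Ties are broken by the smallest displacement magnitude, then row-major
    (dy, dx) order, which is deterministic and motion-minimizing.  Also
    returns the full (2r+1, 2r+1) score grid for subpixel refinement.
    """
    t = template.shape[0]
    grid = np.full((2 * radius + 1, 2 * radius + 1), np.nan)
    candidates = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            patch = window[
                dy + radius : dy + radius + t, dx + radius : dx + radius + t
            ]
            score = _pearson(template, patch)
            grid[dy + radius, dx + radius] = score
            candidates.append((dx, dy, score))
    if np.all(np.isnan(grid)):
        return 0, 0, np.nan, grid
    best = np.nanmax(grid)
    ties = [c for c in candidates if not np.isnan(c[2]) and c[2] >= best - 1e-12]
    ties.sort(key=lambda c: (c[0] ** 2 + c[1] ** 2, c[1], c[0]))
    return ties[0][0], ties[0][1], ties[0][2], grid


def _refine_displacement(
    template: np.ndarray,
    next_crop: np.ndarray,
    center: tuple[float, float],
    start: tuple[float, float],
    bound: float,
) -> tuple[float, float, float]:
    """Continuous refinement of an integer displacement: maximize the
    Pearson correlation of the template against a spline-resampled patch
    of the next frame as a function of the fractional displacement.

    ``next_crop`` must already be spline-prefiltered; ``center`` is the
    current (x, y) position in crop coordinates.  Returns (ex, ey, score).
    """
    from scipy.ndimage import map_coordinates
    from scipy.optimize import minimize

    half = template.shape[0] // 2
    offs = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")

    def neg_ncc(e):
        if max(abs(e[0]), abs(e[1])) > bound:
            return 1.0
        coords = np.vstack([
            (center[1] + e[1] + oy).ravel(),
            (center[0] + e[0] + ox).ravel(),
        ])
        patch = map_coordinates(next_crop, coords, order=3, prefilter=False)
        r = _pearson(template, patch)
        return 1.0 if np.isnan(r) else -r

    res = minimize(
        neg_ncc, list(start), method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 80},
    )
    return float(res.x[0]), float(res.x[1]), float(-res.fun)


def track_point(
    seq: TaggedSequence,
    start,
    template_size: int = DEFAULT_TEMPLATE,
    search_size: int = DEFAULT_SEARCH,
    subpixel: bool = False,
) -> PointTrack:
    """Track one point through the sequence by window correlation.

    With ``subpixel=True`` the accumulated position is kept fractional:
    template and search window are sampled by cubic spline interpolation
    at the exact fractional position, the integer argmax is found as
    usual, and the displacement is then refined by maximizing the
    correlation as a continuous function of the fractional shift.  Plain
    integer tracking rounds every step to the pixel grid, so a steady
    sub-pixel drift accumulates as a persistent bias; the fractional
    variant removes it for per-frame motion within the search radius.
    """
    if template_size % 2 == 0 or search_size % 2 == 0:
        raise ValueError("template_size and search_size must be odd")
    if template_size >= search_size:
        raise ValueError("template_size must be smaller than search_size")
    frames = seq.frames
    T, H, W = frames.shape
    ht = template_size // 2
    hs = search_size // 2
    radius = (search_size - template_size) // 2

    fx, fy = float(start[0]), float(start[1])
    x, y = int(round(fx)), int(round(fy))
    margin = hs + 3 if subpixel else hs  # spline sampling needs extra support
    if not (margin <= x < W - margin and margin <= y < H - margin):
        raise ValueError("start point too close to the image border")

    positions = [(fx, fy) if subpixel else (x, y)]
    scores = []
    truncated = False
    truncated_at = None

    def _frac_patch(filtered: np.ndarray, cx: float, cy: float, half: int):
        from scipy.ndimage import map_coordinates

        offs = np.arange(-half, half + 1)
        ry, rx = np.meshgrid(cy + offs, cx + offs, indexing="ij")
        return map_coordinates(
            filtered, np.vstack([ry.ravel(), rx.ravel()]),
            order=3, prefilter=False,
        ).reshape(2 * half + 1, 2 * half + 1)

    for n in range(T - 1):
        if subpixel:
            from scipy.ndimage import spline_filter

            sl = (slice(y - margin, y + margin + 1),
                  slice(x - margin, x + margin + 1))
            crop_n = spline_filter(frames[n][sl], output=np.float64)
            crop_n1 = spline_filter(frames[n + 1][sl], output=np.float64)
            cx, cy = fx - (x - margin), fy - (y - margin)
            template = _frac_patch(crop_n, cx, cy, ht)
            window = _frac_patch(crop_n1, cx, cy, hs)
        else:
            template = frames[n, y - ht : y + ht + 1, x - ht : x + ht + 1]
            window = frames[n + 1, y - hs : y + hs + 1, x - hs : x + hs + 1]
        if np.ptp(template) < 1e-12:
            logger.warning(
                "zero-variance template at frame %d, point (%d, %d); "
                "keeping zero displacement", n + 1, x, y,
            )
            dx = dy = 0
            score = np.nan
        else:
            dx, dy, score, _grid = _best_displacement(template, window, radius)
            if np.isnan(score):
                logger.warning(
                    "all candidate patches degenerate at frame %d; "
                    "keeping zero displacement", n + 1,
                )
                dx = dy = 0
        if subpixel:
            if not np.isnan(score):
                ex, ey, refined = _refine_displacement(
                    template, crop_n1, (cx, cy), (dx, dy), bound=radius + 0.6
                )
                if refined >= score:
                    dx, dy, score = ex, ey, refined
            fx, fy = fx + dx, fy + dy
            x, y = int(round(fx)), int(round(fy))
            positions.append((fx, fy))
        else:
            x, y = x + dx, y + dy
            positions.append((x, y))
        scores.append(score)
        if not (margin <= x < W - margin and margin <= y < H - margin):
            truncated = True
            truncated_at = n + 1
            logger.warning("track left the trackable region at frame %d", n + 2)
            break

    return PointTrack(
        positions=np.asarray(positions, dtype=float if subpixel else int),
        scores=np.asarray(scores, dtype=float),
        truncated=truncated,
        truncated_at=truncated_at,
    )


def track_points(seq: TaggedSequence, seeds, **kw) -> list[PointTrack]:
    """Track several seed points; see :func:`track_point`."""
    return [track_point(seq, s, **kw) for s in seeds]


def select_seeds(
    frame: np.ndarray,
    candidates,
    n_seeds: int,
    min_separation: float = 10.0,
    patch_half: int = 2,
) -> list[tuple[float, float]]:
    """Pick trackable seed points from candidate positions.

    Stands in for the expert who marks points on the first frame: a
    candidate is scored by the weaker of its local gradient energies along
    the two axes (both must be textured, or the window matcher faces an
    aperture ambiguity), and the best-scoring candidates are kept subject
    to a minimum mutual separation.  Candidate order is preserved only
    through the deterministic score ranking.
    """
    frame = np.asarray(frame, dtype=float)
    scored = []
    for cx, cy in candidates:
        x, y = int(round(cx)), int(round(cy))
        if not (
            patch_half <= x < frame.shape[1] - patch_half
            and patch_half <= y < frame.shape[0] - patch_half
        ):
            continue
        patch = frame[y - patch_half : y + patch_half + 1,
                      x - patch_half : x + patch_half + 1]
        gy, gx = np.gradient(patch)
        scored.append((min(float(np.sum(gx**2)), float(np.sum(gy**2))), cx, cy))
    scored.sort(reverse=True)
    chosen: list[tuple[float, float]] = []
    for _q, cx, cy in scored:
        if all(np.hypot(cx - sx, cy - sy) >= min_separation for sx, sy in chosen):
            chosen.append((cx, cy))
        if len(chosen) == n_seeds:
            break
    return chosen


def strain_from_tracks(
    tracks: list[PointTrack],
    topology="ring",
    convention: str = "green-lagrange",
    layer: str = "tagged",
) -> StrainCurve:
    """Strain curve from tracked tagged points (frame 1 reference).

    ``topology="ring"`` treats the tracks as an ordered circumferential
    ring (>= 3 tracks) and uses the neighbour-chord lengths;
    a list of (i, j) index pairs computes radial strain from the pair
    distances (>= 1 pair).  Truncated tracks shorten the curve to the
    earliest truncation frame.
    """
    if not tracks:
        raise ValueError("no tracks given")
    T = min(t.n_frames for t in tracks)
    pos = np.stack([t.positions[:T] for t in tracks], axis=1).astype(float)  # (T, K, 2)

    if isinstance(topology, str) and topology == "ring":
        if pos.shape[1] < 3:
            raise ValueError("circumferential strain needs >= 3 tracks")
        nxt = np.roll(pos, -1, axis=1)
        prv = np.roll(pos, 1, axis=1)
        lengths = np.linalg.norm(nxt - prv, axis=2)
        direction = "circumferential"
    else:
        pairs = np.asarray(list(topology), dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 1:
            raise ValueError("radial topology must be a list of (i, j) pairs")
        lengths = np.linalg.norm(
            pos[:, pairs[:, 1], :] - pos[:, pairs[:, 0], :], axis=2
        )
        direction = "radial"

    l0 = lengths[0][None, :]
    if np.any(l0 <= 0):
        raise ValueError("zero reference length between paired tracks")
    pw = _length_strain(lengths, l0, convention)
    return StrainCurve(
        values=pw.mean(axis=1),
        direction=direction,
        layer=layer,
        convention=convention,
        n_points=pos.shape[1],
    )
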