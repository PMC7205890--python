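"""Laplace-equation point correspondence between closed boundaries.

The left-ventricular wall (or the thin band swept by a contour between two
cine frames) is treated as a conductor between two Dirichlet boundaries:
the inner/earlier boundary is clamped to potential 0 and the outer/later
boundary to 1.  The harmonic potential gamma solving

    d2(gamma)/dx2 + d2(gamma)/dy2 = 0

is computed with the second-order central-difference stencil iterated by
the Jacobi method, so that at the fixed point every interior pixel is the
average of its four neighbours.  Streamlines of the potential -- curves
everywhere orthogonal to the equipotential lines -- connect each point of
one boundary to a unique point of the other, which gives both wall
thickness (endo -> epi) and frame-to-frame wall tracking (contour at t ->
contour at t+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient
from skimage.draw import polygon2mask

from .errors import (
    DegenerateDomainError,
    InvalidGeometryError,
    TracingStalledError,
)

logger = logging.getLogger(__name__)

#: convergence tolerance on the max per-pixel change in one sweep
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000
#: fixed Euler step for streamline integration, in pixels
DEFAULT_STEP = 0.25
#: contour rasterization super-sampling factor
DEFAULT_SUPERSAMPLE = 2
#: gamma termination band: a streamline stops once gamma >= 1 - EPS_GAMMA
EPS_GAMMA = 1e-2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PotentialGrid:
    """Converged (or best-effort) solution of the Laplace problem.

    ``values`` holds gamma in [0, 1]; ``domain_mask`` flags the interior
    pixels that were updated; the two boundary masks carry the Dirichlet
    values 0 and 1.  ``spacing`` is (dx, dy) in mm per pixel.
    """

    values: np.ndarray
    domain_mask: np.ndarray
    boundary_low: np.ndarray
    boundary_high: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    converged: bool = True
    n_iter: int = 0
    residual: float = 0.0


@dataclass
class ClosedContour:
    """Simple closed polygon in pixel coordinates (x = column, y = row).

    Points are stored counterclockwise in the (x right, y down) raster
    convention used throughout the package.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidGeometryError("contour points must be an (N, 2) array")
        # drop an explicitly repeated closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            raise InvalidGeometryError(
                f"contour needs at least 8 points, got {len(pts)}"
            )
        if np.any(np.all(np.isclose(np.diff(pts, axis=0), 0.0), axis=1)):
            raise InvalidGeometryError("consecutive contour points must be distinct")
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidGeometryError("contour must be a simple polygon")
        # normalize to counterclockwise orientation (shapely CCW == positive
        # signed area, which in the raster y-down convention appears clockwise
        # on screen; the convention only needs to be consistent)
        pts = np.asarray(orient(poly, sign=1.0).exterior.coords)[:-1]
        self.points = pts

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def resample(self, n_points: int) -> np.ndarray:
        """Resample to ``n_points`` equally spaced by arc length."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        targets = np.linspace(0.0, total, n_points, endpoint=False)
        x = np.interp(targets, cum, pts[:, 0])
        y = np.interp(targets, cum, pts[:, 1])
        return np.column_stack([x, y])


@dataclass
class CorrespondenceMap:
    """Streamline pairing between two contours.

    ``source_points[k]`` maps to ``target_points[k]``; ``lengths`` are
    streamline arc lengths in the same units as the contour coordinates
    (multiply by the pixel spacing for mm).
    """

    source_points: np.ndarray
    target_points: np.ndarray
    lengths: np.ndarray
    source_contour_id: str = "source"
    target_contour_id: str = "target"
    midpoints: np.ndarray | None = None  # gamma = 0.5 crossings, if recorded

    def __len__(self) -> int:
        return len(self.source_points)


# ---------------------------------------------------------------------------
# Jacobi solver
# ---------------------------------------------------------------------------

def _neighbor_average(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean of the 4 neighbours, substituting the centre value where a
    neighbour falls outside the valid region (reflecting/Neumann closure)."""
    total = np.zeros_like(values)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(values, shift, axis=axis)
        nb_ok = np.roll(valid, shift, axis=axis)
        total += np.where(nb_ok, nb, values)
    return total * 0.25


def solve_laplace(
    domain_mask: np.ndarray,
    boundary_low: np.ndarray,
    boundary_high: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    method: str = "jacobi",
    spacing: tuple[float, float] = (1.0, 1.0),
) -> PotentialGrid:
    """Solve the Dirichlet problem between two boundaries.

    Parameters
    ----------
    domain_mask : bool array
        Interior pixels to relax.
    boundary_low, boundary_high : bool arrays
        Pixels clamped to 0 and 1 respectively.
    tol : float
        Stop once the max per-pixel change in a sweep is <= tol.
    max_iter : int
        Sweep cap; reaching it is reported via ``converged=False``.
    method : {"jacobi", "redblack"}
        Plain Jacobi (the reference iteration) or checkerboard
        Gauss-Seidel, which converges to the same fixed point faster.
    """
    domain_mask = np.asarray(domain_mask, dtype=bool)
    boundary_low = np.asarray(boundary_low, dtype=bool)
    boundary_high = np.asarray(boundary_high, dtype=bool)
    if tol <= 0:
        raise ValueError("tol must be positive")
    if np.any(boundary_low & boundary_high):
        raise InvalidGeometryError("low and high boundaries overlap")
    interior = domain_mask & ~boundary_low & ~boundary_high
    if not interior.any():
        raise DegenerateDomainError("empty interior between the boundaries")
    valid = interior | boundary_low | boundary_high
    # each boundary must touch the solve region
    for name, bnd in (("low", boundary_low), ("high", boundary_high)):
        grown = np.zeros_like(bnd)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            grown |= np.roll(bnd, shift, axis=axis)
        if not (grown & interior).any():
            raise InvalidGeometryError(f"{name} boundary does not touch the domain")

    # crop to the bounding box (+1 guard ring so np.roll never wraps content)
    rows, cols = np.nonzero(valid)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    pad = 1
    shape = (r1 - r0 + 2 * pad, c1 - c0 + 2 * pad)
    sl = (slice(pad, pad + r1 - r0), slice(pad, pad + c1 - c0))

    def crop(a: np.ndarray, fill=False) -> np.ndarray:
        out = np.full(shape, fill, dtype=a.dtype)
        out[sl] = a[r0:r1, c0:c1]
        return out

    v = crop(valid)
    inter = crop(interior)
    blo = crop(boundary_low)
    bhi = crop(boundary_high)

    g = np.zeros(shape, dtype=np.float64)
    g[bhi] = 1.0
    g[inter] = 0.5

    n_iter = 0
    residual = np.inf
    if method == "jacobi":
        while n_iter < max_iter:
            avg = _neighbor_average(g, v)
            new = np.where(inter, avg, g)
            residual = float(np.max(np.abs(new - g))) if inter.any() else 0.0
            g = new
            n_iter += 1
            if residual <= tol:
                break
    elif method == "redblack":
        rr, cc = np.indices(shape)
        red = inter & ((rr + cc) % 2 == 0)
        black = inter & ~red
        while n_iter < max_iter:
            old = g.copy()
            for color in (red, black):
                avg = _neighbor_average(g, v)
                g = np.where(color, avg, g)
            residual = float(np.max(np.abs(g - old)))
            n_iter += 1
            if residual <= tol:
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    converged = residual <= tol
    if not converged:
        logger.warning(
            "Laplace solve hit max_iter=%d (residual %.3g > tol %.3g)",
            max_iter, residual, tol,
        )

    full = np.zeros(domain_mask.shape, dtype=np.float64)
    full[boundary_high] = 1.0
    full[r0:r1, c0:c1] = g[sl]
    # fill pixels outside the problem with their nearest valid value so
    # interpolated gradients near thin boundaries are not contaminated
    if not valid.all():
        from scipy.ndimage import distance_transform_edt

        _, idx = distance_transform_edt(~valid, return_indices=True)
        full = full[idx[0], idx[1]]
    return PotentialGrid(
        values=full,
        domain_mask=interior,
        boundary_low=boundary_low,
        boundary_high=boundary_high,
        spacing=spacing,
        converged=converged,
        n_iter=n_iter,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# streamline tracing
# ---------------------------------------------------------------------------

@dataclass
class Streamline:
    """Traced path, its arc length, and gamma sampled along it."""

    path: np.ndarray          # (M, 2) x, y
    length: float
    gammas: np.ndarray        # (M,)
    stalled: bool = False

    @property
    def endpoint(self) -> np.ndarray:
        return self.path[-1]

    def crossing(self, level: float) -> np.ndarray | None:
        """Interpolated point where gamma first crosses ``level``."""
        g = self.gammas
        inc = g[-1] >= g[0]
        for i in range(len(g) - 1):
            lo, hi = sorted((g[i], g[i + 1]))
            if lo <= level <= hi and not np.isclose(lo, hi):
                f = (level - g[i]) / (g[i + 1] - g[i])
                return self.path[i] + f * (self.path[i + 1] - self.path[i])
        # level outside the traced range
        if (inc and level <= g[0]) or (not inc and level >= g[0]):
            return self.path[0]
        return None


class _FieldSampler:
    """Bilinear samplers for gamma, its gradient and the boundary masks."""

    def __init__(self, potential: PotentialGrid):
        vals = potential.values
        gy, gx = np.gradient(vals)
        self._vals = vals
        self._gx, self._gy = gx, gy
        self._blo = potential.boundary_low.astype(float)
        self._bhi = potential.boundary_high.astype(float)

    def gamma(self, pts: np.ndarray) -> np.ndarray:
        coords = np.vstack([pts[:, 1], pts[:, 0]])
        return map_coordinates(self._vals, coords, order=1, mode="nearest")

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        coords = np.vstack([pts[:, 1], pts[:, 0]])
        gx = map_coordinates(self._gx, coords, order=1, mode="nearest")
        gy = map_coordinates(self._gy, coords, order=1, mode="nearest")
        return np.column_stack([gx, gy])

    def on_boundary(self, pts: np.ndarray, direction: int) -> bool:
        mask = self._bhi if direction > 0 else self._blo
        coords = np.vstack([pts[:, 1], pts[:, 0]])
        return bool(map_coordinates(mask, coords, order=1, mode="nearest")[0] >= 0.5)


def trace_streamline(
    potential: PotentialGrid,
    seed,
    step: float = DEFAULT_STEP,
    direction: int = +1,
    eps: float = EPS_GAMMA,
    max_steps: int | None = None,
) -> Streamline:
    """Integrate along the (normalized) potential gradient from ``seed``.

    Fixed-step Euler with bilinear gradient interpolation.  With
    ``direction=+1`` the path ascends until gamma >= 1 - eps; with
    ``direction=-1`` it descends until gamma <= eps.  The final point is
    linearly extrapolated to the exact 0/1 level so endpoint and length
    carry sub-step accuracy.
    """
    return _trace(
        _FieldSampler(potential), potential.values.shape, seed,
        step=step, direction=direction, eps=eps, max_steps=max_steps,
    )


def _trace(
    sampler: "_FieldSampler",
    shape: tuple[int, int],
    seed,
    step: float = DEFAULT_STEP,
    direction: int = +1,
    eps: float = EPS_GAMMA,
    max_steps: int | None = None,
) -> Streamline:
    p = np.asarray(seed, dtype=float).reshape(1, 2)
    h, w = shape
    if max_steps is None:
        max_steps = int(20 * (h + w) / step)

    path = [p[0].copy()]
    gammas = [float(sampler.gamma(p)[0])]
    length = 0.0
    stalled_steps = 0
    target = 1.0 - eps if direction > 0 else eps

    for _ in range(max_steps):
        g_here = gammas[-1]
        if (direction > 0 and g_here >= target) or (
            direction < 0 and g_here <= target
        ):
            break
        if len(path) > 1 and sampler.on_boundary(p, direction):
            break  # crossed onto the far Dirichlet boundary itself
        grad = sampler.gradient(p)[0]
        norm = np.hypot(grad[0], grad[1])
        if norm < 1e-12:
            stalled_steps += 1
            if stalled_steps >= 10:
                raise TracingStalledError(
                    f"zero gradient near {tuple(p[0])}: flat potential region"
                )
            continue
        stalled_steps = 0
        p = p + direction * step * grad[None, :] / norm
        p[0, 0] = np.clip(p[0, 0], 0, w - 1)
        p[0, 1] = np.clip(p[0, 1], 0, h - 1)
        length += step
        path.append(p[0].copy())
        gammas.append(float(sampler.gamma(p)[0]))
    else:
        logger.warning("streamline exceeded %d steps without terminating", max_steps)

    # extrapolate the last step to the exact Dirichlet level
    if len(path) >= 2:
        g1, g2 = gammas[-2], gammas[-1]
        goal = 1.0 if direction > 0 else 0.0
        if not np.isclose(g2, g1):
            f = (goal - g2) / (g2 - g1)
            f = float(np.clip(f, 0.0, 1.0))
            if f > 0:
                tail = path[-1] - path[-2]
                path.append(path[-1] + f * tail)
                gammas.append(goal)
                length += f * np.linalg.norm(tail)

    return Streamline(
        path=np.asarray(path),
        length=length,
        gammas=np.asarray(gammas),
    )


# ---------------------------------------------------------------------------
# contour correspondence
# ---------------------------------------------------------------------------

class ContourField:
    """Laplace field between two contours with point-mapping utilities.

    The solve region is the symmetric band between the two filled
    polygons: their intersection is clamped to 0 and everything outside
    their union to 1.  For nested contours this is exactly the annulus
    between them; for slightly crossing frame-to-frame contours it is the
    symmetric-difference band (a warning is logged).

    The grid is super-sampled by ``supersample`` to reduce staircase bias
    in the thin mouse wall; all returned coordinates and lengths are in
    the original (native) pixel units.
    """

    def __init__(
        self,
        source: ClosedContour,
        target: ClosedContour,
        supersample: int = DEFAULT_SUPERSAMPLE,
        grid_margin: int = 4,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        method: str = "jacobi",
        step: float = DEFAULT_STEP,
    ):
        self.source = source
        self.target = target
        self.scale = supersample
        self.step = step

        src_poly = source.polygon
        tgt_poly = target.polygon
        self.identical = src_poly.symmetric_difference(tgt_poly).area < 1e-9
        self._target_ring = LineString(
            np.vstack([target.points, target.points[:1]])
        )
        self._tgt_poly = tgt_poly

        if self.identical:
            self.potential = None
            return

        nested = src_poly.contains(tgt_poly) or tgt_poly.contains(src_poly)
        if not nested:
            logger.warning(
                "contours are not nested; using the symmetric band between them"
            )

        all_pts = np.vstack([source.points, target.points])
        lo = np.floor(all_pts.min(axis=0)) - grid_margin
        hi = np.ceil(all_pts.max(axis=0)) + grid_margin
        self.origin = lo  # native-pixel coordinate of grid pixel (0, 0)
        shape = (
            int((hi[1] - lo[1]) * supersample) + 1,
            int((hi[0] - lo[0]) * supersample) + 1,
        )

        def rasterize(c: ClosedContour) -> np.ndarray:
            rc = np.column_stack([
                (c.points[:, 1] - lo[1]) * supersample,
                (c.points[:, 0] - lo[0]) * supersample,
            ])
            return polygon2mask(shape, rc)

        a = rasterize(source)
        b = rasterize(target)
        low = a & b
        high = ~(a | b)
        domain = (a | b) & ~low
        if not domain.any():
            raise DegenerateDomainError(
                "contours rasterize to the same region; no band to solve on"
            )
        self.potential = solve_laplace(
            domain | low | high, low, high, tol=tol, max_iter=max_iter, method=method
        )
        self._sampler = _FieldSampler(self.potential)

    # -- coordinate helpers ------------------------------------------------
    def to_grid(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) * self.scale

    def to_native(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) / self.scale + self.origin

    # -- mapping -----------------------------------------------------------
    def map_points(
        self, pts: np.ndarray, record_mid: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Trace one streamline per point; return endpoints on the target
        contour, arc lengths (native px) and optionally the gamma = 0.5
        crossing points."""
        pts = np.asarray(pts, dtype=float)
        n = len(pts)
        if self.identical:
            mids = pts.copy() if record_mid else None
            return pts.copy(), np.zeros(n), mids

        endpoints = np.empty_like(pts)
        lengths = np.empty(n)
        mids = np.empty_like(pts) if record_mid else None
        inside = np.array(
            [self._tgt_poly.contains(Point(*p)) for p in pts], dtype=bool
        )
        for k, p in enumerate(pts):
            direction = +1 if inside[k] else -1
            try:
                # step is interpreted on the super-sampled grid
                sl = _trace(
                    self._sampler,
                    self.potential.values.shape,
                    self.to_grid(p),
                    step=self.step,
                    direction=direction,
                )
                path = self.to_native(sl.path)
                mid_grid = sl.crossing(0.5) if record_mid else None
            except TracingStalledError:
                path, mid_grid = p.reshape(1, 2), None
                logger.warning(
                    "streamline stalled at %s; projecting to nearest target point",
                    tuple(np.round(p, 2)),
                )
            end, length = self._terminate_on_target(path, inside[k])
            endpoints[k] = end
            lengths[k] = length
            if record_mid:
                if mid_grid is None:
                    mids[k] = 0.5 * (p + end)
                else:
                    mids[k] = self.to_native(mid_grid)
        return endpoints, lengths, mids

    def _terminate_on_target(
        self, path: np.ndarray, started_inside: bool
    ) -> tuple[np.ndarray, float]:
        """Cut the traced path at its exact crossing of the target contour
        (the Dirichlet level only approximates it at grid resolution); if
        the trace stopped short, extend it to the nearest target point."""
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if len(path) > 1:
            import shapely

            inside = shapely.contains_xy(self._tgt_poly, path[:, 0], path[:, 1])
            crossing = np.nonzero(inside[1:] != started_inside)[0]
            for i in crossing:
                segment = LineString([path[i], path[i + 1]])
                hit = segment.intersection(self._target_ring)
                if hit.is_empty:
                    continue
                if hit.geom_type != "Point":  # multiple hits: take the first
                    hit = min(
                        (g for g in getattr(hit, "geoms", [hit])),
                        key=lambda g: Point(*path[i]).distance(g),
                    )
                q = np.array([hit.x, hit.y])
                return q, float(cum[i] + np.linalg.norm(q - path[i]))
        # no clean crossing: project the final point onto the target ring
        proj = self._target_ring.interpolate(
            self._target_ring.project(Point(*path[-1]))
        )
        q = np.array([proj.x, proj.y])
        return q, float(cum[-1] + np.linalg.norm(q - path[-1]))


def correspond_contours(
    source: ClosedContour,
    target: ClosedContour,
    n_points: int = 100,
    grid_margin: int = 4,
    supersample: int = DEFAULT_SUPERSAMPLE,
    record_mid: bool = False,
    **solver_kw,
) -> CorrespondenceMap:
    """Pair ``n_points`` arc-length-resampled source points with target
    points via Laplace streamlines (inner boundary 0, outer boundary 1)."""
    seeds = source.resample(n_points)
    fieldobj = ContourField(
        source, target, supersample=supersample, grid_margin=grid_margin, **solver_kw
    )
    endpoints, lengths, mids = fieldobj.map_points(seeds, record_mid=record_mid)
    return CorrespondenceMap(
        source_points=seeds,
        target_points=endpoints,
        lengths=lengths,
        midpoints=mids,
    )
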