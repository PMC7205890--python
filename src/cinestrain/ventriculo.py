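"""Global ventriculometrics, wall thickness/thickening and the 17-segment model.

Volumes come from the multi-slice discrete form of Simpson's rule:
cavity pixel count x pixel area x slice spacing, summed over slices.  From
the volume curve, end diastole (t_ED, the maximum) and end systole (t_ES,
the minimum) give

    EDV = V_EnC(t_ED),  ESV = V_EnC(t_ES),  SV = EDV - ESV,
    EF  = SV / EDV x 100 %,
    V_m = V_EpC(t_ED) - V_EnC(t_ED),  LVM = rho x V_m  (rho = 1.05 g/cm^3),

with optional normalization of SV and LVM by body mass or surface area.
Wall thickness is the streamline length of the endo->epi Laplace
correspondence; thickening is (th_ES - th_ED)/th_ED, reported per sector
of the standardized 17-segment model (6 basal, 6 mid-cavity, 4 apical;
segment 17 at the apex tip is excluded), optionally smoothed with a
generalized Gauss-Markov random field (GGMRF) energy over the contour
neighbour graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg

from .errors import UndefinedTermError
from .laplace import ClosedContour, correspond_contours

logger = logging.getLogger(__name__)

#: myocardial tissue density, g/cm^3
MYOCARDIAL_DENSITY = 1.05

LABEL_BACKGROUND, LABEL_CAVITY, LABEL_MYOCARDIUM = 0, 1, 2

LEVELS = ("basal", "mid-cavity", "apical")
#: global segment ids per level; segment 17 (apex tip) is never analysed
_LEVEL_SECTORS = {
    "basal": tuple(range(1, 7)),
    "mid-cavity": tuple(range(7, 13)),
    "apical": tuple(range(13, 17)),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentationStack:
    """Label masks (0 background, 1 cavity, 2 myocardium) per slice/frame.

    ``masks`` has shape (S, T, H, W); ``pixel_area`` is mm^2 per pixel and
    ``slice_spacing`` mm (slice thickness plus gap).
    """

    masks: np.ndarray
    pixel_area: float
    slice_spacing: float

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 4:
            raise ValueError("masks must have shape (slices, frames, H, W)")
        bad = set(np.unique(m)) - {LABEL_BACKGROUND, LABEL_CAVITY, LABEL_MYOCARDIUM}
        if bad:
            raise ValueError(f"unknown labels in masks: {sorted(bad)}")
        self.masks = m.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def n_frames(self) -> int:
        return self.masks.shape[1]


@dataclass
class VolumeCurve:
    """Cavity volume per frame in microlitres (= mm^3)."""

    volumes: np.ndarray
    t_ed: int  # 0-based frame index of maximal volume (earliest on ties)
    t_es: int  # 0-based frame index of minimal volume


@dataclass
class GlobalIndices:
    edv: float            # µL
    esv: float            # µL
    sv: float             # µL
    ef: float             # %
    lvm: float            # g
    svi: float | None = None
    lvm_normalized: float | None = None

    def as_dict(self) -> dict:
        return {
            "EDV": self.edv, "ESV": self.esv, "SV": self.sv,
            "EF": self.ef, "LVM": self.lvm,
            "SVI": self.svi, "LVM_normalized": self.lvm_normalized,
        }


@dataclass
class ThicknessMap:
    """Wall thickness (mm) sampled at matched endo points of one slice."""

    points: np.ndarray       # (N, 2) endo points, px
    thickness: np.ndarray    # (N,) mm
    spacing: float = 1.0
    degenerate: bool = False


@dataclass
class SectorModel:
    """Slice-to-level mapping and angular reference for the 17 segments.

    ``reference_angle`` is the angle (radians, counterclockwise from +x)
    of the anatomical reference ray from which sector division starts; it
    must be supplied by the user (no landmark detection).
    """

    levels: tuple[str, ...]
    reference_angle: float = 0.0

    @classmethod
    def default_for(cls, n_slices: int, reference_angle: float = 0.0) -> "SectorModel":
        # first 3 slices basal, next 3 mid-cavity, rest apical
        levels = tuple(
            "basal" if s < 3 else ("mid-cavity" if s < 6 else "apical")
            for s in range(n_slices)
        )
        return cls(levels=levels, reference_angle=reference_angle)


def sectors_at_level(level: str) -> tuple[int, ...]:
    """Global sector ids for a slice level (6/6/4; apex excluded)."""
    try:
        return _LEVEL_SECTORS[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


# ---------------------------------------------------------------------------
# volumes and global indices
# ---------------------------------------------------------------------------

def lv_volume_curve(stack: SegmentationStack) -> VolumeCurve:
    """Cavity volume per frame by slice summation (discrete Simpson form)."""
    cavity = (stack.masks == LABEL_CAVITY).sum(axis=(0, 2, 3))
    volumes = cavity * stack.pixel_area * stack.slice_spacing
    if np.any(volumes == 0):
        logger.warning("empty cavity in %d frame(s); volume 0 recorded",
                       int((volumes == 0).sum()))
    return VolumeCurve(
        volumes=volumes.astype(float),
        t_ed=int(np.argmax(volumes)),
        t_es=int(np.argmin(volumes)),
    )


def global_indices(
    stack: SegmentationStack,
    curve: VolumeCurve | None = None,
    body_mass: float | None = None,
    surface_area: float | None = None,
    density: float = MYOCARDIAL_DENSITY,
) -> GlobalIndices:
    """EDV/ESV/SV/EF/LVM (and SVI / normalized LVM when a denominator for
    inter-subject comparison is given).  ``body_mass`` in g or
    ``surface_area`` in cm^2; body mass wins if both are present."""
    if curve is None:
        curve = lv_volume_curve(stack)
    edv = float(curve.volumes[curve.t_ed])
    esv = float(curve.volumes[curve.t_es])
    if edv <= 0:
        raise UndefinedTermError("EDV is zero; EF undefined")
    sv = edv - esv
    ef = sv / edv * 100.0

    ed_masks = stack.masks[:, curve.t_ed]
    epc = int(np.isin(ed_masks, (LABEL_CAVITY, LABEL_MYOCARDIUM)).sum())
    enc = int((ed_masks == LABEL_CAVITY).sum())
    v_m_ul = (epc - enc) * stack.pixel_area * stack.slice_spacing  # mm^3
    lvm = density * v_m_ul / 1000.0  # mm^3 -> cm^3

    denom = body_mass if body_mass is not None else surface_area
    svi = sv / denom if denom else None
    lvm_norm = lvm / denom if denom else None
    return GlobalIndices(edv=edv, esv=esv, sv=sv, ef=ef, lvm=lvm,
                         svi=svi, lvm_normalized=lvm_norm)


# ---------------------------------------------------------------------------
# wall thickness / thickening
# ---------------------------------------------------------------------------

def wall_thickness(
    endo: ClosedContour,
    epi: ClosedContour,
    n_points: int = 100,
    spacing: float = 1.0,
    **laplace_kw,
) -> ThicknessMap:
    """Per-point wall thickness: endo->epi streamline lengths, in mm."""
    cmap = correspond_contours(endo, epi, n_points=n_points, **laplace_kw)
    thickness = cmap.lengths * spacing
    degenerate = bool(np.all(thickness < 1e-9))
    if degenerate:
        logger.warning("identical contours: zero wall thickness everywhere")
    return ThicknessMap(
        points=cmap.source_points,
        thickness=thickness,
        spacing=spacing,
        degenerate=degenerate,
    )


def assign_sectors(
    points: np.ndarray,
    cavity_centroid,
    level: str,
    reference_angle: float = 0.0,
) -> np.ndarray:
    """Global 17-segment ids for points of one slice.

    The angle of each point about the cavity centroid is measured
    counterclockwise from ``reference_angle``; basal/mid-cavity levels use
    60-degree bins, apical 90-degree bins.
    """
    ids = sectors_at_level(level)
    pts = np.asarray(points, dtype=float)
    c = np.asarray(cavity_centroid, dtype=float)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]) - reference_angle
    ang = np.mod(ang, 2 * np.pi)
    width = 2 * np.pi / len(ids)
    bins = np.minimum((ang / width).astype(int), len(ids) - 1)
    return np.asarray(ids)[bins]


def wall_thickening(
    th_ed: ThicknessMap,
    th_es: ThicknessMap,
    level: str,
    reference_angle: float = 0.0,
    cavity_centroid=None,
) -> dict[int, float]:
    """Per-sector normalized wall thickening for one slice.

    Pointwise thickening is (th_ES - th_ED)/th_ED; points with zero ED
    thickness are excluded with a warning.  Returns {sector id: mean}.
    """
    if len(th_ed.thickness) != len(th_es.thickness):
        raise ValueError("thickness maps must share point count and ordering")
    ed = th_ed.thickness
    es = th_es.thickness
    ok = ed > 1e-12
    if not np.all(ok):
        logger.warning("%d point(s) with zero ED thickness excluded",
                       int((~ok).sum()))
    centroid = (
        np.asarray(cavity_centroid, float)
        if cavity_centroid is not None
        else th_ed.points.mean(axis=0)
    )
    ids = assign_sectors(th_ed.points, centroid, level, reference_angle)
    out: dict[int, float] = {}
    for sid in sectors_at_level(level):
        sel = (ids == sid) & ok
        out[sid] = float(((es[sel] - ed[sel]) / ed[sel]).mean()) if sel.any() else np.nan
    return out


def thickening_table(per_slice: list[dict[int, float]], model: SectorModel) -> dict[int, float]:
    """Merge per-slice sector thickening into the 16 reported segments.

    ``per_slice[s]`` is the output of :func:`wall_thickening` for slice s;
    sectors shared by several slices of the same level are averaged.
    Returns {1..16: value} matching the standardized table layout.
    """
    acc: dict[int, list[float]] = {i: [] for i in range(1, 17)}
    for vals in per_slice:
        for sid, v in vals.items():
            if sid <= 16 and np.isfinite(v):
                acc[sid].append(v)
    return {sid: (float(np.mean(v)) if v else np.nan) for sid, v in acc.items()}


# ---------------------------------------------------------------------------
# GGMRF smoothing
# ---------------------------------------------------------------------------

def _ring_chain_edges(shape: tuple[int, ...]) -> np.ndarray:
    """Neighbour edges: circular adjacency along the last axis, matched
    points across adjacent slices along the first axis (if 2D)."""
    if len(shape) == 1:
        n = shape[0]
        idx = np.arange(n)
        return np.column_stack([idx, (idx + 1) % n])
    s, n = shape
    edges = []
    flat = lambda i, j: i * n + j
    for i in range(s):
        for j in range(n):
            edges.append((flat(i, j), flat(i, (j + 1) % n)))
            if i + 1 < s:
                edges.append((flat(i, j), flat(i + 1, j)))
    return np.asarray(edges, dtype=int)


def ggmrf_smooth(
    values: np.ndarray,
    p: float = 2.0,
    gamma: float = 1.0,
    iterations: int = 500,
) -> np.ndarray:
    """MAP smoothing of a per-point wall map with a GGMRF prior.

    Minimizes sum |x_s - d_s|^p + gamma^p sum over neighbour pairs
    |x_s - x_r|^p on the contour neighbour graph (ring within a slice,
    matched indices across adjacent slices).  p = 2 is solved exactly via
    the sparse normal equations; 1 <= p < 2 by L-BFGS on an
    epsilon-smoothed energy.  The objective never increases.
    """
    if not (1.0 <= p <= 2.0):
        raise ValueError("p must lie in [1, 2]")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    d = np.asarray(values, dtype=float)
    shape = d.shape
    flat = d.ravel()
    if gamma == 0.0:
        return d.copy()
    edges = _ring_chain_edges(shape)

    if p == 2.0:
        n = flat.size
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        w = np.ones(len(rows))
        adj = scipy.sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
        deg = scipy.sparse.diags(np.asarray(adj.sum(axis=1)).ravel())
        lap = deg - adj
        a = scipy.sparse.eye(n) + gamma**2 * lap
        x = scipy.sparse.linalg.spsolve(a.tocsc(), flat)
        return x.reshape(shape)

    eps = 1e-12

    def energy_grad(x: np.ndarray):
        r = x - flat
        diff = x[edges[:, 0]] - x[edges[:, 1]]
        ar = np.sqrt(r**2 + eps)
        ad = np.sqrt(diff**2 + eps)
        e = np.sum(ar**p) + gamma**p * np.sum(ad**p)
        g = p * r * ar ** (p - 2)
        gd = gamma**p * p * diff * ad ** (p - 2)
        np.add.at(g, edges[:, 0], gd)
        np.add.at(g, edges[:, 1], -gd)
        return e, g

    res = scipy.optimize.minimize(
        energy_grad, flat.copy(), jac=True, method="L-BFGS-B",
        options={"maxiter": iterations},
    )
    if not res.success:
        logger.warning("GGMRF smoothing did not fully converge: %s", res.message)
    e_in, _ = energy_grad(flat)
    e_out, _ = energy_grad(res.x)
    if e_out > e_in:  # never return a worse iterate than the input
        logger.warning("GGMRF optimizer ended above the input energy; "
                       "returning the input map")
        return d.copy()
    return res.x.reshape(shape)
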