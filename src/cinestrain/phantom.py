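"""Synthetic deforming-LV phantom with analytic motion and strain.

A mid-ventricular slice is modelled as an annular myocardium (endocardial
radius ``r_endo``, epicardial radius ``r_epi``, in mm) deformed over a
17-frame cardiac cycle by the composition of five motion classes, each an
independent parameter with an analytic inverse:

1. radial compression/thickening -- piecewise linear in radius: the
   cavity scales by lambda(t) (endo radius -> lambda * r_endo) while the
   wall thickness scales by mu(t), so systolic cavity shrinkage and wall
   thickening are controlled separately;
2. transmural torsion -- rotation growing linearly from 0 at the
   endocardium to tau(t) at the epicardium;
3. rigid rotation by rho(t);
4. simple shear x -> x + s(t) y about the centre;
5. rigid translation.

All amplitudes follow a raised-cosine time profile: zero at frame 1,
peak at the systolic frame (8 of 17 by default), back to zero at the last
frame.  Because the map is known in closed form, the deformation gradient
-- and hence ground-truth Lagrangian strain for any layer and direction --
is available analytically, as are label masks, wall contours and advected
tagged-grid images for end-to-end validation of the tracking pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from .errors import GeometryOverflowError
from .laplace import ClosedContour
from .tagged import TaggedSequence

logger = logging.getLogger(__name__)


@dataclass
class WedgeModulation:
    """Angular modulation of the non-rigid motion amplitudes.

    Inside the core wedge [theta0, theta0 + width) (radians,
    counterclockwise, measured about the phantom centre at the reference
    frame) the compression, thickening and torsion amplitudes are
    multiplied by ``factor`` (0 suppresses motion there), with a
    raised-cosine transition of angular width ``taper`` on each side --
    regional dysfunction is graded, and a hard step would tear the
    contour.  Rigid rotation, shear and translation stay global.
    """

    theta0: float
    width: float
    factor: float = 0.0
    taper: float = np.pi / 9

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        rel = np.mod(np.asarray(theta, float) - self.theta0, 2 * np.pi)
        g = np.ones_like(rel)
        g[rel < self.width] = self.factor
        if self.taper > 0:
            up = (rel >= self.width) & (rel < self.width + self.taper)
            s = (rel[up] - self.width) / self.taper
            g[up] = self.factor + (1 - self.factor) * 0.5 * (1 - np.cos(np.pi * s))
            down = rel > 2 * np.pi - self.taper
            s = (2 * np.pi - rel[down]) / self.taper
            g[down] = self.factor + (1 - self.factor) * 0.5 * (1 - np.cos(np.pi * s))
        return g


@dataclass
class PhantomSpec:
    """Geometry, motion amplitudes and rendering parameters.

    Defaults are sized to the mouse heart: endo 1.0 mm / epi 1.6 mm on a
    256-pixel grid at 0.02 mm/px, cavity compression lambda_min = 0.8,
    wall thickening mu_max = 1.3, 5 deg rotation, 8 deg transmural
    torsion, shear factor 0.05 and 0.1 mm translation per axis over a
    17-frame cycle peaking at frame 8.
    """

    image_size: int = 256
    spacing: float = 0.02          # mm / px
    r_endo: float = 1.0            # mm, frame 1
    r_epi: float = 1.6             # mm, frame 1
    n_frames: int = 17
    translation: tuple[float, float] = (0.1, 0.1)   # mm per cycle
    rotation_deg: float = 5.0
    torsion_deg: float = 8.0
    shear: float = 0.05
    lambda_min: float = 0.8        # cavity compression ratio at systole
    mu_max: float = 1.3            # wall thickening ratio at systole
    systolic_frame: int = 8
    profile: str = "raised-cosine"   # or "linear" (monotone ramp, e.g. steady rotation)
    wedge: WedgeModulation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("raised-cosine", "linear"):
            raise ValueError("profile must be 'raised-cosine' or 'linear'")
        if not (0.0 < self.lambda_min <= 1.0 <= self.mu_max):
            raise ValueError("need 0 < lambda_min <= 1 <= mu_max")
        if not (0.0 < self.r_endo < self.r_epi):
            raise ValueError("radii must be positive with r_endo < r_epi")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if not (1 < self.systolic_frame < self.n_frames):
            raise ValueError("systolic frame must be interior to the cycle")

    # -- geometry ----------------------------------------------------------
    @property
    def center_mm(self) -> np.ndarray:
        c = (self.image_size - 1) / 2.0 * self.spacing
        return np.array([c, c])

    @property
    def wall_width(self) -> float:
        return self.r_epi - self.r_endo

    def mid_radius(self) -> float:
        """Reference mid-wall radius: the gamma = 0.5 level of the annulus
        Laplace field (log-radial profile), i.e. the geometric mean."""
        return float(np.sqrt(self.r_endo * self.r_epi))

    def px_to_mm(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) * self.spacing

    def mm_to_px(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) / self.spacing

    # -- time profile --------------------------------------------------------
    def amplitude(self, frame: int) -> float:
        """Raised-cosine activation in [0, 1] for 1-based ``frame``."""
        t, ts, T = frame, self.systolic_frame, self.n_frames
        if not (1 <= t <= T):
            raise ValueError(f"frame {t} outside 1..{T}")
        if self.profile == "linear":
            return (t - 1) / (T - 1)
        if t <= ts:
            return 0.5 * (1.0 - np.cos(np.pi * (t - 1) / (ts - 1)))
        return 0.5 * (1.0 + np.cos(np.pi * (t - ts) / (T - ts)))

    # -- motion map ----------------------------------------------------------
    def _amps(self, frame: int):
        a = self.amplitude(frame)
        return {
            "rot": np.deg2rad(self.rotation_deg) * a,
            "tor": np.deg2rad(self.torsion_deg) * a,
            "shear": self.shear * a,
            "trans": a * np.asarray(self.translation, float),
            "lam_amp": (self.lambda_min - 1.0) * a,
            "mu_amp": (self.mu_max - 1.0) * a,
        }

    def forward(self, points_mm, frame: int) -> np.ndarray:
        """Map reference (frame-1) points, in mm, to their frame-t positions."""
        m = self._amps(frame)
        q = np.atleast_2d(np.asarray(points_mm, float)) - self.center_mm
        r = np.hypot(q[:, 0], q[:, 1])
        theta = np.arctan2(q[:, 1], q[:, 0])
        g = self.wedge(theta) if self.wedge is not None else 1.0
        lam = 1.0 + m["lam_amp"] * g
        mu = 1.0 + m["mu_amp"] * g
        w0 = self.wall_width
        r_new = np.where(
            r < self.r_endo,
            lam * r,
            np.where(
                r <= self.r_epi,
                lam * self.r_endo + mu * (r - self.r_endo),
                lam * self.r_endo + mu * w0 + (r - self.r_epi),
            ),
        )
        frac = np.clip((r - self.r_endo) / w0, 0.0, 1.0)
        theta_new = theta + m["rot"] + m["tor"] * g * frac
        x = r_new * np.cos(theta_new)
        y = r_new * np.sin(theta_new)
        x = x + m["shear"] * y
        out = np.column_stack([x, y]) + m["trans"] + self.center_mm
        return out

    def inverse(self, points_mm, frame: int) -> np.ndarray:
        """Map frame-t points, in mm, back to their reference positions."""
        m = self._amps(frame)
        q = np.atleast_2d(np.asarray(points_mm, float)) - self.center_mm - m["trans"]
        y = q[:, 1]
        x = q[:, 0] - m["shear"] * y
        r_def = np.hypot(x, y)
        theta_def = np.arctan2(y, x)
        w0 = self.wall_width

        def radial_inverse(g):
            lam = 1.0 + m["lam_amp"] * g
            mu = 1.0 + m["mu_amp"] * g
            r1 = lam * self.r_endo
            r2 = r1 + mu * w0
            return np.where(
                r_def < r1,
                r_def / lam,
                np.where(
                    r_def <= r2,
                    self.r_endo + (r_def - r1) / mu,
                    self.r_epi + (r_def - r2),
                ),
            )

        if self.wedge is None:
            r = radial_inverse(1.0)
            frac = np.clip((r - self.r_endo) / w0, 0.0, 1.0)
            theta = theta_def - m["rot"] - m["tor"] * frac
        else:
            # fixed-point iteration on the reference angle (the wedge factor
            # depends on it); converges quickly for moderate wedges
            theta = theta_def - m["rot"]
            r = radial_inverse(self.wedge(theta))
            for _ in range(60):
                g = self.wedge(theta)
                r = radial_inverse(g)
                frac = np.clip((r - self.r_endo) / w0, 0.0, 1.0)
                theta_next = theta_def - m["rot"] - m["tor"] * g * frac
                if np.max(np.abs(theta_next - theta)) < 1e-13:
                    theta = theta_next
                    break
                theta = theta_next
        out = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return out + self.center_mm


@dataclass
class PhantomSequence:
    """Rendered phantom: masks, contours and the analytic motion maps."""

    spec: PhantomSpec
    masks: np.ndarray                       # (T, H, W) uint8 labels 0/1/2
    contours: list[tuple[ClosedContour, ClosedContour]]  # (endo, epi) px

    def forward(self, points_mm, frame: int) -> np.ndarray:
        return self.spec.forward(points_mm, frame)

    def inverse(self, points_mm, frame: int) -> np.ndarray:
        return self.spec.inverse(points_mm, frame)

    @property
    def n_frames(self) -> int:
        return self.spec.n_frames

    def segmentation_stack(self):
        """Single-slice SegmentationStack view of the masks (1 mm slice)."""
        from .ventriculo import SegmentationStack

        return SegmentationStack(
            masks=self.masks[None, ...],
            pixel_area=self.spec.spacing**2,
            slice_spacing=1.0,
        )


def _layer_radius(spec: PhantomSpec, layer) -> float:
    if isinstance(layer, (int, float)):
        return float(layer)
    return {
        "endo": spec.r_endo,
        "mid": spec.mid_radius(),
        "epi": spec.r_epi,
    }[layer]


def generate_phantom(spec: PhantomSpec, contour_points: int = 360) -> PhantomSequence:
    """Render masks and contours for every frame of the cycle."""
    size = spec.image_size
    margin = 2 * spec.spacing
    half = (size - 1) / 2.0 * spec.spacing
    # conservative overflow bound: deformed epi radius plus translation
    max_mu = 1.0 + (spec.mu_max - 1.0)
    r_out = spec.lambda_min * spec.r_endo + max_mu * spec.wall_width
    r_out = max(r_out, spec.r_epi) * (1.0 + abs(spec.shear))
    if r_out + np.max(np.abs(spec.translation)) > half - margin:
        raise GeometryOverflowError(
            "phantom motion would push the epicardium outside the image"
        )

    theta = np.linspace(0.0, 2 * np.pi, contour_points, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    ref = {
        "endo": spec.center_mm + spec.r_endo * unit,
        "epi": spec.center_mm + spec.r_epi * unit,
    }

    masks = np.zeros((spec.n_frames, size, size), dtype=np.uint8)
    contours = []
    for t in range(1, spec.n_frames + 1):
        endo_mm = spec.forward(ref["endo"], t)
        epi_mm = spec.forward(ref["epi"], t)
        endo_px = spec.mm_to_px(endo_mm)
        epi_px = spec.mm_to_px(epi_mm)
        endo_fill = polygon2mask((size, size), endo_px[:, ::-1])
        epi_fill = polygon2mask((size, size), epi_px[:, ::-1])
        frame = np.zeros((size, size), dtype=np.uint8)
        frame[epi_fill] = 2
        frame[endo_fill] = 1
        masks[t - 1] = frame
        contours.append((ClosedContour(endo_px), ClosedContour(epi_px)))
    return PhantomSequence(spec=spec, masks=masks, contours=contours)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def analytic_strain(
    spec: PhantomSpec,
    frame: int,
    layer="mid",
    direction: str = "circumferential",
    convention: str = "green-lagrange",
    n_theta: int = 360,
) -> float:
    """Exact strain of the stated motion map, averaged over the layer.

    Circumferential strain comes from the deformation gradient F of the
    forward map (differentiated at machine precision) projected on the
    reference tangent: E_cc = (|F t|^2 - 1)/2.  Radial strain mirrors the
    tracker's definition: the distance between layer-pair points that are
    radially aligned at the reference frame.  ``layer`` is a layer name
    (or radius in mm) for circumferential, or a pair such as
    ("endo", "mid") for radial.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])

    if direction == "circumferential":
        r = _layer_radius(spec, layer)
        pts = spec.center_mm + r * unit
        h = 1e-6
        tangent = np.column_stack([-np.sin(theta), np.cos(theta)])
        f_plus = spec.forward(pts + h * tangent, frame)
        f_minus = spec.forward(pts - h * tangent, frame)
        stretch = np.linalg.norm(f_plus - f_minus, axis=1) / (2 * h)
    elif direction == "radial":
        if isinstance(layer, str):
            layer = ("endo", "mid") if layer in ("endo", "inner") else ("mid", "epi")
        ra = _layer_radius(spec, layer[0])
        rb = _layer_radius(spec, layer[1])
        pa = spec.forward(spec.center_mm + ra * unit, frame)
        pb = spec.forward(spec.center_mm + rb * unit, frame)
        stretch = np.linalg.norm(pb - pa, axis=1) / (rb - ra)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if convention == "green-lagrange":
        vals = 0.5 * (stretch**2 - 1.0)
    elif convention == "engineering":
        vals = stretch - 1.0
    else:
        raise ValueError(f"unknown strain convention {convention!r}")
    return float(vals.mean())


def analytic_strain_curve(
    spec: PhantomSpec,
    layer="mid",
    direction: str = "circumferential",
    convention: str = "green-lagrange",
) -> np.ndarray:
    """Ground-truth strain for frames 1..T (frame 1 is exactly zero)."""
    return np.array([
        analytic_strain(spec, t, layer=layer, direction=direction,
                        convention=convention)
        for t in range(1, spec.n_frames + 1)
    ])


# ---------------------------------------------------------------------------
# tagged rendering
# ---------------------------------------------------------------------------

def _material_texture(rng: np.random.Generator, spacing: float, n_waves: int = 24):
    """Smooth random material texture: a seeded sum of random-phase plane
    waves with wavelengths of 3-8 pixels.  Evaluated at reference
    coordinates it rides along with the tissue, which is what gives the
    window-correlation tracker a locally unique pattern to latch onto
    (real tagged myocardium has speckle for the same reason)."""
    ang = rng.uniform(0, 2 * np.pi, n_waves)
    wavelength = rng.uniform(3.0, 8.0, n_waves) * spacing
    phase = rng.uniform(0, 2 * np.pi, n_waves)
    kx = 2 * np.pi * np.cos(ang) / wavelength
    ky = 2 * np.pi * np.sin(ang) / wavelength
    amp = rng.uniform(0.5, 1.0, n_waves)
    amp = amp / np.sqrt(np.sum(amp**2) / 2)  # unit variance

    def tex(p: np.ndarray) -> np.ndarray:
        return np.cos(p[:, :1] * kx + p[:, 1:] * ky + phase) @ amp

    return tex


def render_tagged(
    seq: PhantomSequence,
    tag_spacing: float = 0.6,
    contrast: float = 1.0,
    texture_amplitude: float = 0.15,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TaggedSequence:
    """Advect a sinusoidal tag grid with the phantom motion.

    Frame-t intensity at pixel p is the product of two orthogonal raised
    sinusoids of period ``tag_spacing`` (mm; 0.6 mm matches the real tag
    separation) evaluated at the reference position inverse(p, t), plus a
    seeded material texture advected the same way (amplitude
    ``texture_amplitude`` of the tag contrast), masked to the deformed
    myocardium, plus optional per-frame Gaussian noise.
    """
    spec = seq.spec
    if tag_spacing <= 2 * spec.spacing:
        raise ValueError("tag spacing must exceed 2 pixels")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    texture = _material_texture(rng, spec.spacing)
    size = spec.image_size
    jj, ii = np.meshgrid(np.arange(size), np.arange(size))
    pix_mm = np.column_stack([jj.ravel(), ii.ravel()]) * spec.spacing

    frames = np.empty((spec.n_frames, size, size))
    k = 2 * np.pi / tag_spacing
    for t in range(1, spec.n_frames + 1):
        ref = spec.inverse(pix_mm, t)
        pattern = (0.5 + 0.5 * np.cos(k * ref[:, 0])) * (
            0.5 + 0.5 * np.cos(k * ref[:, 1])
        )
        if texture_amplitude > 0:
            pattern = pattern + texture_amplitude * texture(ref)
        img = contrast * pattern.reshape(size, size) * (seq.masks[t - 1] == 2)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[t - 1] = img
    return TaggedSequence(frames=frames, spacing=spec.spacing)
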