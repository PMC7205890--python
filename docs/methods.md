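# Methods

## Laplace-equation point correspondence

The wall between two closed boundaries is treated as the domain of the
Dirichlet problem ∇²γ = 0 with γ = 0 on the inner (or earlier-frame)
boundary and γ = 1 on the outer (or later-frame) one. The choice of 0
inside / 1 outside makes streamline direction mean "outward through the
wall" and "forward in time", which keeps thickness and tracking on one code
path.

**Discretization.** Contours are scan-filled on a pixel grid super-sampled
by an integer factor (default 2; thin mouse walls are a handful of native
pixels, and super-sampling halves the staircase bias of rasterized
boundaries). The solve region between two contours A (source) and B
(target) is always the symmetric band: A∩B is clamped to 0 and the
complement of A∪B to 1. For nested contours this is exactly the annulus
between them; for frame-to-frame contours that cross slightly (a normal
occurrence under translation or rotation) it degrades gracefully to the
symmetric-difference band, with a log warning.

**Iteration.** Plain Jacobi sweeps (each interior pixel replaced by the
mean of its four neighbours) until the max per-pixel change is ≤ 1e-6 on
the 0–1 scale, capped at 10,000 sweeps; a checkerboard Gauss–Seidel variant
(`method="redblack"`) reaches the same fixed point in fewer sweeps and is
verified against Jacobi in the tests. The solver works on the bounding box
of the problem only, and fills pixels outside the problem with their
nearest valid value afterwards so that interpolated gradients near thin
boundaries are usable.

**Known discretization limit.** A 0/1-clamped rasterized boundary acts as a
continuum boundary displaced by O(h) (~0.4 px measured), so the pointwise
agreement with the closed-form annulus solution is bounded by roughly
0.5·γ′(r_in) = 0.5/(r_in·ln 2) near the inner radius: ≈ 0.05 for a 10 px
inner radius, < 0.02 once the annulus is grid-resolved (30/60 px on 128²).
Fixtures represent circles with the half-pixel convention (clamp pixels
within R ± 0.5), which centres the effective boundary on the true circle.

**Streamlines.** Fixed-step Euler integration (0.25 grid px) along the
bilinearly interpolated, normalized gradient, ascending to γ ≥ 1 − 1e-2 or
descending to γ ≤ 1e-2, with a final linear extrapolation to the exact 0/1
level. When mapping points between contours, the traced path is cut at its
exact crossing of the target polygon (the discrete γ level only
approximates it); if the trace stops short, the endpoint is projected to
the nearest target point. Ten consecutive zero-gradient steps raise a
tracing-stalled error; inside `ContourField` a stalled seed falls back to
nearest-point projection with a warning.

## Wall tracking and Lagrangian strain

Endo- and epicardium are tracked independently: the frame-1 endocardial
contour is resampled to N points equally spaced by arc length, each point
is carried to the next frame by the frame-pair Laplace field, and the
process chains through the analysis window (frames 1–17 by default; the
mouse strain cycle completes within 17 cine frames). The frame-1 endo↔epi
field also pairs each endo point with an epi point and records where its
streamline crosses γ = 0.5; that equipotential defines the mid wall. From
frame 2 on, the mid point is carried as a fixed fractional position along
its endo–epi pair (the fraction w_k measured at frame 1). A plain 0.5
midpoint would contradict the γ = 0.5 initialization — for an annulus the
0.5 level sits at the geometric mean radius, not the arithmetic mean — and
would inject a spurious strain step between frames 1 and 2; the frozen
fraction keeps the reference consistent.

Strain follows the Green–Lagrange convention, E = (L² − L₀²)/(2L₀²),
computed pointwise and then averaged (per sector or globally); engineering
strain (L − L₀)/L₀ is an option and agrees to first order for the strain
magnitudes seen here. Circumferential segment length at point k is the
chord between tracked neighbours k−1 and k+1; radial strain uses the
distance between paired points of two layers. The local 2×2 Green–Lagrange
tensor (`lagrangian_tensor`) is exposed for completeness and verified
rotation-invariant; the reported curves are the normal components, as is
standard.

S1/S2 are two-point secants from the first frame to the peak and from the
peak to the last analysis frame (peak = extremum of |strain|, so one
definition serves negative circumferential and positive radial curves); a
least-squares variant sits behind a flag. A peak on the window boundary
leaves the corresponding slope undefined and flagged.

**Observability limit.** Contour-based correspondence sees only the
boundary-normal component of motion: tangential slip of a translating or
rotating circular contour is invisible to any geometric tracker (measured
up to ~4.5 px at the waist of a translating phantom). This does not affect
strain — rigid motions produce |E| < 0.01 across the test suite — but
per-point trajectories should not be read as material paths where the
motion is tangential.

## Sector model

Points are binned by angle about the frame-1 cavity centroid,
counterclockwise from a user-supplied reference angle (no anatomical
landmark detection): 60° bins at basal and mid-cavity levels (segments 1–6
and 7–12), 90° bins at the apical level (13–16); segment 17 at the apex tip
is excluded from analysis. The default slice→level mapping is three basal,
three mid-cavity, remainder apical. Bin membership is frozen at frame 1;
sector curves therefore average (point-count weighted) exactly to the
global curve.

## Ventriculometrics

Cavity volume per frame is cavity-pixel count × pixel area × slice spacing
summed over slices — the discrete multi-slice form of Simpson's method.
End diastole/systole are the curve's maximum/minimum (earliest frame on
ties). LVM converts the end-diastolic myocardial volume to grams with
ρ = 1.05 g/cm³; SV and LVM are optionally normalized by body mass or
surface area (values supplied by the caller; no surface-area formula is
built in). Wall thickness is the endo→epi streamline length; normalized
thickening is (th_ES − th_ED)/th_ED pointwise (zero-thickness points are
excluded with a warning), averaged per sector into a 16-column table.

GGMRF smoothing of per-point wall maps minimizes
Σ|x_s − d_s|ᵖ + γᵖ Σ_neighbours |x_s − x_r|ᵖ on the contour-neighbour graph
(circular within a slice, index-matched across adjacent slices). p = 2 is
solved exactly via the sparse normal equations (I + γ²L)x = d; 1 ≤ p < 2 by
L-BFGS on an ε-smoothed energy, returning the input if the optimizer ever
ends above the input energy. Defaults p = 2, γ = 1 are conventional
quadratic-smoothing values; the parameters are exposed.

## Segmentation loss and metrics

The loss is pure array math over a probability map ŷ and binary truth y:
L_BCE as the printed pixel sum (a mean-reduction flag exists because
training pipelines usually want per-pixel scale), soft sensitivity +
specificity loss L_ss = 2 − (sens + spec) ∈ [0, 2], and the combination
αL_BCE + βL_ss with α + β = 1 enforced and defaults α = 0.2, β = 0.8 (the
grid-searched optimum). Probabilities are clipped to [1e-7, 1 − 1e-7] for
log stability. Post-processing: Otsu threshold, keep the largest
4-connected component, flood-fill interior holes — deterministic and
idempotent; a constant map has no threshold and returns all-background with
a warning. DSC is reported in percent; the Hausdorff distance is the
symmetric max-min over boundary pixels (erosion boundary, KD-tree), scaled
to mm. Two empty masks score DSC 100 / HD 0 by logged convention; one empty
mask gives HD = inf. The segmentation network itself (U-net, Kaiming
initialization, Adam at lr 0.001 with early stopping, leave-one-out over
subjects) is a training recipe outside this package's scope: it needs
animal data and GPU time, and none of its outputs are required by the
analysis pipeline, which starts from label masks.

## Tagged-MRI tracking

Each seeded point is tracked frame to frame by Pearson correlation of the
3×3 template around its current position against every 3×3 patch in the
5×5 search window of the next frame — displacements of at most ±1 px per
axis per step. Pearson normalization makes the match invariant to tag
fading. Ties break toward the smallest displacement, then row-major order.
Zero-variance templates (flat regions) keep zero displacement with a
warning; tracks nearing the border are truncated and flagged.

Integer tracking quantizes each step, so steady sub-pixel motion
accumulates a persistently same-signed rounding error (a rotating phantom
drifts several px over 17 frames). The `subpixel=True` variant keeps the
position fractional — template and window are spline-resampled at the exact
position, the integer argmax seeds a continuous maximization of the
correlation over the fractional displacement — and follows a 0.5°/frame
rotation within 0.3 px over 17 frames. A simple three-point parabola
vertex was rejected: on a tag-period-k correlation kernel its gain is
k·sin k/(2(1 − cos k)) ≈ 0.87, which still drifts. Seed points are either
user-supplied (the operational analogue of expert-marked points) or chosen
by `select_seeds`, which requires gradient energy along both axes inside
the template — a window matcher at a pattern extremum faces an aperture
ambiguity no refinement can fix.

Strain from tagged tracks reuses the cine formulas (ring topology for
circumferential, index pairs for radial), truncated at the earliest
truncated track.

## The synthetic phantom

A mid-ventricular slice is an annulus (endo 1.0 mm, epi 1.6 mm) on a 256²
grid at 0.02 mm/px, deformed over 17 frames by five independently
parameterized motion classes composed in a fixed order: piecewise-linear
radial compression/thickening (cavity ratio λ(t), wall-thickness ratio
μ(t)), transmural torsion (0 at endo → τ(t) at epi), rigid rotation ρ(t),
simple shear, and translation. Defaults are sized to the mouse heart:
λ_min = 0.8, μ_max = 1.3, rotation 5°, torsion 8°, shear 0.05, translation
0.1 mm per axis. Amplitudes follow a raised-cosine profile peaking at frame
8 and returning to zero at frame 17; a linear ramp is available for
constant-rate motion (used by the rotation-tracking validation at
0.5°/frame). Every component has an analytic inverse, so ground-truth
correspondences, deformation gradients and strain are available in closed
form; with the optional wedge modulation (which tapers the non-rigid
amplitudes over a raised-cosine angular transition — a hard step would tear
the contour) the inverse is obtained by a fixed-point iteration on the
reference angle.

The analytic mid-wall radius is the geometric mean √(r_endo·r_epi) — the
γ = 0.5 equipotential of the annulus field — matching the tracker's mid
layer. Analytic strain differentiates the exact forward map (central
differences at h = 1e-6 mm, machine-precision for this smooth map) and
projects on the reference tangent for circumferential strain; radial
ground truth mirrors the tracker's definition as the distance between
radially aligned layer points.

Tagged rendering evaluates a product of two raised sinusoids (default
period 0.6 mm, the real tag separation) at the analytically inverse-mapped
reference position of every pixel — advection without resampling error —
masked to the deformed myocardium, plus a seeded advected material texture
(a sum of random-phase plane waves, wavelengths 3–8 px, amplitude 0.15 of
the tag contrast) standing in for myocardial speckle, and optional
per-frame Gaussian noise. A noiseless pure grid has aperture-degenerate
extrema that no window matcher can track, which real tissue does not.

**What the phantom does not emulate:** MR physics (tag fading, k-space
artifacts, coil profiles), through-plane motion and 3-D torsion between
slices, segmentation errors (its masks are exact), and papillary muscles.
Passing the phantom validation therefore demonstrates the correctness of
the correspondence/strain machinery given good segmentations, not
robustness to segmentation failure.

## Agreement statistics

Curve comparisons report the Pearson correlation, the MSE (optionally
after each curve is normalized by its own max |value|, in which case the
MSE is reported ×100 in percent), and the Bland–Altman bias with 95 %
limits of agreement (bias ± 1.96·SD of the pairwise differences). The raw
differences vector is kept on the report so any downstream normality test
can be applied. Zero-variance curves make the correlation undefined and
raise an error rather than returning a placeholder.

## Problem sizes used in validation

The end-to-end phantom validation tracks 100 points over 17 frames on the
256² grid (≈ 35 s on one CPU); unit-test phantoms use 96² grids, 9 frames
and 48 points, with super-sampling raised to 4 where a symmetry bound
tighter than the rasterization anisotropy at that scale is asserted. These
sizes are the package's chosen test conditions; all parameters scale.

## Known limitations

* Tangential wall motion is unobservable from contours (see above);
  per-point tracked trajectories are reliable in the wall-normal direction
  and for strain, not as material paths under rigid motion.
* Each short-axis slice is analysed independently; no through-plane
  correspondence is attempted.
* Integer tagged tracking drifts under steady sub-pixel motion; use
  `subpixel=True` when trajectories (rather than strain trends) matter.
* The Jacobi solver's boundary placement is accurate to O(h); super-sample
  (or supply higher-resolution contours) when absolute thickness accuracy
  below a few percent of a pixel matters.
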