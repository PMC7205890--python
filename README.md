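# cinestrain

Automated cardiac function and strain analysis for short-axis cine (and
tagged) MRI of the mouse heart.

Tagged MRI is the traditional gold standard for myocardial strain, but the
tiny mouse heart makes tagging hard to acquire and interpret. `cinestrain`
derives strain directly from segmented cine images instead: left-ventricular
wall points are tracked over the cardiac cycle by solving the Laplace
equation between the wall contours of successive frames and following the
field's streamlines, and Lagrangian strain is assembled from the tracked
points. The same machinery yields wall thickness/thickening on the
standardized 17-segment model and the global volumetric indices
(EDV/ESV/SV/EF/LVM). A deforming-LV phantom with closed-form motion provides
end-to-end validation, and a correlation-window tracker covers the tagged
pathway for comparison.

## Method at a glance

* **Point correspondence / tracking.** Between two nested (or slightly
  crossing) contours the harmonic potential γ solves ∇²γ = 0 with γ = 0 on
  the inner/earlier boundary and γ = 1 on the outer/later one, iterated with
  the Jacobi scheme γ⁽ⁱ⁺¹⁾ = ¼·(4-neighbour sum). Streamlines of ∇γ —
  orthogonal to every equipotential — pair each point of one boundary with a
  unique point of the other. Endo→epi streamline lengths give wall
  thickness; frame-to-frame streamlines track the wall through the cycle.
* **Strain.** For a material segment of reference length L₀ deformed to L,
  the Green–Lagrange strain is E = (L² − L₀²)/(2L₀²) (engineering strain
  (L−L₀)/L₀ available as an option). Circumferential strain uses the chord
  between each point's tracked neighbours; radial strain the distance
  between paired points of two layers (endo–mid or mid–epi). Curves are
  reported globally, per layer (endo/mid/epi), and per sector of the
  17-segment model, with systolic/diastolic secant slopes S1/S2 and the
  peak value as summary metrics. Analysis covers frames 1–17, where the
  mouse strain cycle completes.
* **Global indices.** Cavity volumes by multi-slice summation (discrete
  Simpson form); EDV/ESV at the volume curve's extremes; SV = EDV − ESV,
  EF = SV/EDV × 100 %, LVM = ρ·(V_epi − V_cavity) at end diastole with
  ρ = 1.05 g/cm³.
* **Segmentation loss (standalone array math).** The class-imbalance loss
  L = α·L_BCE + β·L_ss with L_ss = 2 − (sensitivity + specificity),
  α + β = 1 (best at α = 0.2, β = 0.8), plus the Otsu / largest-component /
  hole-filling post-processing chain and DSC / Hausdorff metrics.
* **Tagged tracking.** Maximum Pearson correlation of a 3×3 template within
  a 5×5 search window, frame to frame (integer displacements of ≤ 1 px per
  step; optional continuous subpixel refinement).

## Worked example

Generate the default composite-motion phantom (translation, torsion, shear,
rotation and compression on a mouse-scale annular wall, 17 frames), track it,
and compare against the analytic ground truth:

```python
from cinestrain import (PhantomSpec, generate_phantom, track_wall,
                        circumferential_strain, radial_strain, slope_metrics,
                        analytic_strain_curve, curve_agreement,
                        global_indices, lv_volume_curve)

spec = PhantomSpec(seed=1)
seq = generate_phantom(spec)
tracked = track_wall(seq.contours, n_points=100, frame_window=(1, 17))

circ = circumferential_strain(tracked, "mid")
m = slope_metrics(circ)
print(f"mid-wall circumferential: peak {m.peak:+.3f} at frame {m.peak_frame}, "
      f"S1 {m.s1:+.4f}/frame, S2 {m.s2:+.4f}/frame")

rep = curve_agreement(circ.values,
                      analytic_strain_curve(spec, "mid", "circumferential"),
                      normalize=True)
print(f"vs analytic ground truth: CorCoef {rep.corcoef:.3f}, "
      f"normalized MSE {rep.mse:.3f} %")

stack = seq.segmentation_stack()
gi = global_indices(stack, lv_volume_curve(stack))
print(f"EDV {gi.edv:.2f} uL  ESV {gi.esv:.2f} uL  SV {gi.sv:.2f} uL  "
      f"EF {gi.ef:.1f} %")
```

This prints:

```
mid-wall circumferential: peak -0.087 at frame 8, S1 -0.0125/frame, S2 +0.0099/frame
vs analytic ground truth: CorCoef 1.000, normalized MSE 0.005 %
EDV 3.14 uL  ESV 2.01 uL  SV 1.13 uL  EF 36.0 %
```

The mid wall shortens circumferentially to its systolic peak at frame 8 and
relaxes back; the tracked curve is statistically indistinguishable from the
phantom's closed-form strain. The volume curve of the rendered masks gives
the global indices of the simulated ventricle (a 36 % EF: the phantom's
default compression is deliberately moderate).

A command-line interface mirrors the library
(`cinestrain phantom | track | strain-cine | strain-tagged | indices |
thickening | loss-eval | agree`); every run writes its resolved
configuration next to its outputs.

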