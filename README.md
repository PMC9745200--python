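# ivus2fe

Patient-specific biomechanics of atherosclerotic coronary arteries from
virtual-histology intravascular ultrasound (VH-IVUS).

Rupture-prone plaques correlate with regions of high wall stress, but wall
mechanics are rarely available clinically because building a
patient-specific model by hand is laborious. `ivus2fe` automates the whole
chain: it reads a color-coded VH-IVUS pullback (one RGB frame per gated
position, 0.02 mm/px) plus the 3D vessel centerline from biplane
angiography, reconstructs a closed, anatomically curved surface of the
artery wall (with side branches grafted at detected angular gaps and an
artificial perivascular "sleeve" supporting thin walls), fills it with a
quality tetrahedral mesh, maps every element to one of six tissue
materials by nearest VH pixel in 3D, and solves the static luminal
pressurization problem with a built-in small-strain finite element solver
(compressible neo-Hookean optional), reporting elemental and
nodal-smoothed Von Mises stress per constituent. An FEBio (.feb, spec 3.0)
exporter writes the identical problem for an external solver.

The material model is linear elastic per constituent
(E in MPa, ν = 0.48): arterial wall 0.3, fibrotic 0.6, fibrofatty 0.5,
dense calcium 10, necrotic core 0.02, sleeve 0.4. The effective stress is
the Von Mises stress
σ_vm = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)²] + 3(σ₁₂²+σ₂₃²+σ₃₁²)),
and nodal smoothing is the volume-weighted average of adjacent elements.

Because no patient data ships with the package, a first-class **phantom
generator** renders synthetic VH-IVUS stacks (annular wall, embedded
inclusions of each tissue class, optional branch gap, helical or straight
centerline) with exact pixel-count and volume ground truth, and the
thick-walled-cylinder (Lamé) closed form provides an analytic oracle for
the solver. Every pipeline stage is validated against these.

## Worked example

```python
import numpy as np
from ivus2fe import (default_phantom, generate_vh_stack, classify_pixels,
                     load_centerline, material_table, build_fe_model,
                     solve_static, stress_report)
from ivus2fe.pipeline import PipelineConfig, reconstruct

spec = default_phantom(n_frames=10, seed=0)           # 4.5 mm helical segment
stack = generate_vh_stack(spec)
frames = [classify_pixels(img, frame_index=i) for i, img in enumerate(stack.images)]
c = load_centerline(stack.centerline_csv)

cfg = PipelineConfig(resolution=0.2, sleeve_thickness=0.2, solve=False)
surface, mesh, _ = reconstruct(frames, c, cfg, {})
model = build_fe_model(mesh, material_table(), pressure_kpa=17.0)
result = solve_static(model)
rep = stress_report(result, mesh, model.table)
for name, s in rep["per_material"].items():
    print(f"{name:14s} mean VM {s['mean_vm_kpa']:7.1f} kPa  "
          f"max {s['max_vm_kpa']:7.1f} kPa  ({s['n_elements']} elements)")
print(f"max nodal-smoothed VM {rep['max_nodal_vm_kpa']:.1f} kPa, "
      f"max displacement {rep['max_displacement_mm']:.3f} mm")
```

prints (exact numbers vary with the phantom seed):

```
arterial_wall  mean VM    16.6 kPa  max   159.4 kPa  (66464 elements)
fibrotic       mean VM    24.3 kPa  max    53.9 kPa  (7667 elements)
fibrofatty     mean VM    22.1 kPa  max    32.0 kPa  (3144 elements)
necrotic_core  mean VM     2.6 kPa  max     4.0 kPa  (2610 elements)
calcium        mean VM    83.0 kPa  max   395.8 kPa  (1471 elements)
sleeve         mean VM    13.6 kPa  max    41.4 kPa  (19899 elements)
max nodal-smoothed VM 111.4 kPa, max displacement 0.204 mm
```

Stiff calcium concentrates the load (highest mean effective stress) while
the soft necrotic core carries almost none; nodal smoothing, a convex
average, caps the smoothed maximum below the elemental maximum. Under a
mean systolic pressure of 17 kPa the nodal-smoothed stress stays well
below the ~300 kPa range usually associated with plaque rupture.

A command line mirrors the workflow
(`ivus2fe phantom|reconstruct|solve|sweep|compare-centerline`), e.g.:

```bash
ivus2fe phantom demo/ --n-frames 10
ivus2fe solve demo demo/centerline.csv out/ --resolution 0.2
```

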