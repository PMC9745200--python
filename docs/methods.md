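# Methods

`ivus2fe` rebuilds, as a tested Python package, the automated chain that
turns a color-coded VH-IVUS pullback plus a 3D angiographic centerline into
a heterogeneous curved tetrahedral artery model and computes its wall
stresses under luminal pressure. This note records the model, the numerical
choices, and what the synthetic tests do and do not demonstrate.

## Image processing

VH-IVUS frames arrive as 8-bit RGB overlays in which each tissue class has
a display color (grey arterial wall, dark-green fibrotic, light-green
fibrofatty, red necrotic core, white dense calcium). Classification assigns
each pixel the label of the nearest reference RGB within a Euclidean
tolerance (default 60), else background. The VH export names the colors but
not their numeric values, so the palette is configuration; the defaults are
the common named values. Cleanup removes 8-connected same-label components
below `min_area` (default 20 px²), relabeling them to the dominant
bordering label — an area-opening-style filter.

A perivascular "sleeve" of configurable radial thickness (default 0.2 mm,
i.e. 10 px at the fixed 0.02 mm/px scale) is added by Euclidean dilation of
the tissue union. Dilation alone would also grow into the blood channel, so
candidate pixels radially inside the per-angle innermost tissue radius are
rejected; at branch-gap angles (no tissue along the ray) the sleeve is
allowed to wrap the cut edges. The sleeve stabilizes thin walls during
pressurization and is treated as a sixth material.

Contours are extracted by casting rays from the catheter center (image
center) at uniform angles (default 72, i.e. 5° spacing): the first and last
tissue crossings give the luminal and outer radius per angle. Angles with
no tissue are branch-gap stations; their radii are filled by periodic
interpolation and flagged. Branch gaps are detected on a finer 1° sweep;
maximal runs of empty rays spanning at least 10° on at least 2 consecutive
frames count as branches (single-frame gaps are treated as dropouts). The
ray parameterization directly yields simple, closed, counter-clockwise
polylines with identical point counts and start angle across frames, which
is exactly what uniform lofting needs.

## Centerline and placement

The centerline (QAngio-style CSV of XYZ mm) is resampled to one point per
frame at uniform arc length. Frames (tangent, normal, binormal) are built
with the rotation-minimizing double-reflection scheme: unlike Frenet
frames, it is defined on straight segments and accumulates no spurious
twist. The rotational orientation of the IVUS transducer about the
centerline is not observable from the inputs; a global in-plane rotation
offset (default 0°) is exposed. Contours map rigidly into each frame's
normal/binormal plane; "straight" mode instead stacks frames along +z at
the same arc-length stations, so per-frame cross-sections are identical
between modes by construction and volume differences reflect only the
geometric interaction of curvature with lofting and meshing.

## Surface

Lofting joins consecutive lumen rings and consecutive outer rings with
triangle bands (2n triangles per band) and closes the ends with annular
caps between outer and lumen rings. The result is the boundary of the wall
solid, oriented outward. Note the topology: a thick-walled tube is
annulus × interval, whose boundary is a genus-1 closed surface
(Euler characteristic 0, not 2); every grafted branch tunnels from the
lumen surface to the outer surface and adds a handle (χ decreases by 2).
The validation suite checks these exact values.

Branch grafting removes the faces touching gap-flagged vertices, recovers
the luminal and outer hole loops, and takes the branch direction as the
unit vector between their centroids (oriented outward by the removed outer
faces' mean normal). Both loops are carried to the plane orthogonal to the
branch direction at a configurable offset (default 1.0 mm) past the outer
surface; the luminal loop is dilated in-plane (default factor 1.3) to give
the branch an artificial wall — the true thickness of a side branch cannot
be seen in axial frames — and outer faces under the dilated footprint are
removed. Cubic Hermite lofts (8 intermediate rings; start tangents in the
surface, end tangents along the branch axis, magnitudes equal to the chord)
connect the holes to the plane; loops of unequal point count are stitched
with a shortest-diagonal zipper; an annular cap closes the branch. Face
winding is then re-propagated globally and checked watertight.

Smoothing is the HC (Humphrey's classes) scheme: uniform Laplacian
averaging followed by a correction that subtracts the mean drift toward
the original/previous positions (α = 0.1, β = 0.6, 10 iterations —
conventional values for the scheme). Vertices on tag-boundary creases (cap
rims, branch junction rings) are pinned, and their correction vector is
zeroed so they do not drag neighbors; without this the end caps creep
inward and the wall volume drifts several percent. On the phantom tube the
smoothed + remeshed surface keeps its enclosed volume within ~0.4% of the
first pass (vs ~47% shrinkage for plain Laplacian at equal iterations on a
sphere benchmark).

Remeshing is incremental isotropic remeshing (split edges > 4/3 L,
collapse < 4/5 L under the link condition and normal-flip guards, flips
toward valence 6, tangential relaxation) with projection of every vertex
back to the input surface each iteration, so the Hausdorff distance stays
far below the target edge. Projection candidates come from a KD-tree over
face centroids with exact point–triangle distances; candidates whose
normal opposes the vertex normal are rejected, which keeps points on the
correct sheet where the luminal and outer walls of the branch run close
together. The internal target is `L = target/1.07` because a structured
right-triangle grid has mean edge ≈ 1.07× its spacing; iterations stop
when the mean edge is within 8% of the target and the coefficient of
variation is below 22% (comfortably inside the 10%/25% contract). Face
tags are reassigned from the nearest original face. A guard rejects
targets above the sampled main-artery wall thickness (10th percentile of
lumen-vertex→outer-face distance; the minimum would be zero at a branch
ostium where the surfaces legitimately meet).

## Volume mesh

Tetrahedralization is a pluggable backend behind a fixed contract; the
implementation is a Delaunay-filter mesher: the surface vertices are
combined with a body-centred interior lattice at the target edge length
(equivalently, a maximum element volume of a³/(6√2), the regular-tet
volume), points closer than 0.45·h to the surface are dropped, the
Delaunay tetrahedralization of the union is filtered to tets whose
centroid is inside the surface (ray-parity test with a gridded 2D bucket
join, deterministic sub-µm jitter against co-spherical degeneracies).
Boundary vertices of the result lie exactly on the input surface; boundary
*faces* chord concave regions by ~h²/(8R), which is orders of magnitude
below the 1% volume agreement the suite verifies (measured: tet volume =
surface-enclosed volume to ≤0.05% at 0.2 mm). Boundary faces inherit the
nearest surface face's tag; element regions (artery vs branch) come from
the nearest surface tag with ties to artery. tet4→tet10 conversion inserts
shared mid-edge nodes (geometry, hence volumes, unchanged).

## Materials

Moduli (MPa, ν = 0.48 throughout): arterial wall 0.3, fibrotic 0.6,
fibrofatty 0.5, calcium 10, necrotic core 0.02, sleeve 0.4 — the
linear-elastic table used for VH constituents; all overridable. Internally
the solver uses mm/kPa/mN, so moduli are converted to kPa at assembly.

Every tissue pixel becomes a 3D point via its frame's rigid transform, and
each element takes the material of the pixel nearest its centroid. For
speed, pixels are pre-indexed into overlapping arc-length sections
(default 5 mm with 1 mm overlap) and each centroid searches only its
section's KD-tree; if the sectioned nearest neighbor is farther than the
overlap margin the search escalates to the full cloud. The escalation rule
makes the sectioned result *identical* to a global brute-force
nearest-neighbor assignment (verified exhaustively in the suite); exact
distance ties resolve to the lowest pixel index. Centroids farther than a
cutoff (default 1 mm) from every pixel fall back to sleeve with a warning
count. The guarantee assumes the centerline does not fold back on itself
within a section length — true for coronary geometry.

## Finite elements

Small-strain linear elasticity by default (matching the linear-elastic
material table); a compressible neo-Hookean law
(W = μ/2(I₁−3) − μ ln J + λ/2(ln J)², tet4 only, Newton to 1e-8 relative
residual, follower pressure on the deformed faces) is selectable and
agrees with the linear law at small loads (tested). Luminal pressure
(default 17 kPa, a mean systolic value) acts on boundary faces tagged
lumen — including the branch's luminal wall — as consistent nodal forces
(p·A/3 per corner for tet4; p·A/3 per mid-edge node, zero at corners, for
straight-sided tet10) directed into the wall. Nodes of the end caps and
branch caps are fixed in all axes. The load ramps linearly over a 1 s
pseudo-time in `steps` increments (default 10); for the linear law the
final state equals the single full-load solve by superposition, so one
assembled solve is performed.

Solvers: direct sparse LU up to 30k dofs; above that Jacobi-preconditioned
conjugate gradients (relative tolerance 1e-10), which on these quasi-shell
meshes is an order of magnitude faster and far leaner in memory than
sparse LU. The solution is solver-independent to well below 1e-8.

Post-processing: constant-strain Cauchy stress per tet4 (centroid strain
for tet10), Von Mises effective stress, and volume-weighted nodal
averaging ("nodal smoothing") — a convex combination, so nodal extrema
never exceed elemental extrema. A note on element-level stress quality:
at ν = 0.48 constant-strain tetrahedra exhibit element-scale pressure
oscillations (near-incompressible locking); band or nodal averages are
accurate (mid-wall hoop stress within 2% of the thick-walled-cylinder
closed form at 0.2 mm), while the element-wise RMS stress error is large
at coarse resolution and decreases under refinement. The validation suite
therefore checks magnitudes on band means and convergence on the
volume-weighted RMS error; quadratic tet10 elements reduce the RMS error
by an order of magnitude at equal edge length.

The cylinder validation solves the 90° quarter wedge with symmetry rollers
(u_y = 0 on y = 0, u_x = 0 on x = 0) — the identical boundary-value
problem at a quarter of the unknowns; inner-surface radial stress is
recovered by quadratic extrapolation through the first three element-layer
means, the standard surface-stress recovery for centroid-valued elements.

A sleeve-sensitivity driver repeats reconstruction and solve over a range
of sleeve thicknesses (default 0–0.4 mm) and reports the volume-weighted
mean Von Mises stress of the true tissue: thicker artificial support
shares the pressure load and lowers wall stress, so reported stresses
must always be read together with the sleeve setting.

FEBio export writes a spec-3.0 XML document: per-material neo-Hookean
cards (E in MPa for FEBio's mm/N/MPa convention), tet4 element domains
grouped by material, the pressure surface with a linear (0,0)→(1,1) load
curve over 1 s, and the fixed node set. tet10 export is not implemented.

## Phantom generator

The phantom defines the study conditions: a 0.5 mm frame spacing (gated
0.5 mm/s pullback at ~1 frame/s; the true gated spacing is not knowable
from the acquisition description, so it is a parameter), 400 px frames at
0.02 mm/px, lumen radius ≈ 1.4 mm with a gentle sinusoid plus small seeded
random-walk perturbation, wall thickness 1.0 ± 0.2 mm. Inclusions are
defined in frame-local polar coordinates (angle range, radial fraction of
the wall) so they remain inside the wall as radii vary: one small calcium
patch (60° × ~15% of the pullback, mid-wall — deliberately small, like
spotty calcification, so coarse meshes misresolve it), a larger necrotic
core, and fibrotic/fibrofatty regions. The optional branch erases a 40°
angular gap over ~20% of the frames. Centerlines are helical (radius
15 mm, pitch 40 mm — gentle coronary-like curvature) or straight.
Ground truth is exact pixel counts per frame plus idealized analytic
constituent volumes (trapezoidal between frame cross-sections).

What the phantom does *not* emulate: ultrasound speckle, VH classifier
noise, catheter eccentricity, irregular gating, or non-annular lumen
shapes. Passing the suite therefore demonstrates correctness of the
geometry/meshing/assignment/solver chain, not robustness to real VH image
noise.

## Problem sizes in the test suite

The suite is sized for a single CPU: validation cylinder ladder at
0.2/0.15/0.1 mm (quarter model, up to ~107k dofs) plus tet10 at 0.15
(~261k dofs); phantom volume recovery on a 10-frame (4.5 mm) pullback at
0.1 mm (~0.8M elements); mesh-convergence sweep on a 6-frame segment at
0.35/0.30/0.12/0.08 mm (a short segment in the spirit of the 5-slice
stress sub-study); assignment equivalence with ~5k elements against
~0.9M pixels; stress plausibility at 0.2 mm. These sizes are the package's
validation conditions; all scale linearly if enlarged.

## Known limitations

- Element-level stresses from tet4 at ν = 0.48 oscillate (use nodal or
  band averages, or tet10).
- Material boundaries are not mesh-conforming; stiff–soft interfaces are
  diffused over one element, which inflates local stress at
  calcium/necrotic contacts.
- The branch wall is artificial (dilation factor), branch caps are flat,
  and trifurcations sharing one hole are unsupported.
- No residual stress, perivascular contact, or pulsatile loading; the
  model is a static pressurization snapshot.
- The sectioned-assignment equivalence guarantee assumes the centerline
  does not fold back within one section length.
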