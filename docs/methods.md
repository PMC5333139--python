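# Methods

## Scope and study design

`petalfem` models one petal lamina of an unopened *Camellia* flower bud as
a thin linear-elastic shell, embeds a synthetic sclereid network in it as
beam elements, loads it with a statically equivalent raindrop force, and
compares the equivalent elastic strain fields of the reinforced and
unreinforced configurations on the *same* mesh, load and parenchyma. The
with/without contrast on fixed geometry isolates the mechanical effect of
the sclereids; it deliberately does not try to reproduce any particular
specimen's geometry.

## Geometry and meshing

The lamina midsurface is an ovate outline (widest near 45% of the length,
tapering to a rounded apex and a narrow attachment edge) lifted onto a
shallow cup. Coordinates: x across the width, y from base (v = 0) to apex
(v = 1), z out of plane; file units are mm.

Defaults: length 15 mm, width 10 mm, thickness 0.3 mm, cup sagitta 2 mm,
target edge length 0.35 mm (≈ 1950 facet elements, ≈ 1030 nodes). The
dimensions are plausible for a *C. sinensis* petal primordium and are fully
configurable; every report carries the configuration hash. The default
resolution is the package's standard operating size: it keeps a full
calibration + 5-seed comparison within minutes on one CPU while the
solution is mesh-converged (max deflection changes < 1% when the edge
length is halved).

Meshing is a structured strip triangulation of constant-v rows, which
guarantees a connected 2-manifold with consistent winding and is bit-
reproducible for a fixed specification. Quality diagnostics use
q = 4√3·A/Σlᵢ² and the normalized equiangular skewness
s = max((θmax−60°)/120°, (60°−θmin)/60°) — the usual commercial-mesher
conventions; the generated meshes have quality ≈ 0.93 ± 0.05 and skewness
≈ 0.19 ± 0.06.

## Shell and beam elements

Each triangle is a flat facet shell: CST membrane superposed with a
discrete-Kirchhoff (DKT) bending triangle. The DKT stiffness is built
directly from its defining constraints — quadratic rotation interpolation
over the 6-node triangle, corner rotations equal to the deflection
gradient, midside tangential rotation from a cubic edge deflection, and
midside normal rotation averaged linearly — integrated with the 3-point
Gauss rule (exact for the linear curvature field). By construction the
element reproduces arbitrary constant-curvature states exactly; this and
rigid-body invariance are asserted in tests, and the element is validated
against the Navier plate series (0.05% at 32 × 32), the Scordelis–Lo roof,
the pinched hemisphere, and the Reissner point-load-on-shallow-cap closed
form.

Drilling rotations (about the facet normal) carry no physical stiffness in
this formulation. They are stabilized with a small penalty of magnitude
10⁻⁶·E·t·A on the pattern that vanishes for element-wise constant drilling,
so rigid rotations remain exactly strain-free. The scale E·t·A has units of
moment — i.e. it is a *rotational* stiffness scale — which keeps the
penalty a fixed small fraction of the physical bending stiffness in any
unit system. (Scaling the penalty by the element's maximum diagonal, a
common shortcut, mixes translational N/m and rotational N·m entries and can
silently dominate the bending stiffness of thin, soft shells; this failure
mode was observed during development, visible as severe mesh-dependent
stiffening, and is guarded by the convergence test.) On perfectly flat
meshes the stabilized system retains one near-zero constant-drilling mode;
any rotational constraint (the clamped base) removes it.

Sclereid segments are 3-D Euler–Bernoulli space-frame beams (axial,
bending, torsion; circular section, default radius 30 µm) tied to the shell
by node sharing, so beams inherit shell rotations at shared nodes. Because
sclereid cells (100–300 µm) are shorter than the default element edge
(350 µm), the two endpoints of a segment snap to the nearest *distinct*
mesh nodes; the beam network is therefore a mesh-resolution abstraction of
the cell network — its density and orientation statistics, not individual
cell geometry, carry the reinforcement.

## Materials

| parameter | default | basis |
|---|---|---|
| E sclereid | 0.5 GPa | reported stone-cell value, bracketed by plant fibers (0.49–1.0 GPa) |
| ν sclereid | 0.4 | reported |
| E parenchyma | 10 MPa | free parameter; soft ground tissue, calibrated (below) |
| ν parenchyma | 0.3 | generic soft tissue |

Poisson ratios at or beyond 0.5 (the fibers' quoted incompressible value)
are clamped to 0.49 with a warning, since ν = 0.5 is singular in plane
elasticity.

The parenchyma modulus is genuinely unknown for these organs. Rather than
guessing, `calibrate_parenchyma` bisects log-E in a physical bracket
(1–100 MPa) until the max-strain ratio matches a target (default the
published 2.3-fold contrast) at a fixed network seed; the ratio is monotone
decreasing in E (stiffer parenchyma makes the beams relatively weaker), so
the bisection is well posed. With all other defaults the calibration lands
at E ≈ 10 MPa. The calibration record (bracket, trace, seed) is embedded in
every report.

## Boundary conditions

The proximal attachment edge is clamped (all 6 DOF). In the closed bud the
petal margin is not free: neighboring petals and the sepal whorl overlap it
and together form a rigid protective shell. The pipeline therefore pins the
margin translations (rotations free) by default (`supports.margin:
pinned`; `free` is available). This support model is what produces the
observed apical strain localization; a free-margin single petal is a
cantilever whose strain concentrates at the clamped root instead, which is
not the configuration the bud anatomy suggests.

## Raindrop load

F = ρ·(πd³/6)·v/τ with contact time τ = d/v, i.e. F = ρπd²v²/6 ≈ 0.0754 N
for the default 2 mm, 6 m/s drop (a stagnation-pressure closure
F = ρv²·πr_c² is also available; the choice is recorded in provenance).
The force acts along local surface normals over the nodes within the 1 mm
contact radius of the impact point (default (u, v) = (0.5, 0.8), the apical
region), weighted by a cosine taper times the tributary nodal area so the
discrete distribution converges to a fixed pressure footprint under
refinement. Nodal force magnitudes sum exactly to F. One quasi-static drop
per analysis; impact dynamics and fluid–structure interaction are out of
scope.

## Synthetic sclereid networks

A sclereid cell is one column segment with length uniform in the profile's
range (default 100–300 µm) and isotropic in-plane orientation, plus k ∈
[2, 6] branches (half the column length) fanning outward from randomly
chosen column ends. Cells are placed by rejection sampling against the
gradient weight — apical w ∝ v², central w ∝ 1 − |2v − 1|, uniform — and
must lie entirely inside the lamina outline.

Coverage is the area of the union of segment footprints (each segment
dilated by the 50 µm influence half-width, a stadium shape) divided by the
lamina plan area; overlaps are never double-counted, and the union is
computed exactly with polygon geometry (buffers use 8 segments per quarter
circle, a ≈ 0.1% area error, far below sampling noise). Placement proceeds
in batches sized by a Poisson-overlap coverage model and stops inside
±0.02 of the target; a hard cap of 10⁵ cells guards unreachable targets.
Species presets: `sinensis_petal` (coverage 0.5, apical),
`japonica_petal` (0.02, uniform), `sepal` (0.5, central — the observed
central concentration; sepal coverage is not quantified in the source
anatomy, so 0.5 mirrors the "large numbers" observation and is
configurable). Coverage and the per-element density field are measured in
the flattened plan view; the cup is shallow enough that the metric
distortion (< 2%) is ignored.

What the generator does *not* emulate: real sclereid shape diversity
(polymorphic, interlocking cells), mechanical entanglement between cells,
through-thickness position, and any correlation between cell size and
location. Passing tests therefore demonstrate the mechanical consequences
of *coverage and spatial distribution*, not of cell-scale morphology.

## Numerical choices

* Sparse Cholesky-like direct solve (SuperLU) with up to 3 steps of
  iterative refinement: the 0.5 GPa beams on a ~MPa shell span ~10 decades
  of stiffness and one LU pass can leave residuals above the 10⁻⁸
  acceptance threshold. Residual and reaction balance are checked on every
  solve.
* During calibration the shell stiffness is assembled once at a reference
  modulus and rescaled exactly (it is linear in E); beams are assembled
  once. This is an algebraic identity, not an approximation.
* Strain recovery: membrane strain and curvature at the element centroid;
  surface strains at z = ±t/2 and 0; ε_z from the plane-stress condition
  ε_z = −ν/(1−ν)(ε_x+ε_y) before the principal decomposition; the element
  value is the maximum over the three surfaces. ν′ in the equivalent-strain
  normalization is the element material's ν (the common solver default).
  The reported maximum is never nodal-averaged.
* Ties at the strain argmax break to the lowest element id.
* Comparison runs default to 5 seeds with mean ± sd reported — the seed
  spread is this package's own disclosure of network stochasticity; the
  source study reports a single model realization.

## Known limitations

* Linear kinematics: peak deflections reach the shell thickness, so the
  true response is geometrically nonlinear (membrane stiffening); the
  linear model matches the comparative, not absolute, character of the
  study.
* The absolute strain values depend on the calibrated parenchyma modulus
  and the invented geometry; only the ratio, the localization pattern and
  the coverage statistics are reproduction targets.
* Single petal with an effective margin support, not a multi-petal contact
  model.
* Beam network is a statistical abstraction at mesh resolution (see above);
  sclereid-to-sclereid entanglement is not modeled.
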