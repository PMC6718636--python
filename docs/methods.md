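# Methods

## Volume-conductor model

The electrolyte/tissue around the implant is treated as a purely ohmic,
homogeneous, isotropic medium, so at DC the potential obeys

∇·(σ∇V) = 0

with three materials: physiological liquid (σ = 1.47×10⁻² S/m), the
insulating polymer substrate (σ = 1.31×10⁻¹⁸ S/m) and the electroplated
metal (σ = 45.6×10⁶ S/m).  Relative permittivities are carried in
`MaterialProps` for completeness but never used: the solve is steady-state,
with no displacement current, no electrode capacitance and no transient
response.  Boundary conditions:

- **Insulating surfaces** (substrate, domain truncation box): ∇V·**n** = 0.
- **Electrode–electrolyte interfaces**: the mixed (Robin) condition
  σ∇V·**n** = g (V_metal − V), with surface conductance g in S/m².  The
  metal interior is never solved; each metal is an equipotential at its
  applied value (1 V on the stimulating electrode, 0 V on the ground grid by
  default).
- Optionally a grounded top face or a grounded far-field box
  (`outer_boundary`), used for open-bath comparisons against analytic
  electrode formulas.

### Discretization

Cell-centered finite volumes on a uniform voxel grid.  Faces between two
liquid voxels carry conductance A/h·σ̄ with σ̄ the harmonic mean; faces
against metal carry the interface conductance in **series with the
half-cell bulk path**, k = 1/(1/g + h/(2σ)) per unit area.  The series form
matters: its g → ∞ limit is exactly the discrete Dirichlet condition at the
metal face, so the "ideal electrode" mode and the large-g Robin solve agree
by construction, and a 1D interface/bulk/interface stack reproduces the
three-resistor divider 1/g : L/σ : 1/g to machine precision.

Insulator voxels are excluded from the solve by default and their faces
treated as zero-flux.  This is the exact σ_insulator → 0 limit: at
1.31×10⁻¹⁸ S/m the coupling is ~16 orders of magnitude below the liquid
conductances, i.e. invisible at double precision, while keeping the voxels
would add a floating all-Neumann block that makes the system numerically
singular.  `include_insulator=True` retains them (a test shows the liquid
solution is unchanged).

The matrix is symmetric positive definite and solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 10⁻⁹ with a fixed node
ordering, so solves are bit-deterministic.  The current density is recovered
per voxel as the mean of the two discrete face fluxes along each axis — the
exact fluxes the scheme conserves — rather than by naive differences, which
would be inconsistent at electrode faces where the boundary value lives on
the face, half a voxel from the neighbour center.

Verification oracles (all in the test suite): exact 1D divider solutions;
uniform-field stacks; Kirchhoff conservation (stimulating + ground currents
balance to ≤ 1%); linearity in the applied potential; Robin(g = 10⁶ S/m²) vs
ideal agreement ≤ 1% RMS; mesh convergence of the electrode current (< 5%
between 2 µm and 1 µm voxels); and the classical disc-electrode access
conductance G = 4σa, matched within 5% using two geometrically similar
grounded boxes and Richardson extrapolation in inverse box size (the
extrapolation removes the leading O(a/L) truncation bias of any finite bath,
which would otherwise be 3–10% for affordable domains).

### Geometry

Structures are voxelized by center-point sampling on the X/Y/Z family: a
regular hexagonal well (flat-to-flat X, flats normal to the y axis) of depth
25 µm in the substrate; an electrode disc of diameter Y (one voxel thick) on
the floor; 0–4 mushroom pillars — cylindrical stems of diameter Z capped by
a flat 15 µm disc, 7 µm total height — placed deterministically at half the
electrode radius (pairs along y, triangles pointing +y, squares on the
diagonals); and a 10 µm ground plane on the rim, perforated by the well
opening.  Pillar caps are flat discs rather than domes: the cap diameter is
the electrically dominant feature and voxel fidelity to dome curvature at
2 µm resolution would be illusory.

Unstated dimensions were fixed once as follows.  Well depth: not reported;
it must exceed the 7 µm pillars, and 25 µm (≈ 2.5× the remaining liquid
column above the caps) is the value at which the reported line-C peak
structure of all three geometries coexists over a robust range of sampling
heights rather than at a single voxel level — we treat this as
identification of an unstated geometric parameter from the printed field
structure.  Ground-plane thickness: 10 µm (the plating mold is 15 µm, an
upper bound).  Substrate slab below the floor: 6 µm.  All are configurable.

### Comparison artifacts

`compare_geometries` solves the flat (G0), one-mushroom (G1) and
two-mushroom (G2) structures with every other parameter identical — same
grid dimensions, same boundary settings — and reduces each solution to:

- **Line profiles** of |J| along the well-width (y) axis through the well
  center at three heights.  Line C sits inside the cavity at cap top + 5 µm:
  far enough above the caps that each cap's two rim singularities have
  merged into a single protuberance-aligned maximum, close enough to the
  floor that the planar electrode's edge peaks are not yet masked by the
  convergence of current toward the well opening.  Line B is at ground-plane
  mid-thickness, line A one well-length above the ground plane.  Heights are
  shared by all three geometries.
- **Peak counts/positions**: strict local maxima with prominence ≥ 5% of the
  profile range, ignoring maxima within one voxel of the profile ends.  The
  threshold mirrors what a reader would count by eye in a printed curve and
  is configurable.  With mushrooms present, the peaks over the caps sit
  2–3 voxels outside the pillar axes — current crowds the outer flank of
  each cap, where there is more room toward the wall — so "alignment" is
  asserted against the cap footprint, not the axis, except for a single
  centered pillar where the peak is axis-aligned to one voxel.
- **Attenuation**: the peak |J| over the stimulation zone (|y| ≤ electrode
  radius) per line.  This is deliberately a scale-bearing statistic: the
  peak-to-mean ratio, which is also reported, is scale-invariant and
  measures profile *shape* — on line B it is dominated by the ground-plane
  inner-edge singularity and on line A by the dome shape of the far field,
  for every geometry including the flat one — so it cannot express that the
  electrode's near field fades with distance, whereas the zone peak falls
  ~1.5× from line C to B and ~200× from B to A.
- **Field concentration**: maxima of |∂²V/∂z²| and |∂²V/∂y²| (central
  differences over voxels whose axial neighbours are both liquid) in the
  **central cavity zone** — cavity liquid within 0.75× the electrode radius
  of the well axis.  The second derivative of the extracellular potential
  along a neural process is the classical activating-function predictor of
  stimulation efficacy.  The zone restriction excludes the electrode-rim and
  ground-corner singularities, which are shared by all three geometries and
  would otherwise dominate the maximum (and did, in early experiments, to
  within 1%); inside the zone the mushrooms raise the axial statistic by an
  order of magnitude over the flat electrode.

Known limitations of this stage: absolute current magnitudes depend on the
interface conductance g, which is not known for the modeled device — field
comparisons therefore default to ideal electrodes and only *relative* and
*structural* statements (peak counts, orderings, ratios) are meaningful;
voxel staircasing limits the fidelity of curved surfaces; the retina is
modeled as homogeneous liquid with no cell-scale heterogeneity and no neuron
model — activation is assessed only through the field's second derivatives.

## Histology composition statistics

Each explanted cavity contributes counts of bipolar, glial and other cells.
Because cavity volume varies with width and pillar count, counts are
normalized to percentages within each cavity first, and groups are then
summarized by the unweighted mean and sample (n−1) SD of per-cavity
percentages — the cavity, not the cell, is the replication unit.  Empty
cavities are flagged and excluded rather than raising.  The dispersion
convention (± as SD) is an assumption; the convention is configurable in the
sense that raw per-cavity percentages are returned and any dispersion can be
recomputed.  No hypothesis tests are run: the reported quantities are
descriptive.

The study design (16/8/3 exploitable cavities at 100/80/60 µm; 12/7/9/9/7
cavities with 0–4 pillars) is encoded in `design_table()` and used to size
synthetic datasets.

## Synthetic data generators

**Cavity compositions.**  Per cavity, a total cell count ~ Poisson(mean 30)
and a multinomial class split with group-specific probabilities equal to the
renormalized reported group means (e.g. 84.10/5.11/10.79% for 100 µm
cavities).  The Poisson mean is not reported by the study; 30 cells/cavity
makes the per-group SDs the same order as the reported ±4–14%.  The groups
with one and three protuberances have no reported per-class values; the
bundled model fills them by linear interpolation of the neighbouring groups
and marks them as synthetic stand-ins — no recovery claim is made for them.
The two-protuberance bipolar value is the complement of the reported glial
and other percentages.

What the generator emulates: group-level composition means and
cavity-to-cavity multinomial scatter.  What it does not: overdispersion
between animals or implants, spatial correlation between neighbouring
cavities, counting error, and any dependence of total cell number on cavity
size.  Recovery tests therefore validate the *analysis stage's unbiasedness
and the bundled calibration*, not the biology.

**Evoked recordings.**  Each trial is template × r(I) + white Gaussian noise
(SD 20 µV) at 25 kHz, with the trigger at a fixed sample.  The template is a
biphasic cortical wave (negative lobe of 20 ms FWHM peaking exactly at the
45 ms nominal latency — the construction shifts the wave to compensate for
the rebound lobe pulling the extremum — followed by a half-amplitude
positive rebound), peak deflection 80 µV.  The amplitude-response function
r(I) is a logistic in the stimulation current with threshold 96 µA and width
4 µA, placing the detection threshold between the 64 and 128 µA protocol
amplitudes with the 64 µA response (< 0.2% of saturation) firmly inside the
noise floor.  Latency jitter defaults to 0 (trials are trigger-aligned);
Gaussian jitter is available for robustness experiments.  Not emulated:
line noise, burst artifacts, stimulus artifact bleed-through, background
cortical rhythms, channel geometry of the 16-channel probe.

## Evoked-potential analysis

The band-pass (default 1–100 Hz) is a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), i.e. zero-phase, so filtering adds no
latency bias — a symmetric pulse stays symmetric.  Trials are aligned on
their trigger sample and cropped to the largest common window before
pointwise averaging.  The response measure is the maximum |deflection| from
the pre-trigger baseline mean (50 ms window) within a 0–300 ms post-trigger
window; its time is the latency.  A flat trace reports amplitude 0 with
undefined latency.

Response detection uses 3× the *single-trial* filtered baseline SD, not the
averaged trace's baseline SD: the max-deflection statistic inflates to
≈ σ√(2 ln n_eff) under the null, so a 3σ cut on the averaged baseline is met
by pure noise about half the time, while the single-sweep reference is a
conservative ~30σ criterion at 100-fold averaging.  The stimulation waveform
builder enforces exact charge balance by construction (symmetric integer
sample counts per phase); note the protocol's three 3 ms units span 9 ms of
stimulation — the generator produces exactly 9 ms and makes no attempt to
pad to a round 10.

The amplitude series reports a Kendall concordance between stimulus current
and evoked amplitude as a descriptive monotone-trend statistic; with a
saturating response and only four amplitudes it is deliberately not a test
statistic.  Channel selection on multi-channel recordings (the
largest-response channel) is applied upstream of this package and is out of
scope.

## Problem sizes and numerical defaults

Field comparisons run at 2 µm voxels (≈ 350k unknowns per geometry for the
100/80/12 configuration; all three geometries solve in a few seconds), CG
tolerance 10⁻⁹, maximum 20 000 iterations.  Histology recovery uses 2000
replicates per group.  The disc-electrode oracle uses disc radius a = 8
voxels with boxes of half-width 5a and 10a.  All generators and solvers are
pure functions of (parameters, seed); fixed seeds appear only in tests and
in the acceptance script's command line.
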