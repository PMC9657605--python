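# Methods

This note documents the models, numerical choices and limitations of
`vertep` at the level a maintainer or reviewer needs to judge what the
results do and do not show.

## Physical model

The electric field during pulse delivery is treated as stationary: pulse
durations (~100 µs) are long against charge relaxation in tissue, so the
potential solves ∇·(σ∇V) = 0 with the pulse amplitude applied as a
Dirichlet value on one exposed needle segment, 0 V on the other, and
zero-flux conditions on the outer boundary of the tissue block (the block
is large enough that this choice is immaterial; see the phantom section).
Tissue conductivity increases where the local field electroporates
membranes.  This feedback is modelled per tissue as a C²-continuous
smoothed step in E = |∇V| (quintic smoothstep between σ₀ below the
transition zone and σ₀·f above it).  Any C² sigmoid would serve; the
quintic polynomial is exact at the endpoints, symmetric about the zone
center (σ(c) = σ₀(1 + (f−1)/2) exactly), and cheap.

Default tissue parameters (S/m, –, V/cm, V/cm): bone (0.07, 2.9, 600, 400),
tumor (0.30, 2.8, 600, 400), surrounding soft tissue with adipose
properties (0.02, 3.0, 300, 400).  The electrode metal is not modelled as a
material: the needle voxels are Dirichlet nodes, which is equivalent to a
perfect conductor in the stationary limit, and their voxels are excluded
from all coverage tallies because they hold metal, not tissue.

## Discretization

Cell-centered finite volumes on the label grid; interior faces carry the
harmonic mean of the adjacent voxel conductivities (exact for layered
media, and it keeps the operator an M-matrix, hence the discrete maximum
principle tested in the suite).

**Embedded-boundary needle coupling.**  The needle radius (0.6 mm) is below
the default voxel size (1 mm), so a staircase Dirichlet mask misrepresents
the needle's effective radius by O(h) — measured as ~7–18% in delivered
current between 1 mm and 0.5 mm grids.  Faces between a needle voxel and
tissue therefore use the distance from the tissue voxel center to the
*physical* needle surface (clipped to [0.1h, 1.5h]) in place of the cell
spacing, with the tissue-side conductivity.  The needle is an equipotential,
so anchoring the flux at its surface is consistent; with this coupling the
tissue volume above 400 V/cm changes by < 3% between 1 mm and 0.5 mm grids
on a reference phantom, and the delivered current is computed from the same
face conductances, so active and return currents balance to solver
precision.  The analytic benchmark hook (explicit Dirichlet masks) accepts
an optional surface-distance array so the concentric-sphere oracle runs
with the same scheme.

**Nonlinear iteration.**  σ(E) is resolved by Picard iteration.  The plain
fixed-point map oscillates between conductivity states on realistic
phantoms (voxels near the transition zone flip collectively), so the update
applies geometric under-relaxation (σ ← √(σ_old·σ_new)) during the initial
transient (relative change > 0.2) and whenever the undamped step fails to
contract (change > 0.6× the previous); elsewhere it is undamped, where
convergence is fast.  Convergence: max relative σ change < 10⁻³ (default),
cap 50 inner iterations; non-convergence is reported on the solution, not
raised.

**Linear solves.**  Matrix-free conjugate gradients preconditioned by the
constant-coefficient Neumann Laplacian inverted spectrally in the DCT-II
basis (reference conductivity: geometric mean over tissue).  The iteration
count is then nearly grid-independent (~10–40 on the 1.17-Mvoxel default
grid).  Early Picard steps solve only to min(10⁻⁴, 0.02 × current σ
change); after Picard convergence the last system is re-solved at the
configured tolerance (10⁻⁷ relative residual by default).  Solves are
warm-started from the previous potential (scaled by the voltage ratio) and
the previous σ during voltage ramps and between optimizer iterations.

**Field magnitude** is the norm of the central-difference gradient of V at
voxel centers, reported in V/cm.  Coverage decisions are made at voxel
centers; no sub-voxel interpolation.

## Coverage and islands

The CTV weighting map uses the Euclidean distance transform (voxel-center
metric, mm) from the tumor label: weight 1 on the GTV, 1 − (1−ω_edge)·d/m
within the margin m (default 5 mm), 0 beyond; ω_edge (default 0) can be
raised (e.g. 0.5 for metastatic tumors) to keep a residual requirement at
the outer CTV edge.  "Soft coverage" is implemented as a weight-scaled
local threshold — a voxel with weight ω is covered iff E ≥ ω·400 V/cm —
because the alternative reading (weighted average of a fixed-threshold
indicator) can never report 100% and would deny the optimizer its main
termination criterion.  Undertreated voxels are grouped with
26-connectivity (most permissive; thin undertreated shells stay whole);
island mass is the weight sum scaled by (voxel volume / 1 mm³) so forces
are spacing-consistent; islands below 10% of the largest mass are
discarded.  Island centers of mass are weight-averaged, which biases them
toward the GTV boundary — intentionally, as the forces should pull
electrodes toward the clinically important deficit.

## Optimizer

Initialization: each needle lies on its operator-defined pedicle line
(entry → direction point); the tip is advanced so the exposed-segment
midpoint is the axis point nearest the tumor center of mass.  Both tips are
then retracted in 1 mm steps until the tips are ≥ 5 mm apart **and** the
exposed segments clear each other by 2·radius + 1 mm; the second condition
is required because tip spacing alone cannot prevent two converging
needles from intersecting.  For exactly parallel pedicle lines retraction
changes nothing; the pair is accepted if the lines clear each other
physically and rejected otherwise.

Forces are applied as displacements in mm at the tip, clipped to
`max_step` = 10 mm per iteration.  The force weights carry mixed implied
units (F_geo is a length, island forces mass/length², repulsion 1/length);
the weighted sum is read as mm, matching the magnitudes the selected
weights produce on this geometry (w₁·F_geo ≈ 10 mm at initialization —
consistent with small tumors converging in a single iteration).  The cap
exists to bound island-force spikes when an island CoM passes near a tip
(distances are additionally clamped at 1 mm).

Voltage: U = ratio × exposed-midpoint distance, rounded to the generator
step (100 V) and clamped to [500, 3000] V; the working ratio starts at
1000 V/cm.  At initialization the midpoints may nearly coincide (both sit
near the tumor CoM), which legitimately clamps the first pulse to 500 V.
If a move lowers soft coverage the positions revert and the voltage is
raised 10% above the reverted-to amplitude (rounded, clamped); the working
ratio is raised to U / midpoint distance and stays raised.  Termination:
full soft coverage; coverage change < 0.1 pp between consecutive accepted
iterations (checked only for non-decreases — decreases trigger the revert
rule instead, which keeps the accepted-coverage history monotone); 50
position iterations; a voltage boost requested at the 3000 V cap; or
current > 45 A.  Afterwards, while coverage is incomplete and U < 3000 V,
the voltage ramps in 100 V steps (these solves are warm-started and do not
count as iterations).  Rasterization failures (needle contact, needle
leaving the grid) trigger one retry with each tip displaced 0.5 mm in a
seeded uniformly random direction; a second failure terminates the run with
the last valid state.

The optimizer is deterministic for fixed inputs and seed; the seed feeds
only the error-recovery displacement.

## Synthetic phantoms

The phantom generator emulates segmented vertebra models: a rounded
vertebral body (superellipsoid: elliptic cross-section, capped
superior/inferior, exponent 6) of literature-typical size (lumbar
45 × 35 × 28 mm, thoracic 35 × 28 × 22 mm), two pedicle channels (7 mm
diameter, 12 mm long, ±20° transversal convergence) joining the posterior
aspect, all inside a 130 × 120 × 75 mm surrounding-tissue block.  The
spherical tumor sits at the body centroid, or offset by 40% of the body
half-extent (anterior-lateral / posterior-inferior); when a large sphere
would breach the body surface the offset is shrunk by bisection until the
sphere fits with ~1 mm clearance.  Voxel membership is by voxel center.
Anchors (entry point in the pedicle channel, direction point inside the
body) are generated mirror-symmetric about the sagittal plane.

What the phantoms do *not* reproduce: cortical/trabecular bone distinction,
posterior elements beyond the pedicles, realistic (non-spherical) tumor
shapes, segmentation noise, and inter-patient size variation.  Passing the
cohort tests therefore shows the algorithm handles the paper-scale
geometry, conductivity contrast and generator constraints — not that the
plans are clinically valid for real anatomy.

## Default problem sizes

The evaluation cohort is one lumbar body with 3 tumor locations × 3 radii
(5/7.5/10 mm) at 1 mm spacing (1.17 M voxels per solve) — a desk-scale
stand-in for a 108-model dataset (12 vertebrae × 9 tumor configurations).
The factorial runner defaults to the same 9-phantom cohort; its full
16-group design over 108 models is supported through a directory of
converted volumes but is not exercised in the test suite.  Ranking uses
mean wall time, mean iterations and error count; wall time is recorded in
reports but no automated check depends on it (hardware-dependent).

## Known limitations

- The voxel solver's absolute dosimetry near the needles carries the usual
  staircase/peak-field smoothing of structured grids; the embedded-boundary
  coupling controls the effective-radius error but corner-accurate fields
  would need boundary-fitted meshes.
- Fields are evaluated per electrode pair; multi-pair pulse sequences and
  cumulative-dose overlap are out of scope.
- No thermal (Joule-heating) model; the 45 A limit is the only
  high-current safeguard.
- Tissue parameters are population defaults; no per-patient calibration.
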