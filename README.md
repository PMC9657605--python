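# vertep

Treatment-planning optimizer for electroporation-based therapy
(electrochemotherapy / irreversible-electroporation ablation) of vertebral
tumors using two needle electrodes inserted through the pedicles.

Given a labelled tissue volume (bone / tumor / surrounding soft tissue), two
operator-selected point pairs per pedicle, and per-tissue conductivity laws,
`vertep` iteratively positions the electrode tips and sets the pulse
amplitude so that the clinical target volume (CTV = tumor + 5 mm safety
margin) is covered by a sufficient electric field, while respecting the
constraints of a clinical pulse generator (500–3000 V in 100 V steps, 45 A
current limit) and keeping the entry points fixed for transpedicular access.

## Who this is for

Researchers in computational treatment planning for electroporation who want
a dependency-light, fully scriptable re-implementation of force-based
electrode placement on voxel grids — e.g. to study coverage criteria, force
weightings, or phantom geometries — without a commercial FEM stack.

## The model

**Field.** The stationary potential solves the nonlinear Laplace problem

    ∇·(σ(|∇V|) ∇V) = 0

with Dirichlet conditions on the two exposed needle segments (applied
voltage U on one, 0 V on the other) and insulating outer boundaries.  Each
tissue's conductivity rises with the local field magnitude E (in V/cm)
following a smoothed step with continuous second derivative:

    σ(E) = σ₀ · (1 + (f − 1) · S(t)),   t = clamp((E − c + w/2)/w, 0, 1),
    S(t) = 6t⁵ − 15t⁴ + 10t³

with per-tissue parameters (σ₀, f, c, w): bone (0.07 S/m, 2.9, 600, 400),
tumor (0.30, 2.8, 600, 400), surrounding/adipose (0.02, 3.0, 300, 400).
The discretization is cell-centered finite volumes with harmonic-mean face
conductivities, an embedded-boundary coupling at the needle surfaces, Picard
iteration for the nonlinearity, and DCT-preconditioned conjugate gradients
for the linear solves.

**Coverage.** A weighting map assigns weight 1 on the tumor (GTV), falling
linearly to 0 across the 5 mm margin.  A CTV voxel with weight ω counts as
covered iff E ≥ ω·400 V/cm ("soft coverage"); the GTV must meet the full
400 V/cm electroporation threshold.

**Optimization.** Per iteration, after a field solve, undertreated CTV
voxels are grouped into 26-connected islands with weighted masses mᵢ and
centers of mass; each electrode feels

    F_ele = w₁·F_geo + w₂·Σᵢ F_i,T + w₃·Σᵢ F_i,R ± w₄·F_dd

where F_geo points from the electrode-geometry center to the tumor center
of mass, F_i,T = (mᵢ/‖d‖²)·d̂ attracts the tip (and F_i,R the rear) toward
island i, and F_dd = (1/‖dd‖)·d̂d repels the tips from each other
(default weights 1.3, 0.1, 0.02, 5).  The force moves the tip (entry
fixed); the voltage follows U = 1000 V/cm × exposed-midpoint distance,
rounded to 100 V.  Moves that lower soft coverage are reverted and the
voltage raised 10% instead; the loop stops on full coverage, a coverage
change < 0.1 pp, 50 iterations, 3000 V, or 45 A, followed by a final 100 V
voltage ramp while coverage is incomplete.

Synthetic vertebra phantoms (parametric body + pedicle channels + spherical
tumor at central / anterior-lateral / posterior-inferior positions, radius
5 / 7.5 / 10 mm, in a 130 × 120 × 75 mm tissue block) stand in for
patient-segmented models.

## Worked example

```bash
vertep plan --phantom lumbar,central,5 --out-dir plan_out --seed 1
```

prints (timing machine-dependent):

```
full_coverage: U=1200 V, GTV 100.0%, soft CTV 100.0% (1 iterations, 28 s) -> plan_out/plan.json
```

meaning: for a 5 mm central tumor in a lumbar body the optimizer reached
100% GTV coverage at the 400 V/cm threshold and 100% soft CTV coverage in a
single iteration, with a 1200 V pulse amplitude (the voltage-to-distance
rule applied to the converged geometry).  `plan_out/plan.json` holds the
electrode entry/tip coordinates (mm, volume frame), predicted current,
per-iteration history, and the surgical insertion parameters (transversal
and sagittal angles, entry distance from the sagittal plane, insertion
depth); `plan_out/log.txt` is the step-by-step optimization log.

The same API is available in Python:

```python
import vertep

spec = vertep.PhantomSpec(segment="lumbar", tumor_location="central", tumor_radius=5.0)
volume, anchors, tumor_com = vertep.generate_phantom(spec)
plan = vertep.optimize(volume, anchors, tumor_com)
print(plan.termination_reason, plan.applied_voltage, plan.ctv_soft_coverage)
```

Other CLI entry points: `vertep phantom` (generate and save label volumes +
anchor JSON) and `vertep factorial` (the scaled-down full-factorial
experiment over the four force weights, with rank-based group selection and
a Kruskal–Wallis group test).

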