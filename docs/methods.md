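# Methods

## Scope and intent

The package is a fully synthetic reimplementation of a virtual-population
study of psoas tendon snapping. The original kind of study rests on a
statistical shape model trained on hundreds of segmented lower limbs; no
such training data ships here. Instead, a parametric anatomy generator
plays that role: it produces pelvis–femur geometries whose population
statistics match published sex-specific tables of discrete measures, and
whose construction encodes, as explicit geometry, the couplings that the
snapping literature describes. Everything downstream — shape modeling,
tendon simulation, statistics — operates on generator output exactly as it
would on real data.

## Coordinate frame and units

Right hip, right-handed: +x anterior, +y medial, +z superior; origin at
the femoral head center in neutral pose. Lengths in mm, angles in degrees,
velocities in deg/s.

## The synthetic anatomy

Each case is determined by five clinical measures (neck-shaft angle NSA,
femoral anteversion AV, femoral offset, ischiofemoral distance IFD, head
radius r) drawn from per-sex truncated normals. Defaults are the
western-European adult values built into `PopulationConfig` (e.g. male
offset 43.89 ± 6.54 mm, female IFD 22.23 ± 4.34 mm); truncation bounds are
generous validity intervals (rejection sampling, negligible effect on the
moments). Inter-measure correlations default to zero; a 5×5 correlation
matrix can be configured.

Bones are unions of sphere-swept solids (spheres, capsules, one torus arc)
with exact signed distances; each component also emits a watertight
triangle mesh for export, landmark sampling and mesh-based measurement.
The femur comprises head sphere, a two-segment neck sleeve (a joint-capsule
surrogate, wider than a bony neck: it creates the concave head–neck groove
against the head sphere and closes non-anatomical shortcut corridors under
and behind the neck), proximal/distal shaft capsules with a 4 mm anterior
bow, greater trochanter, the lesser-trochanter capsule, a **calcar
prominence** and a **lateral groove lip** (below). The pelvis comprises the
iliopectineal ridge (medial wall of the psoas groove at the brim), the
pubic-ramus bar under the tendon's brim crossing, an acetabular dome
sphere and rim arc with an anterior notch (the iliopsoas groove), an
inferomedial capsule bar (the acetabular fossa / medial capsule region),
and the ischium.

Measurement closure: the five measures are recovered from a built instance
by line fits (shaft, neck, condylar axes), an algebraic-plus-Gauss-Newton
sphere fit (head), point-to-line distance (offset), and an
ischium-to-lesser-trochanter surface proximity query (IFD; landmark-pair
fallback for bare landmark sets). Closure errors are < 0.1° for angles and
< 0.1 mm for lengths, so measured cohort tables are effectively ground
truth.

### The dysplasia coupling

The study's central anatomical claim is that a single rotational-dysplasia
pattern — valgus, anteverted femora with low offset, a narrow
ischiofemoral gap and (weakly) smaller heads — presents as a medially
located minor trochanter and snaps. The generator realizes this as one
variable, the *dysplastic medial prominence*:

```
raw = 0.6·softplus₄(29 − IFD) + 0.65·(NSA − NSA_ref) + 0.7·(offset_ref − offset)
      + 0.8·(AV − AV_ref) + 2.5·(r_ref − r)
medial_extra = 10·tanh(raw/10)   (raw ≥ 0; floor −9 mm below)
```

with per-sex reference means for the angular/size terms and an *absolute*
softplus hinge (onset 29 mm, softness 4 mm) for ischiofemoral crowding —
crowding is a property of the gap itself, which is why the sex with the
narrower gap is systematically more exposed. `medial_extra` (mm) shifts
the lesser trochanter's reach medially, raises the calcar prominence at
the inferomedial head–neck junction into the tendon's station, and grows
the lateral groove lip (a cam-like overgrowth of the anterolateral
junction). The coupling magnitudes were fixed during design so that the
relative strengths of the five measure–velocity associations resemble the
published correlation table; the tanh ceiling keeps extreme variants in
the snapping regime instead of a saturated dead zone. The ischium is
placed *after* the trochanter so the neutral-pose surface gap equals the
sampled IFD exactly, preserving closure.

## Landmarks and shape model

A 600-point template (configurable) samples each component at fixed
parametric coordinates in the component's own frame, so index k is the
same material location on every instance — correspondence by construction.
Two template points sit at the ischiofemoral facing pair, which makes the
landmark-based IFD measure exact.

The PCA model uses the dual (economy-SVD) decomposition of the centred
landmark matrix; optional generalized Procrustes alignment is rigid only
(scale retained — size is anatomy). Mode retention takes the smallest k
reaching 99% cumulative variance, capped at 20; the pipeline additionally
floors retention at 5 modes, the generator's degrees of freedom, because
truncating below the generative dimensionality collapses one anatomical
axis and scrambles the measured cohort statistics. Cohorts are sampled as
independent `N(0, λ_i)` weights, reconstructed to landmarks, re-measured,
and rebuilt through the generator so that each virtual case has solid
geometry consistent with its measured parameters.

## Kinematics

Clinical angles compose intrinsically as
`R = R_abd(x)·R_flex(y)·R_rot(z)` about the head center; with flexion as
the middle angle the decomposition is unique and exact for |flexion| < 90°,
so the apex (90, 60, 30) round-trips exactly. Signs follow the right-hip
clinical convention (abduction lateral, flexion anterior, external
rotation turning the anterior femur laterally). The default sequence has
120 frames: a simultaneous linear ramp up over the first 60 steps and down
over the remaining 59, first and last frames neutral. (Exactly 120 frames,
neutral endpoints and an exact integer apex cannot all be split evenly;
the extra step is assigned to the up-phase.) Frame times follow from the
per-step geodesic rotation angle at 25 deg/s.

## Tendon solver

The tendon is a 40-node chain with pinned endpoints. Each iteration
applies (1) an implicit curve-shortening step — the pinned-end implicit
Laplacian with weight 12, whose inverse is precomputed — and (2)
projection of penetrating interior nodes to the nearest surface point plus
the 1.5 mm clearance (tendon half-thickness surrogate), most-penetrating
obstacle first, up to eight passes to settle concave creases. The update
is under-relaxed (damping 0.65). Convergence is declared when the largest
node displacement falls below 3 µm, when successive displacements cancel
(a sub-millimetre period-2 flicker between two projection branches), or
when a 300-iteration window shows less than 1.5 mm net movement (a bounded
rattle); a genuine slide toward another minimum keeps progressing and is
never accepted early. The production inner loop is a numba kernel; a
pure-numpy reference path produces bitwise-identical results and serves
the iteration-trace diagnostics.

Frame 0 (static neutral) relaxes from two analytic seeds — the
tangent/great-arc/tangent sphere wrap over the anterior and anterolateral
head — and keeps the shorter converged result: a quasi-static tendon
settles into the global groove before motion begins. Later frames
warm-start from the previous solution, with nodes in femoral contact
carried rigidly by the incremental femur rotation; this hysteresis is what
lets the tendon stay hooked (a stable local minimum) during the return and
then release suddenly. A cold-start mode re-seeds every frame and serves
as the bistability diagnostic. Non-converged frames are flagged and the
case is excluded from cohort statistics with a logged reason.

The tracked point for the velocity series is the soft-min-weighted
(0.5 mm scale) tendon point nearest the head center: many nodes are
equidistant when the tendon wraps the head, and a raw nearest-node would
hop along the contact arc, injecting spurious angular jumps. Angular
position is accumulated between successive (tracked − center) directions
in the fixed pelvis frame; velocity is Δθ/Δt with Δt from the motion's
geodesic timing; the per-case outcome is the series maximum. Attachment
endpoints are exempt from the clearance constraint (they are on bone,
under soft tissue), as is containment of the insertion in the
capsule-sleeve surrogate.

## Statistics

Per-mode correlations are Pearson r (two-sided t p-values) on Mahalanobis
scores. The composite association is the first canonical correlation
between the score block and the univariate velocity, computed in closed
form as the multiple correlation of least squares via an orthonormal basis
of the centred predictor block (rank-reduced if degenerate); p-values come
from seeded permutations of the velocity (default 10,000 in the library,
fewer at desk scale), because asymptotic p-values at population scale are
vanishingly small and uninformative; an asymptotic F option exists.
Consensus shapes use one-component PLSR of mode scores on standardized
velocity, evaluated at ∓3 SD and reconstructed through the model; with one
component this direction equals the score–velocity covariance direction.
Sexes are compared with Welch's t on peak velocity, with mean/median/range
summaries. No multiple-testing correction is applied beyond reporting.

## What the generator does and does not emulate

It emulates: the population marginals of the five discrete measures;
landmark correspondence; a medially crowded proximal femur as the common
risk pattern; the qualitative snap sequence (medial rest, lateral
excursion over the anterior head, hooked return, late fast release); the
sign structure of the measure–velocity correlations; the female excess in
peak velocity via absolutely narrower ischiofemoral spacing.

It does not emulate: real cortical surface detail or inter-individual
variation beyond five degrees of freedom (so the PCA spectrum is ~5 modes
deep rather than the tens of modes of dense real data); correlated
measure distributions (defaults are independent marginals); absolute peak
velocity magnitudes, which depend on the unavailable training anatomy —
desk-scale cohort means here are roughly twice the published ones, and
individual release sizes are grid-sensitive, so only directional and
rank-order statements transfer. Passing tests therefore validate the
pipeline's mechanics and statistics on a controlled population, not
clinical effect sizes.

## Numerical and design choices

- Anteversion sign: positive = neck anterior to the posterior condylar
  axis; transverse plane taken perpendicular to the fitted shaft axis.
- IFD is measured on component surfaces via a KD-tree-candidate
  point-to-triangle query (the mesh proximity module of trimesh requires
  an unavailable spatial index, so the query is implemented directly);
  rigid transforms carry the tessellation along, keeping the measure
  exactly invariant.
- Degenerate inputs raise typed errors: non-PSD correlation matrices,
  coplanar sphere fits, odd step counts, non-orthonormal rotations,
  geometrically infeasible parameter combinations (e.g. offset unreachable
  at a near-180° neck-shaft angle).
- Desk-scale defaults: 60 training shapes and 80–200 cases per sex over
  60-frame sequences run in minutes on one core; the population-scale preset
  (20,000 cases per sex, 120 frames) is available but expected to run for
  hours.
- Reproducibility: every stage derives its generator from the master seed
  and a stable stage tag; identical configurations produce byte-identical
  outputs.

## Known limitations

- The +3 SD male risk shape releases marginally harder on the way out
  than on the return (≈3%), an asymmetry of the surrogate geometry; the
  female risk shape shows the expected return-dominant peak.
- The solver finds local minima by design; which minimum the cold start
  selects can differ from the warm-started branch, which is the point of
  the bistability diagnostic but means cold-start peak velocities are not
  comparable across cases.
- The acetabular cup exists as an obstacle dome plus rim arc; its mesh
  shell is for export/visualisation only.
- Pelvic constants (ridge, notch, dome) are population-fixed; only their
  head-radius-linked dimensions scale between cases.
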