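# hipsnap

Virtual-population mechanics of psoas tendon snapping (internal snapping
hip, *coxa saltans*). The package generates synthetic pelvis–femur
anatomies whose discrete measures follow published sex-specific population
statistics, builds PCA statistical shape models from them, simulates the
iliopsoas tendon wrapping over the bony surfaces during a provocative hip
circumduction, and relates the peak angular velocity of tendon movement to
anatomical shape with per-mode correlations, canonical correlation analysis
and partial-least-squares consensus shapes.

It is written for musculoskeletal-biomechanics researchers who want a
fully synthetic, reproducible test bed for shape–function analyses of
tendon snapping: every anatomical effect in the cohort is generated by an
explicit geometric mechanism, so statistical pipelines can be validated
against known ground truth.

## The model

**Shape.** Corresponding landmark configurations are modeled with a
point-distribution model, `S = S̄ + Pᵀb`, where `S̄` is the mean
configuration (3n vector), the rows of `P` are orthonormal modes of
variation with variances λ₁ ≥ … ≥ λ_t, and virtual cases are drawn with
independent weights `b_i ~ N(0, λ_i)`. Mahalanobis scores `b_i/√λ_i` put
the modes on a common dimensionless scale for statistics.

**Motion.** The hip is a spherical joint; the provocative circumduction
ramps abduction/flexion/external rotation simultaneously from neutral to
(90°, 60°, 30°) and back over 120 frames at a constant 25 deg/s geodesic
speed, with an exact clinical-angle decomposition
`R = R_abd(x)·R_flex(y)·R_rot(z)`.

**Tendon.** The psoas tendon is an inextensible ideal line: a 40-node chain
pinned at its pelvic-brim origin and lesser-trochanter insertion, relaxed
to a *local* minimum of length subject to a 1.5 mm clearance from every
bone surface (sphere-swept solids with exact signed distances). Frames are
warm-started from the previous solution, so the tendon can remain hooked in
a concave groove — a stable local minimum — during the return phase and
then release suddenly: the snap. The angular velocity of the tendon point
nearest the femoral head center, measured in the pelvis frame, is the
outcome; its per-case maximum ("peak tendon velocity") is what the
statistics explain.

**Statistics.** Per-mode Pearson correlations on whitened scores; the
composite shape–velocity association as the first canonical correlation
(with a univariate response this equals the multiple correlation R of least
squares, and p-values come from seeded permutations); one-component PLSR
consensus shapes at ±3 SD of velocity; Welch's t between the sexes.

## Worked example

```python
import numpy as np
from hipsnap import (AnatomicalParameters, build_anatomy,
                     build_circumduction_sequence, simulate_trajectory)

# a high-risk right hip: anteverted, valgus-neutral, low offset (female stats)
params = AnatomicalParameters(
    neck_shaft_angle=126.5, anteversion=29.0, femoral_offset=20.2,
    ischiofemoral_distance=22.2, head_radius=22.4, sex="female",
)
anatomy = build_anatomy(params)
motion = build_circumduction_sequence()          # 120 frames, apex (90, 60, 30)
traj = simulate_trajectory(anatomy, motion)
print(f"peak tendon velocity {traj.peak_velocity:.1f} deg/s "
      f"at frame {traj.peak_frame} (apex at {motion.apex_index})")
```

prints

```
peak tendon velocity 419.5 deg/s at frame 118 (apex at 60)
```

— the tendon sweeps laterally over the anterior femoral head during the
up-phase, stays hooked while the joint returns, and releases medially near
the end of the motion at many times the 25 deg/s imposed joint speed.

The full study (`analysis/04_virtual_cohort_study.py`, ~3 min) simulates
200 cases per sex and prints the per-measure correlation table; on this
cohort the composite femoral-shape association reaches r = 0.72 (male) and
0.55 (female), exceeding every single discrete measure, with positive
correlations for neck-shaft angle and anteversion and negative ones for
offset, ischiofemoral distance and head radius, and a higher female mean
peak velocity (211 vs 167 deg/s, Welch p ≈ 8e-10).

## Layout

- `src/hipsnap/` — the library: `anatomy` (synthetic population and
  parametric geometry), `shape_model` (PCA), `morphometrics` (the five
  discrete measures), `kinematics` (circumduction), `wrapping`
  (discrete-element tendon path), `stats` (shape–function statistics),
  `pipeline` + `cli` (orchestration; `hipsnap run-all --help`).
- `analysis/` — numbered narrative drivers that reproduce the study stages
  and write their tables under `results/`.
- `docs/methods.md` — model assumptions, parameters, numerical choices and
  limitations.

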