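"""Discrete-element psoas tendon wrapping.

The tendon is an inextensible ideal line: a chain of M nodes pinned at the
psoas origin (pelvis) and insertion (lesser trochanter), relaxed to a LOCAL
minimum of path length subject to staying at least ``clearance`` outside
every bone surface. Each relaxation iteration alternates

1. an implicit curve-shortening (smoothing) step with pinned endpoints
   (which also drives the nodes toward uniform spacing), and
2. projection of penetrating nodes to the nearest surface point plus
   clearance along the outward normal.

Globality is deliberately NOT guaranteed: snapping is a hysteresis
phenomenon, and the solver's frame-to-frame warm start is what lets the
tendon stay hooked in the concave head-neck valley (a stable local minimum)
during the return phase before jumping medially - the snap. The tendon's
angular position about the femoral head center is tracked through the
motion and differentiated into an angular-velocity series; its maximum is
the per-case peak tendon velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomyInstance
from .geometry import (
    ObstacleSet,
    polyline_length,
    resample_polyline,
    sphere_wrap_points,
)
from .kinematics import JointPose, MotionSequence

logger = logging.getLogger(__name__)

try:  # compiled inner loop; the pure-numpy path below is the reference
    from ._kernels import relax_kernel

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

ANTERIOR = np.array([1.0, 0.0, 0.0])
# second seed side for the neutral frame: slightly lateral on the anterior
# face; the static rest position is taken as the shorter of the two relaxed
# candidates (a quasi-static tendon settles into the global groove before
# the motion begins; hysteresis applies only during motion)
ANTEROLATERAL = np.array([0.866, -0.5, 0.0])

# nodes within this extra distance of a femoral surface are treated as in
# contact and carried rigidly with the femur between frames
_CARRY_BAND = 0.75

# obstacles the tendon is allowed to touch by default: the full femur plus
# the anterior pelvic ridge and the ischium
DEFAULT_OBSTACLES = (
    "head",
    "neck",
    "neck_base",
    "shaft_proximal",
    "shaft_distal",
    "lesser_trochanter",
    "calcar",
    "groove_lip",
    "greater_trochanter",
    "iliopectineal_ridge",
    "ischium",
    "acetabular_rim",
    "acetabular_dome",
    "medial_capsule",
)


class GeometryError(ValueError):
    pass


@dataclass
class WrapConfig:
    n_nodes: int = 40
    clearance: float = 1.5  # mm; tendon half-thickness surrogate
    step_tol: float = 3e-3  # mm; convergence on max node displacement
    max_iterations: int = 6000
    smoothing: float = 12.0  # implicit curve-shortening weight
    damping: float = 0.65  # under-relaxation of the smooth+project update
    obstacles: tuple[str, ...] = DEFAULT_OBSTACLES

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.clearance < 0 or self.step_tol <= 0:
            raise ValueError("clearance must be >= 0 and step_tol > 0")


@dataclass
class TendonPath:
    nodes: np.ndarray  # (M, 3)
    length: float
    converged: bool
    iterations: int


@dataclass
class TendonTrajectory:
    paths: list[TendonPath]
    tracked_points: np.ndarray  # (F, 3)
    theta: np.ndarray  # cumulative angular position, deg
    velocity: np.ndarray  # deg/s
    peak_velocity: float
    peak_frame: int
    frame_converged: np.ndarray  # bool per frame
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.frame_converged.all())

    def to_csv(self, path, times=None) -> None:
        with open(path, "w") as fh:
            fh.write("frame,time_s,theta_deg,v_deg_per_s,tracked_x,tracked_y,tracked_z\n")
            for k in range(len(self.paths)):
                t = 0.0 if times is None else float(times[k])
                p = self.tracked_points[k]
                fh.write(
                    f"{k},{t:.9f},{self.theta[k]:.6f},{self.velocity[k]:.6f},"
                    f"{p[0]:.4f},{p[1]:.4f},{p[2]:.4f}\n"
                )

    def export_path_ply(self, path, frame: int) -> None:
        """One frame's tendon polyline as an ASCII PLY (for visualisation)."""
        nodes = self.paths[frame].nodes
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(nodes)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element edge {len(nodes) - 1}\n"
                "property int vertex1\nproperty int vertex2\nend_header\n"
            )
            for p in nodes:
                fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
            for i in range(len(nodes) - 1):
                fh.write(f"{i} {i + 1}\n")


def _gather_obstacles(anatomy: AnatomyInstance, config: WrapConfig, femur_components=None) -> ObstacleSet:
    femur = femur_components if femur_components is not None else anatomy.femur_components
    pool = {**femur, **anatomy.pelvis_components}
    caps = [pool[name] for name in config.obstacles if name in pool]
    return ObstacleSet(caps)


def _smoothing_matrix(m: int, lam: float) -> np.ndarray:
    """Inverse of the pinned-end implicit-Laplacian operator (cached)."""
    A = np.eye(m)
    for i in range(1, m - 1):
        A[i, i - 1] -= lam
        A[i, i] += 2.0 * lam
        A[i, i + 1] -= lam
    return np.linalg.inv(A)


_SMOOTH_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _smoother(m: int, lam: float) -> np.ndarray:
    key = (m, round(lam, 9))
    if key not in _SMOOTH_CACHE:
        _SMOOTH_CACHE[key] = _smoothing_matrix(m, lam)
    return _SMOOTH_CACHE[key]


def seed_path(
    anatomy: AnatomyInstance,
    pose: JointPose | None = None,
    config: WrapConfig | None = None,
    femur_components=None,
    insertion=None,
    side=None,
) -> TendonPath:
    """Analytic seed: straight chord if clear, else a femoral-head sphere wrap.

    The wrap runs over the anterior side of the head - the anatomical side
    of the psoas - via the closed-form tangent/great-arc/tangent
    construction, resampled to the configured node count.
    """
    config = config or WrapConfig()
    if pose is not None and femur_components is None:
        from .kinematics import apply_pose

        _, femur_components, insertion = apply_pose(anatomy, pose)
    origin = anatomy.psoas_origin
    if insertion is None:
        insertion = anatomy.psoas_insertion
    obstacles = _gather_obstacles(anatomy, config, femur_components)

    # attachment points sit on bone under soft tissue: containment in the
    # capsule-sleeve surrogate is legitimate (the tendon dives under it to
    # reach bone), and sub-millimetre overlap with bone components is
    # construction slack; only gross bony containment is an error
    hard = ObstacleSet([c for c in obstacles.primitives if c.name != "neck_base"])
    for label, p in (("origin", origin), ("insertion", insertion)):
        if hard.min_signed_distance(p[None])[0] < -2.0:
            raise GeometryError(f"psoas {label} lies deep inside an obstacle")

    head = (femur_components or anatomy.femur_components)["head"]
    if _chord_is_clear(origin, insertion, obstacles, config.clearance):
        nodes = origin + np.linspace(0.0, 1.0, config.n_nodes)[:, None] * (insertion - origin)
    else:
        nodes = sphere_wrap_points(
            origin,
            insertion,
            head.a,
            head.radius + config.clearance,
            config.n_nodes,
            side=side if side is not None else ANTERIOR,
        )
    return TendonPath(
        nodes=nodes, length=polyline_length(nodes), converged=False, iterations=0
    )


def _chord_is_clear(a, b, obstacles: ObstacleSet, clearance: float, samples: int = 80) -> bool:
    """Is the straight chord at least ``clearance`` outside all obstacles?

    The ends are attachment points on bone, so a band near each endpoint is
    exempt from the clearance requirement.
    """
    t = np.linspace(0.0, 1.0, samples)[:, None]
    pts = a + t * (np.asarray(b) - a)
    exempt = max(3.0 * clearance, 5.0)
    chord = np.linalg.norm(np.asarray(b) - a)
    d_end = np.minimum(t[:, 0], 1.0 - t[:, 0]) * chord
    sd = obstacles.min_signed_distance(pts)
    return bool((sd[d_end > exempt] >= clearance - 1e-9).all())


def relax_path(
    path: TendonPath,
    obstacles: ObstacleSet,
    config: WrapConfig | None = None,
    max_iterations: int | None = None,
    record_lengths: bool = False,
):
    """Relax a node chain to a local shortest path outside the obstacles.

    Terminates when the largest node displacement in an iteration falls
    below ``step_tol`` or at ``max_iterations`` (converged flag False, a
    warning is logged). Endpoints stay pinned and, being attachments on the
    bone surface, are exempt from the clearance constraint.
    """
    config = config or WrapConfig()
    iters = max_iterations if max_iterations is not None else config.max_iterations
    W = _smoother(len(path.nodes), config.smoothing)
    nodes = np.ascontiguousarray(path.nodes, dtype=float)

    if _HAVE_NUMBA and not record_lengths:
        nodes, it, converged = relax_kernel(
            nodes,
            W,
            *obstacles.kernel_arrays(),
            config.clearance,
            config.step_tol,
            iters,
            config.damping,
        )
    else:
        lengths = [polyline_length(nodes)] if record_lengths else None
        converged = False
        it = 0
        for it in range(1, iters + 1):
            prev = nodes
            nodes = W @ nodes  # implicit curve-shortening, endpoints pinned
            interior = obstacles.project_out(nodes[1:-1], config.clearance, passes=8)
            nodes = np.vstack([nodes[:1], interior, nodes[-1:]])
            if config.damping < 1.0:
                nodes = config.damping * nodes + (1.0 - config.damping) * prev
            if record_lengths:
                lengths.append(polyline_length(nodes))
            if np.linalg.norm(nodes - prev, axis=1).max() < config.step_tol:
                converged = True
                break
    if not converged:
        logger.warning("tendon relaxation did not converge in %d iterations", iters)
    result = TendonPath(
        nodes=nodes, length=polyline_length(nodes), converged=converged, iterations=it
    )
    return (result, np.array(lengths)) if record_lengths else result


def check_clearance(path: TendonPath, obstacles: ObstacleSet, clearance: float, tol: float = 1e-3) -> bool:
    """Non-penetration invariant on the interior (non-attachment) nodes."""
    sd = obstacles.min_signed_distance(path.nodes[1:-1])
    return bool((sd >= clearance - tol).all())


def simulate_trajectory(
    anatomy: AnatomyInstance,
    motion: MotionSequence,
    config: WrapConfig | None = None,
    warm_start: bool = True,
) -> TendonTrajectory:
    """Wrap the tendon through a motion sequence and report angular velocity.

    Frame 0 is solved from the analytic seed; later frames are warm-started
    from the previous converged path, with nodes that were in contact with
    the femur carried rigidly by the incremental femur rotation (this
    contact-carrying is what allows the path to stay in the head-neck
    valley's local minimum and then snap out). ``warm_start=False`` re-seeds
    every frame analytically - the cold-start diagnostic mode.
    """
    from .kinematics import apply_pose

    config = config or WrapConfig()
    c = anatomy.head_center
    paths: list[TendonPath] = []
    warnings: list[str] = []
    prev_nodes = None
    prev_R = np.eye(3)
    prev_contact = None

    for k, pose in enumerate(motion.frames):
        _, femur_k, insertion_k = apply_pose(anatomy, pose)
        obstacles = _gather_obstacles(anatomy, config, femur_k)
        if k == 0 and warm_start:
            # static neutral rest: best of two analytic seed sides
            budget = config.max_iterations * 2
            candidates = []
            for side in (ANTERIOR, ANTEROLATERAL):
                seed = seed_path(
                    anatomy, config=config, femur_components=femur_k, insertion=insertion_k, side=side
                )
                cand = relax_path(seed, obstacles, config, max_iterations=budget)
                candidates.append(cand)
            candidates.sort(key=lambda c: (not c.converged, c.length))
            solved = candidates[0]
            if not solved.converged:
                warnings.append("frame 0: relaxation not converged")
            paths.append(solved)
            femur_obs = ObstacleSet([femur_k[n] for n in femur_k if n in config.obstacles])
            prev_contact = femur_obs.min_signed_distance(solved.nodes) < config.clearance + _CARRY_BAND
            prev_nodes = solved.nodes
            prev_R = pose.rotation
            continue
        if not warm_start or prev_nodes is None:
            seed = seed_path(anatomy, config=config, femur_components=femur_k, insertion=insertion_k)
            nodes = seed.nodes
            budget = config.max_iterations * (2 if k == 0 else 1)
        else:
            delta = pose.rotation @ prev_R.T
            nodes = prev_nodes.copy()
            if prev_contact is not None and prev_contact.any():
                nodes[prev_contact] = (nodes[prev_contact] - c) @ delta.T + c
            nodes[0] = anatomy.psoas_origin
            nodes[-1] = insertion_k
            budget = config.max_iterations
        solved = relax_path(
            TendonPath(nodes, polyline_length(nodes), False, 0),
            obstacles,
            config,
            max_iterations=budget,
        )
        if not solved.converged:
            warnings.append(f"frame {k}: relaxation not converged after {solved.iterations} iterations")
        paths.append(solved)
        # contact state against the femur only (the pelvis does not move)
        femur_obs = ObstacleSet([femur_k[n] for n in femur_k if n in config.obstacles])
        sd = femur_obs.min_signed_distance(solved.nodes)
        prev_contact = sd < config.clearance + _CARRY_BAND
        prev_nodes = solved.nodes
        prev_R = pose.rotation

    theta, velocity, tracked = angular_velocity_series(
        [p.nodes for p in paths], c, motion.times
    )
    peak_frame = int(np.argmax(velocity))
    return TendonTrajectory(
        paths=paths,
        tracked_points=tracked,
        theta=theta,
        velocity=velocity,
        peak_velocity=float(velocity[peak_frame]),
        peak_frame=peak_frame,
        frame_converged=np.array([p.converged for p in paths]),
        warnings=warnings,
    )


def angular_velocity_series(frames_nodes, head_center, times):
    """Angular position/velocity of the tendon about the femoral head center.

    The tracked point is, per frame, the tendon point closest to the head
    center, computed as a soft-min average over the chain: when the tendon
    wraps the head many nodes are equidistant from the center, and the raw
    nearest node would hop along the contact arc frame to frame, injecting
    spurious angular jumps. Weighting nodes by exp(-(d - d_min)/0.5 mm)
    tracks the centre of the closest-approach region instead, which moves
    with the tendon, not with the discretisation. The per-step angle is the
    angle between successive (tracked point - center) directions in the
    fixed pelvis frame. Returns (theta cumulative deg, velocity deg/s,
    tracked points).
    """
    c = np.asarray(head_center, float)
    times = np.asarray(times, float)
    if len(frames_nodes) < 2:
        raise ValueError("need at least two frames")
    tracked = np.empty((len(frames_nodes), 3))
    for k, nodes in enumerate(frames_nodes):
        d = np.linalg.norm(nodes - c, axis=1)
        w = np.exp(-(d - d.min()) / 0.5)
        tracked[k] = (nodes * w[:, None]).sum(axis=0) / w.sum()
    radii = np.linalg.norm(tracked - c, axis=1)
    if (radii < 1e-9).any():
        raise GeometryError("tracked tendon point coincides with the head center")
    dirs = (tracked - c) / radii[:, None]
    dots = np.clip(np.einsum("ij,ij->i", dirs[:-1], dirs[1:]), -1.0, 1.0)
    dtheta = np.degrees(np.arccos(dots))
    theta = np.concatenate([[0.0], np.cumsum(dtheta)])
    dt = np.diff(times)
    v = np.zeros(len(frames_nodes))
    with np.errstate(divide="ignore", invalid="ignore"):
        v[1:] = np.where(dt > 0, dtheta / dt, 0.0)
    return theta, v, tracked
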