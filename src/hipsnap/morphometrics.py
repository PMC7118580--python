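"""Discrete radiographic measures of the proximal femur.

Recomputes, from a labelled landmark set (or a full anatomy instance), the
five clinical measures the synthetic generator is parameterised by:
neck-shaft angle, femoral anteversion, femoral offset, ischiofemoral
distance and head radius. All measures are invariant to rigid motion of the
whole instance; lengths scale linearly and angles are invariant under
uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomicalParameters, AnatomyInstance, LandmarkSet


class FitError(ValueError):
    pass


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere: linearised algebraic fit + one geometric refinement.

    The algebraic stage solves ``|p|^2 = 2 c.p + k`` for center c and
    ``k = r^2 - |c|^2``; the geometric stage takes one Gauss-Newton step on
    the true residuals ``|p - c| - r``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise FitError("sphere fit needs >= 4 three-dimensional points")
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise FitError("degenerate (coplanar or coincident) points: sphere is not identifiable")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise FitError("algebraic sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))

    # one Gauss-Newton step on the geometric residuals
    d = points - center
    dist = np.linalg.norm(d, axis=1)
    if (dist < 1e-12).any():
        raise FitError("a point coincides with the fitted center")
    J = np.column_stack([-d / dist[:, None], -np.ones(len(points))])
    res = dist - radius
    step, *_ = np.linalg.lstsq(J, -res, rcond=None)
    center = center + step[:3]
    radius = float(radius + step[3])
    if radius <= 0:
        raise FitError("sphere fit produced non-positive radius")
    dist = np.linalg.norm(points - center, axis=1)
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean((dist - radius) ** 2))))


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line: (point on line, unit direction)."""
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[0]


def _point_line_distance(p, origin, direction) -> float:
    d = p - origin
    return float(np.linalg.norm(d - (d @ direction) * direction))


def compute_discrete_measures(
    anatomy: AnatomyInstance | LandmarkSet,
    sex: str | None = None,
) -> AnatomicalParameters:
    """Measure the five discrete parameters from landmarks (and meshes).

    For a full :class:`AnatomyInstance` the ischiofemoral distance is taken
    as a surface-to-surface proximity query between the ischium and
    lesser-trochanter component meshes; for a bare landmark set it is the
    closest labelled point pair (the template places landmarks at the facing
    points, so both routes agree).
    """
    if isinstance(anatomy, AnatomyInstance):
        lms = anatomy.landmarks
        sex = sex or anatomy.ground_truth.sex
    else:
        lms = anatomy

    required = [
        "head_surface",
        "neck_axis",
        "shaft_axis",
        "condylar_axis",
        "ischium",
        "lesser_trochanter",
    ]
    missing = [lab for lab in required if not any(l == lab for l in lms.labels)]
    if missing:
        raise MeasurementError(f"missing landmark labels: {missing}")

    head = fit_sphere(lms.subset("head_surface"))

    shaft_pt, shaft_dir = fit_line(lms.subset("shaft_axis"))
    neck_pt, neck_dir = fit_line(lms.subset("neck_axis"))
    cond_pt, cond_dir = fit_line(lms.subset("condylar_axis"))

    # orient: shaft superior = away from the condyles; neck toward the head
    cond_centroid = lms.subset("condylar_axis").mean(axis=0)
    if shaft_dir @ (cond_centroid - shaft_pt) > 0:
        shaft_dir = -shaft_dir
    if neck_dir @ (head.center - neck_pt) < 0:
        neck_dir = -neck_dir
    # condylar axis oriented medially: toward the head side of the shaft axis
    medial = head.center - shaft_pt
    medial = medial - (medial @ shaft_dir) * shaft_dir
    medial /= np.linalg.norm(medial)
    if cond_dir @ medial < 0:
        cond_dir = -cond_dir

    nsa = float(np.degrees(np.arccos(np.clip(neck_dir @ -shaft_dir, -1.0, 1.0))))

    # anteversion: signed angle between the transverse-plane projections of
    # the neck and condylar axes; positive = neck anterior to the condyles
    def proj(v):
        w = v - (v @ shaft_dir) * shaft_dir
        return w / np.linalg.norm(w)

    n_p, c_p = proj(neck_dir), proj(cond_dir)
    anteversion = float(np.degrees(np.arctan2(-shaft_dir @ np.cross(c_p, n_p), c_p @ n_p)))

    offset = _point_line_distance(head.center, shaft_pt, shaft_dir)

    if isinstance(anatomy, AnatomyInstance):
        ifd = _mesh_min_distance(
            anatomy.component_mesh("ischium"), anatomy.component_mesh("lesser_trochanter")
        )
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(lms.subset("ischium"))
        d, _ = tree.query(lms.subset("lesser_trochanter"))
        ifd = float(d.min())

    return AnatomicalParameters(
        neck_shaft_angle=nsa,
        anteversion=anteversion,
        femoral_offset=offset,
        ischiofemoral_distance=ifd,
        head_radius=head.radius,
        sex=sex,
    )


def _points_to_mesh_distance(points: np.ndarray, mesh, k: int = 32) -> np.ndarray:
    """Unsigned point-to-surface distances (candidate faces by centroid tree)."""
    from scipy.spatial import cKDTree
    from trimesh.triangles import closest_point as tri_closest

    tris = mesh.triangles  # (F, 3, 3)
    tree = cKDTree(tris.mean(axis=1))
    k = min(k, len(tris))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    flat_pts = np.repeat(points, k, axis=0)
    flat_tris = tris[idx.ravel()]
    nearest = tri_closest(flat_tris, flat_pts)
    d = np.linalg.norm(nearest - flat_pts, axis=1).reshape(len(points), k)
    return d.min(axis=1)


def _mesh_min_distance(mesh_a, mesh_b) -> float:
    """Minimum surface-to-surface distance between two meshes.

    Queries each mesh's vertices against the other's triangulated surface
    and takes the smaller minimum (symmetrised vertex-to-surface proximity).
    """
    d_ab = _points_to_mesh_distance(mesh_b.vertices, mesh_a).min()
    d_ba = _points_to_mesh_distance(mesh_a.vertices, mesh_b).min()
    return float(min(d_ab, d_ba))


def measures_table(instances, sexes=None):
    """Five measures for a list of anatomies/landmark sets, as an (n, 5) array."""
    rows = []
    for i, inst in enumerate(instances):
        sex = None if sexes is None else sexes[i]
        rows.append(compute_discrete_measures(inst, sex=sex).as_array())
    return np.stack(rows)
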