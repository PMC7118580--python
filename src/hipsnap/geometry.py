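"""Sphere-swept solid primitives and small geometric utilities.

Bone components are modeled as sphere-swept solids (spheres and capsules):
they carry an exact signed-distance function and an exact nearest-surface-point
projection, which the tendon relaxation solver queries tens of thousands of
times per case, and they can emit a watertight triangle mesh for export,
landmark sampling and mesh-based oracles.

Units are millimetres throughout; arrays are float64, shape (n, 3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh


@dataclass(frozen=True)
class Capsule:
    """Sphere-swept segment: all points within ``radius`` of segment a-b.

    With ``a == b`` this degenerates to a sphere, which is handled exactly.
    """

    name: str
    a: np.ndarray
    b: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.radius <= 0:
            raise ValueError(f"capsule {self.name!r}: radius must be > 0")

    @property
    def is_sphere(self) -> bool:
        return bool(np.allclose(self.a, self.b))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector a -> b (arbitrary fixed direction for spheres)."""
        d = self.b - self.a
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])

    def skeleton_closest(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the core segment for each query point."""
        points = np.atleast_2d(points)
        ba = self.b - self.a
        denom = float(ba @ ba)
        if denom == 0.0:
            return np.broadcast_to(self.a, points.shape).copy()
        h = np.clip((points - self.a) @ ba / denom, 0.0, 1.0)
        return self.a + h[:, None] * ba

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact signed distance to the surface (< 0 inside)."""
        points = np.atleast_2d(points)
        q = self.skeleton_closest(points)
        return np.linalg.norm(points - q, axis=1) - self.radius

    def surface_point_toward(self, points: np.ndarray, offset: float = 0.0) -> np.ndarray:
        """Nearest surface point (plus ``offset`` along the outward normal)."""
        points = np.atleast_2d(points)
        q = self.skeleton_closest(points)
        d = points - q
        n = np.linalg.norm(d, axis=1)
        # points exactly on the skeleton have no preferred normal; push along
        # a fixed perpendicular of the axis for determinism
        bad = n < 1e-12
        if bad.any():
            perp = _any_perpendicular(self.axis)
            d[bad] = perp
            n[bad] = 1.0
        return q + d * ((self.radius + offset) / n)[:, None]

    def transformed(self, rotation: np.ndarray, center: np.ndarray) -> "Capsule":
        """Rigidly rotate about ``center``."""
        center = np.asarray(center, dtype=float)
        return replace(
            self,
            a=center + rotation @ (self.a - center),
            b=center + rotation @ (self.b - center),
        )

    def mesh(self, sections: int = 24) -> trimesh.Trimesh:
        """Watertight triangle mesh of the solid."""
        if self.is_sphere:
            m = trimesh.creation.icosphere(subdivisions=2, radius=self.radius)
            m.apply_translation(self.a)
            return m
        height = float(np.linalg.norm(self.b - self.a))
        m = trimesh.creation.capsule(height=height, radius=self.radius, count=(sections, sections))
        # trimesh capsules are centred on the origin along +z
        T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], self.axis)
        m.apply_transform(T)
        m.apply_translation((self.a + self.b) / 2.0)
        return m

    def surface_grid(self, n: int) -> np.ndarray:
        """Deterministic parametric sampling of n surface points.

        Points are laid out on a (axial, azimuthal) grid in the capsule's own
        frame, so they move rigidly with the primitive: the same grid index is
        the same material location on every instance (correspondence by
        construction).
        """
        u = self.axis
        n1 = _any_perpendicular(u)
        n2 = np.cross(u, n1)
        if self.is_sphere:
            dirs = fibonacci_sphere(n)
            # express in the local frame for frame-consistency
            local = dirs @ np.stack([n1, n2, u])
            return self.a + self.radius * local
        nphi = max(4, int(round(np.sqrt(2.0 * n))))
        nt = int(np.ceil(n / nphi))
        ts = np.linspace(-0.08, 1.08, nt)  # slight overshoot covers the end caps
        phis = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
        tt, pp = np.meshgrid(ts, phis, indexing="ij")
        centers = self.a + np.clip(tt.ravel(), 0.0, 1.0)[:, None] * (self.b - self.a)
        # overshot rows tilt toward the poles of the end caps
        tilt = np.where(tt.ravel() < 0, -1.0, np.where(tt.ravel() > 1, 1.0, 0.0))
        rad = (
            np.cos(pp.ravel())[:, None] * n1
            + np.sin(pp.ravel())[:, None] * n2
            + (tilt * 0.8)[:, None] * u
        )
        rad /= np.linalg.norm(rad, axis=1)[:, None]
        pts = centers + self.radius * rad
        return pts[:n]


@dataclass(frozen=True)
class ArcTube:
    """Sphere-swept circular arc (an open torus segment).

    Skeleton: the arc of radius ``arc_radius`` about ``center`` in the plane
    spanned by ``e1``/``e2``, from angle 0 to ``span`` radians; the solid is
    all points within ``radius`` of it. Used for the acetabular rim, where a
    chain of capsules would leave concave junctions that make alternating
    projection chatter.
    """

    name: str
    center: np.ndarray
    e1: np.ndarray  # unit, angle origin
    e2: np.ndarray  # unit, perpendicular to e1 in the arc plane
    arc_radius: float
    span: float  # radians, in (0, 2*pi]
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "e1", np.asarray(self.e1, dtype=float))
        object.__setattr__(self, "e2", np.asarray(self.e2, dtype=float))
        if self.radius <= 0 or self.arc_radius <= 0:
            raise ValueError(f"arc {self.name!r}: radii must be > 0")

    def skeleton_closest(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        q = points - self.center
        x, y = q @ self.e1, q @ self.e2
        theta = np.arctan2(y, x) % (2.0 * np.pi)
        # clamp to the arc span; beyond it, snap to the nearer end
        over = theta > self.span
        theta = np.where(over & (theta - self.span > 2.0 * np.pi - theta), 0.0, np.minimum(theta, self.span))
        return self.center + self.arc_radius * (
            np.cos(theta)[:, None] * self.e1 + np.sin(theta)[:, None] * self.e2
        )

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        s = self.skeleton_closest(points)
        return np.linalg.norm(points - s, axis=1) - self.radius

    def surface_point_toward(self, points: np.ndarray, offset: float = 0.0) -> np.ndarray:
        points = np.atleast_2d(points)
        s = self.skeleton_closest(points)
        d = points - s
        n = np.linalg.norm(d, axis=1)
        bad = n < 1e-12
        if bad.any():
            normal = np.cross(self.e1, self.e2)
            d[bad] = normal
            n[bad] = 1.0
        return s + d * ((self.radius + offset) / n)[:, None]

    def transformed(self, rotation: np.ndarray, center: np.ndarray) -> "ArcTube":
        c = np.asarray(center, dtype=float)
        return replace(
            self,
            center=c + rotation @ (self.center - c),
            e1=rotation @ self.e1,
            e2=rotation @ self.e2,
        )

    def mesh(self, sections: int = 24) -> trimesh.Trimesh:
        """Approximate mesh: short capsules chained along the arc (export only)."""
        n_seg = max(6, int(np.ceil(self.span / 0.35)))
        thetas = np.linspace(0.0, self.span, n_seg + 1)
        pts = self.center + self.arc_radius * (
            np.cos(thetas)[:, None] * self.e1 + np.sin(thetas)[:, None] * self.e2
        )
        parts = [
            Capsule(f"{self.name}_{i}", pts[i], pts[i + 1], self.radius).mesh(max(sections // 2, 8))
            for i in range(n_seg)
        ]
        return trimesh.util.concatenate(parts)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


class ObstacleSet:
    """Sphere-swept primitives supporting vectorised distance/projection.

    Capsules/spheres are batched into one stacked query; other primitives
    (arc tubes) are queried individually and appended as extra columns.
    """

    def __init__(self, primitives: list):
        if not primitives:
            raise ValueError("obstacle set must contain at least one primitive")
        self.primitives = list(primitives)
        caps = [p for p in primitives if isinstance(p, Capsule)]
        self._others = [p for p in primitives if not isinstance(p, Capsule)]
        # column order: capsules first, then the rest
        self._ordered = caps + self._others
        self._a = np.stack([c.a for c in caps]) if caps else np.zeros((0, 3))
        self._ba = np.stack([c.b - c.a for c in caps]) if caps else np.zeros((0, 3))
        self._denom = np.einsum("ij,ij->i", self._ba, self._ba)
        self._r = np.array([c.radius for c in caps])

    @property
    def names(self) -> list[str]:
        return [p.name for p in self._ordered]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of each point to each obstacle, shape (N, K)."""
        points = np.atleast_2d(points)
        cols = []
        if len(self._a):
            pa = points[:, None, :] - self._a[None, :, :]  # (N, K, 3)
            with np.errstate(invalid="ignore", divide="ignore"):
                h = np.einsum("nkj,kj->nk", pa, self._ba) / self._denom
            h = np.nan_to_num(h, nan=0.0)
            np.clip(h, 0.0, 1.0, out=h)
            delta = pa - h[:, :, None] * self._ba[None, :, :]
            cols.append(np.linalg.norm(delta, axis=2) - self._r)
        for p in self._others:
            cols.append(p.signed_distance(points)[:, None])
        return np.hstack(cols)

    def min_signed_distance(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points).min(axis=1)

    def kernel_arrays(self):
        """Flat parameter arrays for the compiled relaxation kernel."""
        if not hasattr(self, "_kernel_arrays"):
            caps = [p for p in self._ordered if isinstance(p, Capsule)]
            arcs = self._others
            self._kernel_arrays = (
                np.ascontiguousarray(np.stack([c.a for c in caps]) if caps else np.zeros((0, 3))),
                np.ascontiguousarray(np.stack([c.b for c in caps]) if caps else np.zeros((0, 3))),
                np.array([c.radius for c in caps], dtype=float),
                np.ascontiguousarray(np.stack([a.center for a in arcs]) if arcs else np.zeros((0, 3))),
                np.ascontiguousarray(np.stack([a.e1 for a in arcs]) if arcs else np.zeros((0, 3))),
                np.ascontiguousarray(np.stack([a.e2 for a in arcs]) if arcs else np.zeros((0, 3))),
                np.array([a.arc_radius for a in arcs], dtype=float),
                np.array([a.span for a in arcs], dtype=float),
                np.array([a.radius for a in arcs], dtype=float),
            )
        return self._kernel_arrays

    def project_out(self, points: np.ndarray, clearance: float, passes: int = 4) -> np.ndarray:
        """Push points to at least ``clearance`` outside every obstacle.

        Each pass projects every violating point out of its currently most
        penetrating obstacle; repeated passes settle points in concave
        creases between obstacles.
        """
        pts = np.array(np.atleast_2d(points), dtype=float)
        for _ in range(passes):
            sd = self.signed_distance(pts)
            worst = np.argmin(sd, axis=1)
            viol = sd[np.arange(len(pts)), worst] < clearance - 1e-12
            if not viol.any():
                break
            for k in np.unique(worst[viol]):
                mask = viol & (worst == k)
                pts[mask] = self._ordered[k].surface_point_toward(pts[mask], offset=clearance)
        return pts


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit directions (deterministic golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def spherical_cup(
    inner_radius: float,
    outer_radius: float,
    cap_angle_deg: float,
    direction: np.ndarray,
    center: np.ndarray,
    n_lat: int = 6,
    n_lon: int = 24,
) -> trimesh.Trimesh:
    """Watertight hemispherical-shell mesh (an acetabulum surrogate).

    The shell spans polar angles [0, cap_angle] about ``direction``, with a
    concave inner surface at ``inner_radius`` and convex outer surface at
    ``outer_radius``, joined by an annular rim.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n1 = _any_perpendicular(direction)
    n2 = np.cross(direction, n1)
    cap = np.radians(cap_angle_deg)

    def ring(r, theta):
        lon = np.linspace(0.0, 2.0 * np.pi, n_lon, endpoint=False)
        return center + r * (
            np.cos(theta) * direction
            + np.sin(theta) * (np.cos(lon)[:, None] * n1 + np.sin(lon)[:, None] * n2)
        )

    verts = [center + outer_radius * direction, center + inner_radius * direction]
    thetas = np.linspace(0.0, cap, n_lat + 1)[1:]
    for r in (outer_radius, inner_radius):
        for th in thetas:
            verts.append(ring(r, th))
    verts = np.vstack([np.atleast_2d(v) for v in verts])

    def ring_index(surface, i):  # surface 0 = outer, 1 = inner
        return 2 + (surface * n_lat + i) * n_lon

    faces = []
    for surface, apex in ((0, 0), (1, 1)):
        base = ring_index(surface, 0)
        for j in range(n_lon):
            tri = [apex, base + j, base + (j + 1) % n_lon]
            faces.append(tri if surface == 0 else tri[::-1])
        for i in range(n_lat - 1):
            r0, r1 = ring_index(surface, i), ring_index(surface, i + 1)
            for j in range(n_lon):
                j1 = (j + 1) % n_lon
                quad = [(r0 + j, r1 + j, r1 + j1), (r0 + j, r1 + j1, r0 + j1)]
                for tri in quad:
                    faces.append(list(tri) if surface == 0 else list(tri)[::-1])
    # rim joining the outermost rings of the two surfaces
    r_out, r_in = ring_index(0, n_lat - 1), ring_index(1, n_lat - 1)
    for j in range(n_lon):
        j1 = (j + 1) % n_lon
        faces.append([r_out + j, r_in + j, r_in + j1])
        faces.append([r_out + j, r_in + j1, r_out + j1])

    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh


def sphere_wrap_length(a: np.ndarray, b: np.ndarray, center: np.ndarray, radius: float) -> float:
    """Closed-form shortest a->b path length around a sphere.

    The optimal path lies in the plane through a, b and the center: two
    tangent segments joined by a great-circle arc. Falls back to the straight
    distance when the segment clears the sphere.
    """
    a = np.asarray(a, float) - center
    b = np.asarray(b, float) - center
    da, db = np.linalg.norm(a), np.linalg.norm(b)
    if da <= radius or db <= radius:
        raise ValueError("endpoint inside the sphere")
    # does the straight chord clear the sphere?
    t = np.clip(np.dot(-a, b - a) / np.dot(b - a, b - a), 0.0, 1.0)
    if np.linalg.norm(a + t * (b - a)) >= radius:
        return float(np.linalg.norm(b - a))
    gamma = np.arccos(np.clip(np.dot(a, b) / (da * db), -1.0, 1.0))
    arc = gamma - np.arccos(radius / da) - np.arccos(radius / db)
    return float(np.sqrt(da**2 - radius**2) + np.sqrt(db**2 - radius**2) + radius * max(arc, 0.0))


def sphere_wrap_points(
    a: np.ndarray,
    b: np.ndarray,
    center: np.ndarray,
    radius: float,
    n: int,
    side: np.ndarray | None = None,
) -> np.ndarray:
    """Polyline realisation of the tangent-arc-tangent sphere wrap.

    ``side`` biases which way round the circle the arc runs (the wrap plane
    contains a, b and the center; the arc can bulge toward either in-plane
    side). Default picks the side of the in-plane normal pointing away from
    the chord, preferring the hemisphere of ``side`` when given.
    """
    center = np.asarray(center, float)
    A, B = np.asarray(a, float) - center, np.asarray(b, float) - center
    da, db = np.linalg.norm(A), np.linalg.norm(B)
    if da <= radius or db <= radius:
        raise ValueError("endpoint inside the sphere")
    t = np.clip(np.dot(-A, B - A) / np.dot(B - A, B - A), 0.0, 1.0)
    if np.linalg.norm(A + t * (B - A)) >= radius:
        return center + np.linspace(0.0, 1.0, n)[:, None] * (B - A) + A
    # orthonormal in-plane basis (e1 toward A)
    e1 = A / da
    w = B - np.dot(B, e1) * e1
    nw = np.linalg.norm(w)
    if nw < 1e-9:  # a, b, center colinear: plane chosen by the side hint
        hint = np.asarray(side, float) if side is not None else _any_perpendicular(e1)
        w = hint - np.dot(hint, e1) * e1
        nw = np.linalg.norm(w)
    e2 = w / nw
    if side is not None and np.dot(e2, np.asarray(side, float)) < 0:
        e2 = -e2
    ang_b = np.arctan2(np.dot(B, e2), np.dot(B, e1)) % (2 * np.pi)
    # tangent departure/arrival angles in the plane
    ta, tb = np.arccos(radius / da), np.arccos(radius / db)
    th0 = ta
    th1 = ang_b - tb
    if th1 < th0:
        th0, th1 = th0, th0  # degenerate: arc collapses
    arc_angles = np.linspace(th0, max(th1, th0), max(n - 2, 2))
    arc = radius * (np.cos(arc_angles)[:, None] * e1 + np.sin(arc_angles)[:, None] * e2)
    pts = np.vstack([A, arc, B]) + center
    return resample_polyline(pts, n)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n nodes uniformly spaced in arclength."""
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, points[:, k]) for k in range(3)])


def polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())
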