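"""Parameterised synthetic pelvis-femur anatomy.

A right-hip anatomy is constructed deterministically from five clinical
measures (neck-shaft angle, femoral anteversion, femoral offset,
ischiofemoral distance, head radius) so that morphometric re-measurement
recovers each input exactly (measurement closure). Population sampling draws
the measures from sex-specific truncated (multivariate) normals whose default
means and standard deviations are those of a western-European adult
population (males: NSA 125.23 +/- 5.48 deg, anteversion 9.86 +/- 7.02 deg,
offset 43.89 +/- 6.54 mm, IFD 29.05 +/- 4.18 mm, head radius
25.28 +/- 1.10 mm; females: 126.48 +/- 5.49, 10.72 +/- 6.09, 39.11 +/- 6.29,
22.23 +/- 4.34, 22.37 +/- 1.04).

Coordinate frame (right hip, right-handed): +x anterior, +y medial,
+z superior, origin at the femoral head center in the neutral pose. All
lengths in mm, angles in degrees.

Key geometric couplings (these make shape-snapping analysis possible):

* rising anteversion rotates the neck anteriorly and carries the lesser
  trochanter with it, moving its world position medially;
* falling femoral offset brings the shaft axis - and with it the lesser
  trochanter - medially;
* a falling ischiofemoral distance is realised as an extra medial
  protrusion of the lesser trochanter (the rotational-dysplasia pattern in
  which a medial minor trochanter and a narrow ischiofemoral gap are two
  faces of the same variant), with the ischium then placed so the
  neutral-pose minimum ischium-to-lesser-trochanter surface distance equals
  the sampled value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
import yaml

from .geometry import ArcTube, Capsule, fibonacci_sphere, spherical_cup

PARAMETER_FIELDS = (
    "neck_shaft_angle",
    "anteversion",
    "femoral_offset",
    "ischiofemoral_distance",
    "head_radius",
)

# validity intervals; sampling truncates to these by rejection
PARAMETER_BOUNDS = {
    "neck_shaft_angle": (90.0, 180.0),
    "anteversion": (-30.0, 45.0),
    "femoral_offset": (5.0, 90.0),
    "ischiofemoral_distance": (3.0, 60.0),
    "head_radius": (8.0, 45.0),
}

# population means/SDs of the five discrete measures, per sex
DEFAULT_POPULATION = {
    "male": {
        "neck_shaft_angle": (125.23, 5.48),
        "anteversion": (9.86, 7.02),
        "femoral_offset": (43.89, 6.54),
        "ischiofemoral_distance": (29.05, 4.18),
        "head_radius": (25.28, 1.10),
    },
    "female": {
        "neck_shaft_angle": (126.48, 5.49),
        "anteversion": (10.72, 6.09),
        "femoral_offset": (39.11, 6.29),
        "ischiofemoral_distance": (22.23, 4.34),
        "head_radius": (22.37, 1.04),
    },
}

LANDMARK_LABELS = (
    "head_surface",
    "neck_axis",
    "shaft_axis",
    "lesser_trochanter",
    "greater_trochanter",
    "acetabulum",
    "iliopectineal_ridge",
    "ischium",
    "psoas_origin",
    "psoas_insertion",
    "condylar_axis",
)

# relative landmark budget per region (scaled to the configured template size)
_LANDMARK_WEIGHTS = {
    "head_surface": 120,
    "neck_axis": 30,
    "shaft_axis": 40,
    "lesser_trochanter": 60,
    "greater_trochanter": 40,
    "acetabulum": 90,
    "iliopectineal_ridge": 60,
    "ischium": 120,
    "psoas_origin": 1,
    "psoas_insertion": 1,
    "condylar_axis": 38,
}

FEMUR_LABELS = frozenset(
    {
        "head_surface",
        "neck_axis",
        "shaft_axis",
        "lesser_trochanter",
        "greater_trochanter",
        "psoas_insertion",
        "condylar_axis",
    }
)


class ConfigurationError(ValueError):
    pass


class ConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class AnatomicalParameters:
    """The five discrete measures describing one hip, plus sex."""

    neck_shaft_angle: float
    anteversion: float
    femoral_offset: float
    ischiofemoral_distance: float
    head_radius: float
    sex: str | None = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def validate(self) -> None:
        for name in PARAMETER_FIELDS:
            lo, hi = PARAMETER_BOUNDS[name]
            v = getattr(self, name)
            if not np.isfinite(v) or not (lo < v < hi):
                raise ConstructionError(f"{name}={v} outside validity interval ({lo}, {hi})")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAMETER_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values, sex: str | None = None) -> "AnatomicalParameters":
        values = np.asarray(values, dtype=float)
        return cls(**dict(zip(PARAMETER_FIELDS, values)), sex=sex)

    def clipped(self, margin: float = 1e-6) -> "AnatomicalParameters":
        """Copy with each field clipped strictly inside its validity interval."""
        vals = {}
        for name in PARAMETER_FIELDS:
            lo, hi = PARAMETER_BOUNDS[name]
            vals[name] = float(np.clip(getattr(self, name), lo + margin, hi - margin))
        return replace(self, **vals)


@dataclass
class PopulationConfig:
    """Per-sex parameter distributions and template/mesh settings."""

    statistics: dict = field(default_factory=lambda: {s: dict(v) for s, v in DEFAULT_POPULATION.items()})
    correlation: np.ndarray | None = None  # 5x5, order = PARAMETER_FIELDS
    n_landmarks: int = 600
    mesh_sections: int = 24  # azimuthal resolution of component meshes

    def __post_init__(self):
        for sex, stats in self.statistics.items():
            for name, (_, sd) in stats.items():
                if sd < 0:
                    raise ConfigurationError(f"{sex}/{name}: SD must be >= 0")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (5, 5) or not np.allclose(C, C.T, atol=1e-10):
                raise ConfigurationError("correlation matrix must be symmetric 5x5")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ConfigurationError("correlation matrix must be positive semi-definite")
            self.correlation = C

    def mean_sd(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        stats = self.statistics[sex]
        mean = np.array([stats[f][0] for f in PARAMETER_FIELDS])
        sd = np.array([stats[f][1] for f in PARAMETER_FIELDS])
        return mean, sd

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "statistics": {s: {k: [float(m), float(sd)] for k, (m, sd) in v.items()} for s, v in self.statistics.items()},
            "correlation": None if self.correlation is None else np.asarray(self.correlation).tolist(),
            "n_landmarks": self.n_landmarks,
            "mesh_sections": self.mesh_sections,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        stats = {s: {k: tuple(v) for k, v in d.items()} for s, d in data["statistics"].items()}
        corr = data.get("correlation")
        return cls(
            statistics=stats,
            correlation=None if corr is None else np.asarray(corr, dtype=float),
            n_landmarks=int(data.get("n_landmarks", 600)),
            mesh_sections=int(data.get("mesh_sections", 24)),
        )


@dataclass
class LandmarkSet:
    """Ordered, labelled 3D landmark template (mm)."""

    points: np.ndarray  # (n, 3)
    labels: list[str]  # length n

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.labels) != len(self.points):
            raise ValueError("labels/points length mismatch")

    def subset(self, label: str) -> np.ndarray:
        mask = [l == label for l in self.labels]
        return self.points[np.asarray(mask)]

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("index,label,x,y,z\n")
            for i, (lab, p) in enumerate(zip(self.labels, self.points)):
                fh.write(f"{i},{lab},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        labels, pts = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                _, lab, x, y, z = line.strip().split(",")
                labels.append(lab)
                pts.append([float(x), float(y), float(z)])
        return cls(points=np.array(pts), labels=labels)


@dataclass
class AnatomyInstance:
    """One synthetic right hip: landmarks, solid components, ground truth."""

    landmarks: LandmarkSet
    femur_components: dict[str, Capsule]
    pelvis_components: dict[str, Capsule]
    ground_truth: AnatomicalParameters
    head_center: np.ndarray
    psoas_origin: np.ndarray
    psoas_insertion: np.ndarray
    mesh_sections: int = 24
    _femur_mesh: trimesh.Trimesh | None = None
    _pelvis_mesh: trimesh.Trimesh | None = None
    _mesh_cache: dict = field(default_factory=dict)

    @property
    def femur_mesh(self) -> trimesh.Trimesh:
        """Concatenation of per-component watertight femur meshes (lazy)."""
        if self._femur_mesh is None:
            self._femur_mesh = trimesh.util.concatenate(
                [c.mesh(self.mesh_sections) for c in self.femur_components.values()]
            )
        return self._femur_mesh

    @property
    def pelvis_mesh(self) -> trimesh.Trimesh:
        if self._pelvis_mesh is None:
            gt = self.ground_truth
            cup = spherical_cup(
                inner_radius=gt.head_radius + _CUP_CLEARANCE,
                outer_radius=gt.head_radius + _CUP_CLEARANCE + 5.0,
                cap_angle_deg=80.0,
                direction=_CUP_DIRECTION,
                center=self.head_center,
            )
            parts = [cup] + [c.mesh(self.mesh_sections) for c in self.pelvis_components.values()]
            self._pelvis_mesh = trimesh.util.concatenate(parts)
        return self._pelvis_mesh

    def component_mesh(self, name: str) -> trimesh.Trimesh:
        if name not in self._mesh_cache:
            comp = {**self.femur_components, **self.pelvis_components}[name]
            self._mesh_cache[name] = comp.mesh(self.mesh_sections)
        return self._mesh_cache[name]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnatomyInstance":
        """Rigidly transform the whole instance (used by invariance tests)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        move = lambda p: p @ R.T + t

        def move_caps(caps):
            out = {}
            for k, c in caps.items():
                if isinstance(c, Capsule):
                    out[k] = replace(c, a=R @ c.a + t, b=R @ c.b + t)
                else:  # arc tube
                    out[k] = replace(c, center=R @ c.center + t, e1=R @ c.e1, e2=R @ c.e2)
            return out

        out = AnatomyInstance(
            landmarks=LandmarkSet(move(self.landmarks.points), list(self.landmarks.labels)),
            femur_components=move_caps(self.femur_components),
            pelvis_components=move_caps(self.pelvis_components),
            ground_truth=self.ground_truth,
            head_center=R @ self.head_center + t,
            psoas_origin=R @ self.psoas_origin + t,
            psoas_insertion=R @ self.psoas_insertion + t,
            mesh_sections=self.mesh_sections,
        )
        # carry rigidly moved copies of the component meshes: a moved bone
        # keeps its tessellation (and so its measured surface distances)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        for name in {**self.femur_components, **self.pelvis_components}:
            out._mesh_cache[name] = self.component_mesh(name).copy().apply_transform(T)
        return out

    def export(self, directory, stem: str = "anatomy") -> None:
        """Write meshes (PLY binary + OBJ) and landmarks (CSV + JSON)."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for bone, mesh in (("femur", self.femur_mesh), ("pelvis", self.pelvis_mesh)):
            mesh.export(directory / f"{stem}_{bone}.ply", encoding="binary")
            mesh.export(directory / f"{stem}_{bone}.obj")
        self.landmarks.to_csv(directory / f"{stem}_landmarks.csv")
        with open(directory / f"{stem}_landmarks.json", "w") as fh:
            json.dump(
                {
                    "labels": list(self.landmarks.labels),
                    "points_mm": self.landmarks.points.tolist(),
                },
                fh,
            )


# fixed anatomical design constants (not Table-style measures; they only shape
# the wrapping surfaces)
_SHAFT_RADIUS = 14.0
_SHAFT_LENGTH = 170.0
_NECK_RADIUS_FRACTION = 0.52  # thin bony neck (landmark/visual); sleeve is wider
_LT_RADIUS = 8.0
_LT_DEPTH = 34.0  # lesser trochanter depth below the head center
_LT_BASE_ANGLE = 45.0  # posterior offset of the LT from the neck direction
_LT_REACH = 16.0  # baseline LT tip distance from the vertical head axis
_IFD_COUPLING = 0.6  # mm of extra medial LT reach per mm of IFD deficit
_IFD_CROWDING_ONSET = 29.0  # gap (mm) below which ischiofemoral crowding begins
_IFD_SOFTNESS = 4.0  # softness (mm) of the crowding onset
_NSA_COUPLING = 0.65  # mm of extra medial LT reach per degree of valgus
_OFFSET_COUPLING = 0.7  # mm of extra medial LT reach per mm of offset deficit
_AV_COUPLING = 0.8  # mm of extra medial LT reach per degree of anteversion
_HEAD_COUPLING = 2.5  # relative calcar prominence per mm of head-radius deficit
_EXTRA_CEILING = 10.0  # asymptotic cap on the dysplastic medial prominence
_CALCAR_BASE = 8.0  # calcar center distance from the head axis at mean anatomy
_CALCAR_RADIUS = 7.0
_CALCAR_AZ_DEG = 40.0  # calcar azimuth (from medial toward anterior), fixed
_LIP_AZ_DEG = 88.0  # lateral groove-lip azimuth
_LIP_RADIUS = 5.0
_LIP_COUPLING = 0.7  # lip protrusion per mm of dysplastic medial prominence
_GT_RADIUS = 11.0
_ISCHIUM_RADIUS = 12.0
_ISCHIUM_HALF_LENGTH = 14.0
_RIDGE_RADIUS = 7.0
_CUP_CLEARANCE = 2.0
_CUP_DIRECTION = np.array([-0.35, 0.25, 0.9])
_RIM_NOTCH_HALF_ANGLE = 65.0  # anterior rim deficiency (iliopsoas groove), deg
_RIM_NOTCH_CENTER_DEG = 25.0  # notch center, rotated from anterior toward medial
_RIM_STANDOFF = 6.0  # rim skeleton distance beyond the head surface
_RIM_RADIUS = 4.0  # head-rim gap = standoff - radius = 2 mm < tendon diameter
_ORIGIN_X = 16.0  # psoas brim-crossing point (anterior, slightly medial)
_ORIGIN_Y = 20.0
_BOW_AMPLITUDE = 4.0  # anterior bow of the distal shaft


def sample_parameters(
    sex: str,
    n: int,
    seed=None,
    config: PopulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[AnatomicalParameters]:
    """Draw n i.i.d. parameter vectors from the configured population.

    Draws come from the per-sex (multivariate) normal, truncated to each
    field's validity interval by rejection; reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PopulationConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    mean, sd = config.mean_sd(sex)
    if config.correlation is None:
        L = np.eye(5)
    else:
        # PSD square root via eigendecomposition (tolerates semi-definite input)
        w, V = np.linalg.eigh(config.correlation)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    lo = np.array([PARAMETER_BOUNDS[f][0] for f in PARAMETER_FIELDS])
    hi = np.array([PARAMETER_BOUNDS[f][1] for f in PARAMETER_FIELDS])

    out = np.empty((n, 5))
    filled = 0
    while filled < n:
        z = rng.standard_normal((n - filled, 5))
        x = mean + (z @ L.T) * sd
        ok = ((x > lo) & (x < hi)).all(axis=1)
        kept = x[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return [AnatomicalParameters.from_array(row, sex=sex) for row in out]


def sample_parameter_table(sex, n, seed=None, config=None, rng=None):
    """Same draws as :func:`sample_parameters`, as an (n, 5) array."""
    params = sample_parameters(sex, n, seed=seed, config=config, rng=rng)
    return np.stack([p.as_array() for p in params])


def _allocate_counts(n_total: int) -> dict[str, int]:
    base = sum(_LANDMARK_WEIGHTS.values())
    counts = {}
    for label in LANDMARK_LABELS:
        w = _LANDMARK_WEIGHTS[label]
        counts[label] = 1 if w == 1 else max(2, int(round(w * n_total / base)))
    # make the total exact by adjusting the largest multi-point region
    diff = n_total - sum(counts.values())
    counts["ischium"] += diff
    if counts["ischium"] < 2:
        raise ConfigurationError(f"landmark template too small: n={n_total}")
    return counts


def build_anatomy(params: AnatomicalParameters, config: PopulationConfig | None = None) -> AnatomyInstance:
    """Deterministic parametric construction of one right-hip anatomy."""
    config = config or PopulationConfig()
    params.validate()

    nsa = params.neck_shaft_angle
    av = np.radians(params.anteversion)
    offset = params.femoral_offset
    ifd = params.ischiofemoral_distance
    head_r = params.head_radius

    chi = np.radians(180.0 - nsa)  # neck inclination from the superior axis
    sin_chi = np.sin(chi)
    neck_len = offset / sin_chi
    if neck_len > 130.0:
        raise ConstructionError(
            "femoral_offset unreachable at this neck_shaft_angle: "
            f"required neck length {neck_len:.1f} mm (offset={offset}, neck_shaft_angle={nsa})"
        )
    head_c = np.zeros(3)
    # neck direction: from neck base toward the head center
    d_neck = np.array([sin_chi * np.sin(av), sin_chi * np.cos(av), np.cos(chi)])
    neck_base = head_c - neck_len * d_neck
    neck_r = _NECK_RADIUS_FRACTION * head_r

    shaft_top = neck_base.copy()
    shaft_mid = shaft_top + np.array([0.0, 0.0, -0.55 * _SHAFT_LENGTH])
    shaft_bot = shaft_top + np.array([_BOW_AMPLITUDE, 0.0, -_SHAFT_LENGTH])

    # lesser trochanter: posteromedial prominence at a fixed depth below the
    # head center. Its transverse direction turns with the neck (anteversion
    # coupling) and its medial reach - measured from the vertical axis
    # through the head center - grows as the ischiofemoral distance shrinks
    # (the rotational-dysplasia pattern: a medial minor trochanter and a
    # narrow ischiofemoral gap are two faces of one variant).
    # the rotational-dysplasia coupling: a valgus neck, anteversion, a small
    # offset, a narrow ischiofemoral gap and a small head all present as a
    # medially located minor trochanter / prominent calcar. The angular and
    # size terms are deviations from the sex's population mean; the
    # ischiofemoral term is an ABSOLUTE hinge - crowding is a property of
    # the gap itself, not of the sex distribution, which is why the sex
    # with the narrower ischiofemoral space is systematically more exposed.
    sex_for_ref = params.sex or "male"
    ref = config.statistics[sex_for_ref]
    crowding = _IFD_SOFTNESS * np.logaddexp(0.0, (_IFD_CROWDING_ONSET - ifd) / _IFD_SOFTNESS)
    raw_extra = (
        _IFD_COUPLING * crowding
        + _NSA_COUPLING * (nsa - ref["neck_shaft_angle"][0])
        + _OFFSET_COUPLING * (ref["femoral_offset"][0] - offset)
        + _AV_COUPLING * (params.anteversion - ref["anteversion"][0])
        + _HEAD_COUPLING * (ref["head_radius"][0] - head_r)
    )
    # smooth saturation: prominence approaches the ceiling asymptotically,
    # so extreme variants stay in the snapping regime without a dead zone
    if raw_extra > 0.0:
        medial_extra = float(_EXTRA_CEILING * np.tanh(raw_extra / _EXTRA_CEILING))
    else:
        medial_extra = float(max(raw_extra, -9.0))
    theta_lt = av - np.radians(_LT_BASE_ANGLE)  # angle from +y toward +x
    dir_lt = np.array([np.sin(theta_lt), np.cos(theta_lt), 0.0])
    z_lt = -_LT_DEPTH
    lt_axis_pt = np.array([shaft_top[0], shaft_top[1], z_lt])  # on the shaft axis
    lt_tip = (_LT_REACH + medial_extra) * dir_lt + np.array([0.0, 0.0, z_lt])
    if np.linalg.norm(lt_tip[:2] - lt_axis_pt[:2]) > 110.0:
        raise ConstructionError(
            "lesser trochanter unreachable: femoral_offset and "
            "ischiofemoral_distance place its tip too far from the shaft"
        )

    # calcar prominence: the superior extension of the trochanteric mass at
    # the inferomedial head-neck junction. At mean anatomy it is flush with
    # the local surface; in the rotational-dysplasia variant it protrudes
    # into the tendon's station at head level - the feature that hooks the
    # returning tendon and sets snap severity
    z_cal = -0.8 * head_r
    rho_cal = _CALCAR_BASE + 0.8 * medial_extra
    dir_cal = np.array([np.sin(np.radians(_CALCAR_AZ_DEG)), np.cos(np.radians(_CALCAR_AZ_DEG)), 0.0])
    calcar_c = rho_cal * dir_cal + np.array([0.0, 0.0, z_cal])

    # lateral lip of the femoral psoas groove: a fixed small prominence on
    # the anterolateral head margin. It bounds the tendon's lateral station
    # laterally, so the returning tendon is retained between calcar and lip
    # and released medially late - the final-stage snap
    u_lip = np.array([np.sin(np.radians(_LIP_AZ_DEG)), np.cos(np.radians(_LIP_AZ_DEG)), -0.25])
    u_lip /= np.linalg.norm(u_lip)
    # lip prominence shares the dysplasia coupling: flush at mean anatomy,
    # a cam-like overgrowth of the lateral junction in the at-risk variant
    lip_c = (head_r - _LIP_RADIUS + 2.0 + _LIP_COUPLING * max(0.0, medial_extra)) * u_lip

    # greater trochanter: lateral prominence at the neck-base level
    theta_gt = av + np.radians(172.0)
    dir_gt = np.array([np.sin(theta_gt), np.cos(theta_gt), 0.0])
    gt_base = shaft_top + np.array([0.0, 0.0, 2.0])
    gt_tip = gt_base + (_SHAFT_RADIUS + 8.0) * dir_gt

    femur = {
        "head": Capsule("head", head_c, head_c, head_r),
        # capsule sleeve surrogate: a thick upper neck (the concave
        # head-neck valley is the crease against the head sphere) over a
        # fatter base merging into the trochanteric mass; the sleeve also
        # forbids non-anatomical shortcuts under or behind the neck
        "neck": Capsule(
            "neck", neck_base + 0.45 * (head_c - neck_base), head_c + 0.1 * neck_len * d_neck, 0.60 * head_r
        ),
        "neck_base": Capsule(
            "neck_base", neck_base, neck_base + 0.5 * (head_c - neck_base), min(head_r, _SHAFT_RADIUS + 9.0)
        ),
        "shaft_proximal": Capsule("shaft_proximal", shaft_top, shaft_mid, _SHAFT_RADIUS),
        "shaft_distal": Capsule("shaft_distal", shaft_mid, shaft_bot, _SHAFT_RADIUS - 1.0),
        "lesser_trochanter": Capsule("lesser_trochanter", lt_axis_pt, lt_tip, _LT_RADIUS),
        "calcar": Capsule("calcar", calcar_c, calcar_c, _CALCAR_RADIUS),
        "groove_lip": Capsule("groove_lip", lip_c, lip_c, _LIP_RADIUS),
        "greater_trochanter": Capsule("greater_trochanter", gt_base, gt_tip, _GT_RADIUS),
    }
    del neck_r

    # pelvis: iliopectineal ridge/eminence (medial wall of the psoas groove
    # at the brim), acetabular dome and inferomedial capsule (they seal the
    # over-the-top and posteromedial corridors the real acetabulum, fossa
    # and capsule occupy), rim arc with anterior notch, and ischium
    ridge_a = np.array([_ORIGIN_X - 6.0, _ORIGIN_Y + 12.0, head_r + 6.0])
    ridge_b = np.array([_ORIGIN_X - 2.0, _ORIGIN_Y + 26.0, head_r + 30.0])
    ridge = Capsule("iliopectineal_ridge", ridge_a, ridge_b, _RIDGE_RADIUS)

    # ischium placed so the min surface distance to the LT equals the IFD
    isch_gap = ifd + _LT_RADIUS + _ISCHIUM_RADIUS
    isch_c = lt_tip + isch_gap * dir_lt
    ischium = Capsule(
        "ischium",
        isch_c + np.array([0.0, 0.0, -_ISCHIUM_HALF_LENGTH]),
        isch_c + np.array([0.0, 0.0, _ISCHIUM_HALF_LENGTH]),
        _ISCHIUM_RADIUS,
    )
    pole = _CUP_DIRECTION / np.linalg.norm(_CUP_DIRECTION)
    dome = Capsule("acetabular_dome", 10.0 * pole, 10.0 * pole, head_r + 2.0)
    medial_capsule = Capsule(
        "medial_capsule",
        np.array([2.0, head_r * 0.9, -2.0]),
        np.array([-6.0, head_r * 1.15, -20.0]),
        7.0,
    )
    pelvis = {
        "iliopectineal_ridge": ridge,
        "ischium": ischium,
        "acetabular_dome": dome,
        "medial_capsule": medial_capsule,
    }

    # acetabular rim: a sphere-swept arc along the acetabular margin with an
    # anterior deficiency (the iliopsoas groove). The gap between rim tube
    # and head surface is smaller than the tendon diameter, so it confines
    # the tendon to the anterior aspect of the joint - without it a shortest
    # path could slip around the posteromedial head, which the real
    # acetabulum, capsule and pubis forbid.
    u_pole = _CUP_DIRECTION / np.linalg.norm(_CUP_DIRECTION)
    e1 = np.array([1.0, 0.0, 0.0]) - u_pole[0] * u_pole
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u_pole, e1)
    notch = np.radians(_RIM_NOTCH_HALF_ANGLE)
    center_rot = np.radians(_RIM_NOTCH_CENTER_DEG)
    e1 = np.cos(center_rot) * e1 + np.sin(center_rot) * e2
    e2 = np.cross(u_pole, e1)
    # arc runs from the medial notch edge the long way round to the lateral edge
    e1_start = np.cos(notch) * e1 + np.sin(notch) * e2
    e2_start = -np.sin(notch) * e1 + np.cos(notch) * e2
    pelvis["acetabular_rim"] = ArcTube(
        "acetabular_rim",
        center=head_c,
        e1=e1_start,
        e2=e2_start,
        arc_radius=head_r + _RIM_STANDOFF,
        span=2.0 * np.pi - 2.0 * notch,
        radius=_RIM_RADIUS,
    )

    # psoas endpoints: origin where the tendon crosses the brim anterior to
    # the head (the psoas groove), insertion on the inferior face of the LT
    # tip so the tendon drapes over the medial trochanteric bulge on its way
    # down - the bulge is the barrier whose medial reach sets snap severity
    psoas_origin = np.array([_ORIGIN_X, _ORIGIN_Y, 55.0])
    # the brim bone under the crossing point (superior ramus surface): the
    # origin lies exactly on it
    ramus_dir = np.array([0.0, 0.3, -1.0])
    ramus_dir /= np.linalg.norm(ramus_dir)
    pelvis["pubic_ramus"] = Capsule(
        "pubic_ramus", psoas_origin + 6.0 * ramus_dir, psoas_origin + 14.0 * ramus_dir, 6.0
    )
    # inferior LT surface at a fixed medial station: the tendon descending
    # from the brim must clear the LT's medial bulge before curling down to
    # its attachment (candidate point projected exactly onto the LT surface)
    ins_radial = min(10.0, _LT_REACH + medial_extra - 2.0)
    ins_candidate = ins_radial * dir_lt + np.array([0.0, 0.0, z_lt - _LT_RADIUS])
    psoas_insertion = femur["lesser_trochanter"].surface_point_toward(ins_candidate[None])[0]

    if ridge.signed_distance(psoas_insertion[None])[0] < 0:
        raise ConstructionError("psoas_insertion lies inside the iliopectineal ridge")

    landmarks = _build_landmarks(
        config,
        head_c,
        head_r,
        neck_base,
        d_neck,
        shaft_top,
        femur,
        pelvis,
        psoas_origin,
        psoas_insertion,
        dir_lt,
        shaft_bot,
    )

    return AnatomyInstance(
        landmarks=landmarks,
        femur_components=femur,
        pelvis_components=pelvis,
        ground_truth=params,
        head_center=head_c,
        psoas_origin=psoas_origin,
        psoas_insertion=psoas_insertion,
        mesh_sections=config.mesh_sections,
    )


def _build_landmarks(
    config,
    head_c,
    head_r,
    neck_base,
    d_neck,
    shaft_top,
    femur,
    pelvis,
    psoas_origin,
    psoas_insertion,
    dir_lt,
    shaft_bot,
) -> LandmarkSet:
    counts = _allocate_counts(config.n_landmarks)
    pts, labels = [], []

    def add(label, arr):
        arr = np.atleast_2d(arr)
        pts.append(arr)
        labels.extend([label] * len(arr))

    add("head_surface", head_c + head_r * fibonacci_sphere(counts["head_surface"]))
    t = np.linspace(0.05, 0.95, counts["neck_axis"])[:, None]
    add("neck_axis", neck_base + t * (head_c - neck_base))
    t = np.linspace(0.02, 0.85, counts["shaft_axis"])[:, None]
    shaft_axis_bot = shaft_top + np.array([0.0, 0.0, -_SHAFT_LENGTH])
    add("shaft_axis", shaft_top + t * (shaft_axis_bot - shaft_top))

    lt = femur["lesser_trochanter"]
    lt_pts = lt.surface_grid(counts["lesser_trochanter"])
    lt_facing = lt.b + lt.radius * dir_lt  # LT point facing the ischium
    lt_pts[0] = lt_facing
    add("lesser_trochanter", lt_pts)
    add("greater_trochanter", femur["greater_trochanter"].surface_grid(counts["greater_trochanter"]))

    # acetabulum: spherical cap congruent with the head (fixed clearance)
    dirs = fibonacci_sphere(max(counts["acetabulum"] * 4, 64))
    score = dirs @ (_CUP_DIRECTION / np.linalg.norm(_CUP_DIRECTION))
    order = np.argsort(-score, kind="stable")[: counts["acetabulum"]]
    add("acetabulum", head_c + (head_r + _CUP_CLEARANCE) * dirs[order])

    add("iliopectineal_ridge", pelvis["iliopectineal_ridge"].surface_grid(counts["iliopectineal_ridge"]))
    isch = pelvis["ischium"]
    isch_pts = isch.surface_grid(counts["ischium"])
    # facing point: ischium surface point nearest the LT (distance = IFD)
    isch_pts[0] = isch.surface_point_toward(lt_facing[None])[0]
    add("ischium", isch_pts)

    add("psoas_origin", psoas_origin)
    add("psoas_insertion", psoas_insertion)

    t = np.linspace(-1.0, 1.0, counts["condylar_axis"])[:, None]
    condylar_center = shaft_bot + np.array([0.0, 0.0, -8.0])
    add("condylar_axis", condylar_center + t * np.array([[0.0, 40.0, 0.0]]))

    return LandmarkSet(points=np.vstack(pts), labels=labels)
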