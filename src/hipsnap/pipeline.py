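"""End-to-end virtual-population study orchestration.

One configuration drives: training anatomy generation -> per-sex PCA shape
model fitting -> virtual cohort sampling from the model -> tendon-wrapping
simulation of the provocative circumduction per case -> shape-function
statistics -> report tables. Every stage draws its randomness from a child
seed spawned deterministically from the master seed, so a run is exactly
reproducible and per-case work could be distributed without changing
results.

Desk-scale defaults run in minutes on one core; ``StudyConfig.population_scale``
configures the full-size protocol (20,000 cases per sex, 120-step motion).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import (
    AnatomicalParameters,
    PopulationConfig,
    build_anatomy,
    sample_parameters,
)
from .kinematics import build_circumduction_sequence
from .morphometrics import compute_discrete_measures
from .shape_model import ShapeModel, fit_shape_model
from .stats import (
    compare_sexes,
    discrete_measure_correlations,
    make_cohort_table,
    per_pc_correlations,
    plsr_consensus_shapes,
)
from .wrapping import WrapConfig, simulate_trajectory

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_training: int = 60  # training anatomies per sex for the shape model
    n_cohort: int = 80  # virtual cases per sex simulated
    n_steps: int = 60
    peak_abduction: float = 90.0
    peak_flexion: float = 60.0
    peak_rotation: float = 30.0
    speed: float = 25.0
    wrap: WrapConfig = field(default_factory=WrapConfig)
    n_permutations: int = 2000
    mode_cap: int = 20
    min_modes: int = 5  # >= generator dof, so no anatomical dimension is truncated
    variance_threshold: float = 0.99
    sd_level: float = 3.0
    sexes: tuple[str, ...] = ("male", "female")
    seed: int = 0

    def __post_init__(self):
        if self.n_cohort < 1 or self.n_training < 3:
            raise ValueError("cohort size must be >= 1 and training count >= 3")

    @classmethod
    def population_scale(cls, seed: int = 0) -> "StudyConfig":
        """The full-size protocol: 20,000 cases/sex, 120-step motion."""
        return cls(
            n_training=300,
            n_cohort=20000,
            n_steps=120,
            n_permutations=10000,
            seed=seed,
        )

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_training",
                "n_cohort",
                "n_steps",
                "peak_abduction",
                "peak_flexion",
                "peak_rotation",
                "speed",
                "n_permutations",
                "mode_cap",
                "min_modes",
                "variance_threshold",
                "sd_level",
                "seed",
            )
        }
        d["sexes"] = list(self.sexes)
        d["wrap"] = {
            "n_nodes": self.wrap.n_nodes,
            "clearance": self.wrap.clearance,
            "step_tol": self.wrap.step_tol,
            "max_iterations": self.wrap.max_iterations,
            "smoothing": self.wrap.smoothing,
            "obstacles": list(self.wrap.obstacles),
        }
        d["population"] = {
            "statistics": {
                s: {k: [float(m), float(sd)] for k, (m, sd) in v.items()}
                for s, v in self.population.statistics.items()
            },
            "correlation": None
            if self.population.correlation is None
            else np.asarray(self.population.correlation).tolist(),
            "n_landmarks": self.population.n_landmarks,
            "mesh_sections": self.population.mesh_sections,
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = dict(d)
        pop = kwargs.pop("population", None)
        if pop is not None:
            kwargs["population"] = PopulationConfig(
                statistics={s: {k: tuple(v) for k, v in st.items()} for s, st in pop["statistics"].items()},
                correlation=None if pop.get("correlation") is None else np.asarray(pop["correlation"]),
                n_landmarks=int(pop.get("n_landmarks", 600)),
                mesh_sections=int(pop.get("mesh_sections", 24)),
            )
        wrap = kwargs.pop("wrap", None)
        if wrap is not None:
            wrap = dict(wrap)
            if "obstacles" in wrap:
                wrap["obstacles"] = tuple(wrap["obstacles"])
            kwargs["wrap"] = WrapConfig(**wrap)
        if "sexes" in kwargs:
            kwargs["sexes"] = tuple(kwargs["sexes"])
        return cls(**kwargs)


def _child_seed(master: int, *tags: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed.

    The stage tags map to a stable integer (interpreter hash() is salted per
    process, so it must not be used here).
    """
    digest = sum((i + 1) * sum(tag.encode()) for i, tag in enumerate(tags)) % (2**20)
    return np.random.default_rng(np.random.SeedSequence([int(master) % (2**31), digest]))


@dataclass
class StudyResult:
    cohorts: dict[str, pd.DataFrame]
    models: dict[str, ShapeModel]
    tables: dict[str, pd.DataFrame]
    sex_comparison: dict | None
    report: dict


def simulate_case(
    params: AnatomicalParameters,
    config: StudyConfig,
):
    """Build one anatomy and wrap the tendon through the study motion."""
    anatomy = build_anatomy(params, config.population)
    motion = build_circumduction_sequence(
        config.peak_abduction,
        config.peak_flexion,
        config.peak_rotation,
        config.speed,
        config.n_steps,
    )
    return simulate_trajectory(anatomy, motion, config.wrap)


def run_sex(config: StudyConfig, sex: str) -> tuple[pd.DataFrame, ShapeModel, dict, np.ndarray]:
    """Training, model fitting, cohort sampling and simulation for one sex."""
    info: dict = {"sex": sex}
    t0 = time.time()

    rng_train = _child_seed(config.seed, "training", sex)
    training_params = sample_parameters(sex, config.n_training, rng=rng_train, config=config.population)
    training = [build_anatomy(p, config.population) for p in training_params]
    model_full = fit_shape_model([a.landmarks for a in training], align=False)
    k = model_full.modes_for_fraction(config.variance_threshold, cap=config.mode_cap)
    k = min(max(k, config.min_modes), model_full.t)
    model = model_full.truncated(k)
    info["retained_modes"] = k
    info["explained_variance"] = model_full.explained_variance_fraction(k)

    rng_cohort = _child_seed(config.seed, "cohort", sex)
    coeffs = model.sample_coefficients(config.n_cohort, rng=rng_cohort)

    scores = np.stack([c.b for c in coeffs])
    mah = np.stack([c.mahalanobis for c in coeffs])
    measures = np.empty((config.n_cohort, 5))
    peaks = np.empty(config.n_cohort)
    velocity_curves = np.full((config.n_cohort, config.n_steps), np.nan)
    converged = np.zeros(config.n_cohort, dtype=bool)
    n_clipped = 0
    failures: list[str] = []
    for i, c in enumerate(coeffs):
        landmarks = model.reconstruct(c)
        from .anatomy import LandmarkSet

        lms = LandmarkSet(points=landmarks, labels=list(training[0].landmarks.labels))
        measured = compute_discrete_measures(lms, sex=sex)
        measures[i] = measured.as_array()
        case_params = measured.clipped(margin=0.5)
        if not np.allclose(case_params.as_array(), measured.as_array(), atol=1e-6):
            n_clipped += 1
        try:
            traj = simulate_case(case_params, config)
            peaks[i] = traj.peak_velocity
            velocity_curves[i] = traj.velocity
            converged[i] = traj.converged
            if not traj.converged:
                failures.append(f"{sex} case {i}: {len(traj.warnings)} non-converged frames")
        except Exception as exc:  # rare degenerate geometry must not kill the run
            peaks[i] = np.nan
            failures.append(f"{sex} case {i}: {exc}")
    info["n_cohort"] = config.n_cohort
    info["n_converged"] = int(converged.sum())
    info["n_excluded"] = int(config.n_cohort - converged.sum())
    info["n_clipped_parameters"] = n_clipped
    info["failures"] = failures[:50]
    info["runtime_s"] = round(time.time() - t0, 2)
    cohort = make_cohort_table(sex, scores, mah, measures, peaks, converged)
    return cohort, model, info, velocity_curves


def run_study(config: StudyConfig, out_dir) -> StudyResult:
    """Execute the full study and write the report tables.

    Writes per-sex cohort tables, Manhattan-style per-mode correlations,
    discrete-measure correlations with the composite shape row, per-sex
    population summary, consensus shapes at +/- sd_level SD of velocity, and
    a JSON run report (counts, exclusions, timings, config echo, version).
    Partial outputs are preserved if a stage fails; the report records the
    failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "failed_stage": None,
    }
    cohorts: dict[str, pd.DataFrame] = {}
    models: dict[str, ShapeModel] = {}
    tables: dict[str, pd.DataFrame] = {}
    comparison = None
    try:
        curve_frames = []
        for sex in config.sexes:
            cohort, model, info, curves = run_sex(config, sex)
            cohorts[sex] = cohort
            models[sex] = model
            report["stages"][f"simulate_{sex}"] = info
            cohort.to_csv(out / f"cohort_{sex}.csv", index=False, float_format="%.8g")
            model.save(out / f"shape_model_{sex}.npz")
            ok = cohort["converged"].to_numpy()
            if ok.any():
                kept = curves[ok]
                curve_frames.append(
                    pd.DataFrame(
                        {
                            "sex": sex,
                            "frame": np.arange(config.n_steps),
                            "v_mean": np.nanmean(kept, axis=0),
                            "v_median": np.nanmedian(kept, axis=0),
                            "v_p05": np.nanpercentile(kept, 5, axis=0),
                            "v_p95": np.nanpercentile(kept, 95, axis=0),
                        }
                    )
                )
        if curve_frames:
            tables["cohort_velocity_curves"] = pd.concat(curve_frames, ignore_index=True)
            tables["cohort_velocity_curves"].to_csv(out / "cohort_velocity_curves.csv", index=False)

        # Table-1-style population summary of the measured cohort
        rows = []
        for name in ("neck_shaft_angle", "anteversion", "femoral_offset", "ischiofemoral_distance", "head_radius"):
            row = {"measure": name}
            for sex in config.sexes:
                vals = cohorts[sex][name]
                row[f"{sex}_mean"] = vals.mean()
                row[f"{sex}_sd"] = vals.std(ddof=1)
            rows.append(row)
        tables["population_summary"] = pd.DataFrame(rows)
        tables["population_summary"].to_csv(out / "population_summary.csv", index=False)

        rng = _child_seed(config.seed, "stats")
        mode_corr_frames, measure_corr_frames = [], []
        for sex in config.sexes:
            pc = per_pc_correlations(cohorts[sex])
            pc.insert(0, "sex", sex)
            mode_corr_frames.append(pc)
            dm = discrete_measure_correlations(
                cohorts[sex], n_permutations=config.n_permutations, seed=int(rng.integers(2**31))
            )
            dm.insert(0, "sex", sex)
            measure_corr_frames.append(dm)
            low, high, low_b, high_b = plsr_consensus_shapes(models[sex], cohorts[sex], config.sd_level)
            np.savetxt(out / f"consensus_low_{sex}.csv", low, fmt="%.4f", delimiter=",", header="x,y,z", comments="")
            np.savetxt(out / f"consensus_high_{sex}.csv", high, fmt="%.4f", delimiter=",", header="x,y,z", comments="")
        tables["mode_correlations"] = pd.concat(mode_corr_frames, ignore_index=True)
        tables["mode_correlations"].to_csv(out / "mode_correlations.csv", index=False)
        tables["measure_correlations"] = pd.concat(measure_corr_frames, ignore_index=True)
        tables["measure_correlations"].to_csv(out / "measure_correlations.csv", index=False)

        if {"male", "female"} <= set(config.sexes):
            comparison = compare_sexes(cohorts["male"], cohorts["female"])
            report["sex_comparison"] = comparison
    except Exception as exc:
        report["failed_stage"] = f"{type(exc).__name__}: {exc}"
        logger.exception("study stage failed")
    finally:
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return StudyResult(cohorts=cohorts, models=models, tables=tables, sex_comparison=comparison, report=report)
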