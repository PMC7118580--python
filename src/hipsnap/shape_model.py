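"""Point-distribution (PCA) statistical shape model.

Shapes are corresponding landmark configurations flattened to vectors of
length 3n; the model is S = S_mean + P^T b with orthonormal mode matrix P
(t x 3n) and per-mode variances lambda_i (descending). Virtual cohorts are
drawn by sampling each deviation weight b_i ~ Normal(0, lambda_i)
independently. Whitened scores b_i / sqrt(lambda_i) ("Mahalanobis scores")
put all modes on a common dimensionless scale, removing the dominance of
size before shape-function statistics.

Alignment is generalized Procrustes WITHOUT scale removal (rigid): size is
anatomy, and the population's size signal must stay in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.linalg import orthogonal_procrustes


class CorrespondenceError(ValueError):
    pass


@dataclass
class ShapeCoefficients:
    b: np.ndarray  # (t,) mode weights, mm
    mahalanobis: np.ndarray  # (t,) b_i / sqrt(lambda_i), dimensionless


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (3n,)
    modes: np.ndarray  # (t, 3n), orthonormal rows
    eigenvalues: np.ndarray  # (t,), mm^2, descending
    n_landmarks: int
    aligned: bool = False
    alignment: list = field(default_factory=list)  # per-training (R, t) pairs

    @property
    def t(self) -> int:
        return len(self.eigenvalues)

    # ------------------------------------------------------------------
    def explained_variance_fraction(self, k: int) -> float:
        if not 1 <= k <= self.t:
            raise ValueError(f"k must be in [1, {self.t}]")
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[:k].sum() / total)

    def modes_for_fraction(self, threshold: float = 0.99, cap: int | None = 20) -> int:
        """Smallest k whose cumulative variance fraction reaches threshold."""
        frac = np.cumsum(self.eigenvalues) / self.eigenvalues.sum()
        k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
        k = min(k, self.t)
        return min(k, cap) if cap is not None else k

    def truncated(self, k: int) -> "ShapeModel":
        if not 1 <= k <= self.t:
            raise ValueError(f"k must be in [1, {self.t}]")
        return ShapeModel(
            mean_shape=self.mean_shape,
            modes=self.modes[:k],
            eigenvalues=self.eigenvalues[:k],
            n_landmarks=self.n_landmarks,
            aligned=self.aligned,
            alignment=self.alignment,
        )

    # ------------------------------------------------------------------
    def sample_coefficients(self, n: int, seed=None, rng=None) -> list[ShapeCoefficients]:
        """n independent draws b_i ~ Normal(0, lambda_i)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        sd = np.sqrt(self.eigenvalues)
        B = rng.standard_normal((n, self.t)) * sd
        return [self._coeffs(b, sd) for b in B]

    def _coeffs(self, b, sd=None) -> ShapeCoefficients:
        sd = np.sqrt(self.eigenvalues) if sd is None else sd
        with np.errstate(divide="ignore", invalid="ignore"):
            mah = np.where(sd > 0, b / sd, np.nan)
        return ShapeCoefficients(b=np.asarray(b, float), mahalanobis=mah)

    def reconstruct(self, coeffs) -> np.ndarray:
        """Landmark set (n, 3) from mode weights."""
        b = coeffs.b if isinstance(coeffs, ShapeCoefficients) else np.asarray(coeffs, float)
        if len(b) != self.t:
            raise ValueError(f"expected {self.t} coefficients, got {len(b)}")
        return (self.mean_shape + b @ self.modes).reshape(-1, 3)

    def project(self, landmarks) -> ShapeCoefficients:
        """Mode weights b = P (S - S_mean) of a landmark configuration."""
        S = _flatten(landmarks)
        if len(S) != len(self.mean_shape):
            raise CorrespondenceError(
                f"landmark count mismatch: got {len(S) // 3}, model has {self.n_landmarks}"
            )
        if self.aligned:
            S = _rigid_align(S.reshape(-1, 3), self.mean_shape.reshape(-1, 3)).reshape(-1)
        return self._coeffs(self.modes @ (S - self.mean_shape))

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single .npz archive: binary arrays plus an embedded YAML header."""
        header = yaml.safe_dump(
            {"n_landmarks": self.n_landmarks, "t": self.t, "aligned": self.aligned}
        )
        np.savez(
            path,
            header=np.array(header),
            mean_shape=self.mean_shape,
            modes=self.modes,
            eigenvalues=self.eigenvalues,
        )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as data:
            meta = yaml.safe_load(str(data["header"]))
            return cls(
                mean_shape=data["mean_shape"],
                modes=data["modes"],
                eigenvalues=data["eigenvalues"],
                n_landmarks=int(meta["n_landmarks"]),
                aligned=bool(meta["aligned"]),
            )


def _flatten(landmarks) -> np.ndarray:
    pts = getattr(landmarks, "points", landmarks)
    return np.asarray(pts, dtype=float).reshape(-1)


def _rigid_align(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid (rotation + translation, scale retained) alignment to reference."""
    mu_p, mu_r = points.mean(axis=0), reference.mean(axis=0)
    R, _ = orthogonal_procrustes(points - mu_p, reference - mu_r)
    return (points - mu_p) @ R + mu_r


def fit_shape_model(training, align: bool = True, gpa_iterations: int = 3) -> ShapeModel:
    """PCA shape model from >= 3 corresponding landmark sets.

    Optional rigid generalized Procrustes alignment (iterative alignment to
    the evolving mean; scale retained), then eigendecomposition of the
    landmark covariance via SVD of the centred data matrix - the dual
    (Gram-matrix) route, efficient when the training count is far below 3n.
    """
    mats = [_flatten(s).reshape(-1, 3) for s in training]
    if len(mats) < 3:
        raise ValueError("need at least 3 training shapes")
    n = len(mats[0])
    if any(len(m) != n for m in mats):
        raise CorrespondenceError("training shapes have mismatched landmark counts")

    shapes = [m.astype(float) for m in mats]
    if align:
        ref = shapes[0]
        for _ in range(gpa_iterations):
            shapes = [_rigid_align(s, ref) for s in shapes]
            ref = np.mean(shapes, axis=0)

    X = np.stack([s.reshape(-1) for s in shapes])  # (m, 3n)
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD == dual eigendecomposition for m << 3n
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = svals**2 / (len(X) - 1)
    keep = eigenvalues > max(eigenvalues[0], 1.0) * 1e-12
    return ShapeModel(
        mean_shape=mean,
        modes=Vt[keep],
        eigenvalues=eigenvalues[keep],
        n_landmarks=n,
        aligned=align,
        alignment=[],
    )


def coefficients_to_csv(path, coeff_list) -> None:
    t = len(coeff_list[0].b)
    with open(path, "w") as fh:
        fh.write("case_id," + ",".join(f"b_{i + 1}" for i in range(t)) + "\n")
        for i, c in enumerate(coeff_list):
            fh.write(f"{i}," + ",".join(f"{v:.8g}" for v in c.b) + "\n")
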