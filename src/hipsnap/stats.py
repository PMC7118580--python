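"""Shape-function statistics for the simulated cohorts.

Relates per-case peak tendon velocity to anatomy three ways: per-mode
Pearson correlations on whitened (Mahalanobis) shape scores, a composite
canonical correlation between the full score block and velocity, and
one-component PLSR consensus shapes at +/- k SD of velocity. Discrete
clinical measures get the same correlation treatment for clinical
translation, and the sexes are compared with a Welch t-test.

With a univariate response the first canonical correlation equals the
multiple correlation R of least-squares regression of velocity on the score
block; the implementation computes it in that closed form and the test
suite checks it against an independent regression oracle. p-values are by
seeded permutation of the response (population-scale asymptotic p-values
are meaningless at desk-scale n; an asymptotic option exists).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anatomy import PARAMETER_FIELDS

MEASURE_COLUMNS = list(PARAMETER_FIELDS)


class CohortError(ValueError):
    pass


def make_cohort_table(
    sex: str,
    scores: np.ndarray,
    mahalanobis: np.ndarray,
    measures: np.ndarray,
    peak_velocity: np.ndarray,
    converged: np.ndarray,
) -> pd.DataFrame:
    """Assemble the per-case cohort table (one row per simulated case)."""
    n, t = scores.shape
    data = {"case_id": np.arange(n), "sex": sex}
    for i in range(t):
        data[f"b_{i + 1}"] = scores[:, i]
    for i in range(t):
        data[f"m_{i + 1}"] = mahalanobis[:, i]
    for j, name in enumerate(MEASURE_COLUMNS):
        data[name] = measures[:, j]
    data["peak_velocity"] = peak_velocity
    data["converged"] = np.asarray(converged, bool)
    return pd.DataFrame(data)


def _converged(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["converged"]] if "converged" in cohort else cohort


def _mode_columns(cohort: pd.DataFrame, prefix: str = "m_") -> list[str]:
    cols = [c for c in cohort.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def per_pc_correlations(cohort: pd.DataFrame, modes: int | None = None) -> pd.DataFrame:
    """Pearson r and two-sided p of peak velocity on each Mahalanobis score."""
    df = _converged(cohort)
    if len(df) < 3:
        raise CohortError("need at least 3 converged cases")
    cols = _mode_columns(df)
    if modes is not None:
        cols = cols[:modes]
    y = df["peak_velocity"].to_numpy()
    rows = []
    for c in cols:
        x = df[c].to_numpy()
        if np.std(x) < 1e-14 or np.std(y) < 1e-14:
            rows.append((c, np.nan, np.nan, len(df), True))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((c, r, p, len(df), False))
    return pd.DataFrame(rows, columns=["predictor", "r", "p", "n", "degenerate"])


def _multiple_correlation(X: np.ndarray, y: np.ndarray):
    """R of least squares of y on X, via an orthonormal basis of centred X.

    Returns (R, Q) with Q the orthonormal basis (rank-reduced when X is
    rank deficient).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    Q = U[:, :rank]
    ny = np.linalg.norm(yc)
    if ny < 1e-14:
        raise CohortError("zero velocity variance")
    r = float(np.linalg.norm(Q.T @ yc) / ny)
    return min(r, 1.0), Q, yc


def composite_correlation_cca(
    cohort: pd.DataFrame,
    n_permutations: int = 10000,
    seed=None,
    method: str = "permutation",
    predictors: list[str] | None = None,
) -> tuple[float, float]:
    """First canonical correlation between the score block and velocity.

    With a univariate response this is exactly the multiple correlation R of
    least-squares regression. p by seeded permutation of the velocity
    (default) or by the asymptotic overall-regression F test.
    """
    df = _converged(cohort)
    cols = predictors if predictors is not None else _mode_columns(df)
    if len(df) <= len(cols) + 2:
        raise CohortError("need cases > modes + 2")
    X = df[cols].to_numpy(float)
    y = df["peak_velocity"].to_numpy(float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(cols):
        import warnings

        warnings.warn("rank-deficient predictor block; using reduced rank", stacklevel=2)
    r, Q, yc = _multiple_correlation(X, y)

    if method == "asymptotic":
        n, k = len(y), Q.shape[1]
        r2 = r**2
        F = (r2 / k) / max((1 - r2) / (n - k - 1), 1e-300)
        p = float(sps.f.sf(F, k, n - k - 1))
    else:
        rng = np.random.default_rng(seed)
        ny = np.linalg.norm(yc)
        hits = 0
        for _ in range(n_permutations):
            yp = rng.permutation(yc)
            rp = np.linalg.norm(Q.T @ yp) / ny
            hits += rp >= r - 1e-12
        p = (1.0 + hits) / (1.0 + n_permutations)
    return float(r), float(p)


def plsr_consensus_shapes(model, cohort: pd.DataFrame, sd_level: float = 3.0):
    """One-component PLSR consensus shapes at -/+ ``sd_level`` SD of velocity.

    Regresses the mode-score block on standardized peak velocity with a
    single PLS component and reconstructs the predicted coefficient vectors
    at velocity = -sd_level and +sd_level SD through the shape model.
    Returns (low_shape, high_shape, low_b, high_b) with shapes as (n, 3)
    landmark arrays.
    """
    from sklearn.cross_decomposition import PLSRegression

    df = _converged(cohort)
    if len(df) < 10:
        raise CohortError("need at least 10 converged cases")
    cols = _mode_columns(df, prefix="b_")
    B = df[cols].to_numpy(float)
    y = df["peak_velocity"].to_numpy(float)
    if np.std(y) < 1e-14:
        raise CohortError("zero velocity variance")
    y_std = (y - y.mean()) / y.std()

    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(y_std[:, None], B)
    low = pls.predict([[-sd_level]])[0]
    high = pls.predict([[sd_level]])[0]
    return model.reconstruct(low), model.reconstruct(high), low, high


def discrete_measure_correlations(
    cohort: pd.DataFrame, n_permutations: int = 10000, seed=None
) -> pd.DataFrame:
    """Per-measure Pearson correlations with peak velocity + composite row."""
    df = _converged(cohort)
    if len(df) < 3:
        raise CohortError("need at least 3 converged cases")
    y = df["peak_velocity"].to_numpy()
    rows = []
    for name in MEASURE_COLUMNS:
        x = df[name].to_numpy()
        if np.std(x) < 1e-14 or np.std(y) < 1e-14:
            rows.append((name, np.nan, np.nan, len(df), True))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((name, r, p, len(df), False))
    r_comp, p_comp = composite_correlation_cca(cohort, n_permutations=n_permutations, seed=seed)
    rows.append(("femoral_shape_ssm", r_comp, p_comp, len(df), False))
    return pd.DataFrame(rows, columns=["predictor", "r", "p", "n", "degenerate"])


def compare_sexes(cohort_male: pd.DataFrame, cohort_female: pd.DataFrame) -> dict:
    """Welch two-sample t-test on peak velocity, plus per-sex summaries."""
    vm = _converged(cohort_male)["peak_velocity"].to_numpy()
    vf = _converged(cohort_female)["peak_velocity"].to_numpy()
    if len(vm) < 2 or len(vf) < 2:
        raise CohortError("need at least 2 converged cases per sex")
    t, p = sps.ttest_ind(vf, vm, equal_var=False)
    if np.isnan(t):  # identical degenerate samples
        t, p = 0.0, 1.0

    def summary(v):
        return {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": int(len(v)),
        }

    return {"t": float(t), "p": float(p), "male": summary(vm), "female": summary(vf)}
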