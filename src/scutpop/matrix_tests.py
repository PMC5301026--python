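"""Distance-matrix construction and association tests.

Isolation-by-distance / isolation-by-environment layer: build geographic and
environmental distance matrices over populations and test their association
with genetic distance (Rousset-linearized F_ST) via the Spearman Mantel
test, the partial Mantel test, and multiple matrix regression with
randomization (MMRR).

Permutation conventions: one matrix is permuted by jointly shuffling its
rows and columns; p-values use the add-one rule ((hits + 1)/(P + 1)).
Mantel p is one-tailed (positive association); MMRR coefficient p-values are
two-tailed and the overall model uses the upper tail of F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats

from .core_data import (
    BIOCLIM_VARS,
    DistanceMatrix,
    SiteTable,
    ValidationError,
    unfold_upper,
)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MatrixTestResult:
    statistic: str  # "mantel_rho" | "partial_mantel_rho" | "mmrr"
    coefficients: dict[str, float]
    p_values: dict[str, float]
    permutations: int
    r2: float | None = None
    f: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Distance construction
# ---------------------------------------------------------------------------


def geographic_distance(sites: list[SiteTable], mode: str = "projected") -> DistanceMatrix:
    """3-D geographic distances between sites.

    ``projected`` (default): latitude/longitude mapped to km by a local
    equirectangular projection, altitude in km -- physically meaningful.
    ``raw``: plain Euclidean distance on (latitude deg, longitude deg,
    altitude m), reproducing the mixed-unit convention some studies use.
    """
    if mode not in ("projected", "raw"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = [s.population for s in sites]
    lat = np.array([s.latitude for s in sites])
    lon = np.array([s.longitude for s in sites])
    alt = np.array([s.altitude for s in sites], dtype=float)
    if np.isnan(alt).any():
        raise ValidationError("missing altitude in a 3-D geographic mode")
    if mode == "raw":
        pts = np.column_stack([lat, lon, alt])
    else:
        lat0 = math.radians(lat.mean())
        x = np.radians(lon) * EARTH_RADIUS_KM * math.cos(lat0)
        y = np.radians(lat) * EARTH_RADIUS_KM
        pts = np.column_stack([x, y, alt / 1000.0])
    diff = pts[:, None, :] - pts[None, :, :]
    m = np.sqrt(np.sum(diff**2, axis=2))
    return DistanceMatrix(labels, m, kind="geographic")


def environmental_distance(
    sites: list[SiteTable],
    variables: tuple[str, ...] = BIOCLIM_VARS,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over bioclim variables (z-scored by default)."""
    labels = [s.population for s in sites]
    rows = []
    for s in sites:
        missing = [v for v in variables if v not in s.climate]
        if missing:
            raise ValidationError(f"site {s.population}: missing variables {missing}")
        rows.append([s.climate[v] for v in variables])
    X = np.asarray(rows, dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = [variables[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(f"zero-variance variables: {bad}")
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    m = np.sqrt(np.sum(diff**2, axis=2))
    return DistanceMatrix(labels, m, kind="environmental")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


def _aligned_values(*mats: DistanceMatrix) -> list[np.ndarray]:
    labels = mats[0].labels
    out = [mats[0].values]
    for m in mats[1:]:
        if set(m.labels) != set(labels):
            raise ValidationError("matrices cover different label sets")
        out.append(m.reorder(list(labels)).values)
    return out


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant distance matrix: correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _permute(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = rng.permutation(m.shape[0])
    return m[np.ix_(p, p)]


def mantel(
    ma: DistanceMatrix,
    mb: DistanceMatrix,
    method: str = "spearman",
    perms: int = 9999,
    seed: int = 0,
) -> MatrixTestResult:
    """Mantel test: correlation of unfolded upper triangles; one-tailed
    (greater) permutation p by jointly permuting rows+columns of ``mb``."""
    A, B = _aligned_values(ma, mb)
    iu = np.triu_indices(A.shape[0], k=1)
    rho = _corr(A[iu], B[iu], method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(perms):
        rho_p = _corr(A[iu], _permute(B, rng)[iu], method)
        hits += rho_p >= rho
    return MatrixTestResult(
        "mantel_rho", {"rho": rho}, {"rho": (hits + 1) / (perms + 1)}, perms
    )


def _partial_r(r_ab, r_ac, r_bc):
    denom = math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if denom == 0:
        raise ValidationError("degenerate conditioning: |r with C| = 1")
    return (r_ab - r_ac * r_bc) / denom


def partial_mantel(
    ma: DistanceMatrix,
    mb: DistanceMatrix,
    mc: DistanceMatrix,
    perms: int = 9999,
    seed: int = 0,
) -> MatrixTestResult:
    """Partial Mantel: Spearman rank correlation of A and B controlling C.

    The statistic is the first-order partial correlation of the rank-
    transformed unfolded triangles. Significance permutes the residuals of
    A's ranks on C's ranks (refolded to a matrix, rows+columns shuffled
    jointly) and correlates them with B's residuals on C.
    """
    A, B, C = _aligned_values(ma, mb, mc)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    ra = stats.rankdata(A[iu])
    rb = stats.rankdata(B[iu])
    rc = stats.rankdata(C[iu])
    r_ab = _corr(ra, rb, "pearson")
    r_ac = _corr(ra, rc, "pearson")
    r_bc = _corr(rb, rc, "pearson")
    rho = _partial_r(r_ab, r_ac, r_bc)

    def residuals(y, x):
        beta = np.polyfit(x, y, 1)
        return y - np.polyval(beta, x)

    res_a = residuals(ra, rc)
    res_b = residuals(rb, rc)
    # refold the A-residuals so rows/columns can be permuted jointly
    ra_mat = np.zeros((n, n))
    ra_mat[iu] = res_a
    ra_mat = ra_mat + ra_mat.T
    rng = np.random.default_rng(seed)
    denom = math.sqrt(np.sum(res_a**2) * np.sum(res_b**2))
    stat_obs = float(np.sum(res_a * res_b) / denom)
    hits = 0
    for _ in range(perms):
        perm = _permute(ra_mat, rng)[iu]
        stat_p = float(np.sum(perm * res_b)
                       / math.sqrt(np.sum(perm**2) * np.sum(res_b**2)))
        hits += stat_p >= stat_obs
    return MatrixTestResult(
        "partial_mantel_rho", {"rho": rho},
        {"rho": (hits + 1) / (perms + 1)}, perms,
    )


# ---------------------------------------------------------------------------
# MMRR
# ---------------------------------------------------------------------------


def mmrr(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    perms: int = 9999,
    seed: int = 0,
) -> MatrixTestResult:
    """Multiple matrix regression with randomization.

    OLS of the standardized unfolded response on standardized unfolded
    predictors; standardized betas, R^2 and F. Significance by permuting the
    response matrix (rows+columns jointly) and recomputing |t| (two-tailed,
    per coefficient) and F (upper tail).
    """
    if not predictors:
        raise ValidationError("MMRR needs >= 1 predictor matrix")
    names = list(predictors)
    mats = _aligned_values(response, *[predictors[k] for k in names])
    Yfull, Xmats = mats[0], mats[1:]
    n = Yfull.shape[0]
    iu = np.triu_indices(n, k=1)

    def z(v):
        sd = v.std()
        if sd == 0:
            raise ValidationError("constant matrix in MMRR")
        return (v - v.mean()) / sd

    X = np.column_stack([z(m[iu]) for m in Xmats])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValidationError("perfectly collinear predictor matrices")
    k = X.shape[1]
    Xd = np.column_stack([np.ones(len(X)), X])
    npair = len(X)

    def fit(yvec):
        y = z(yvec)
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1 - ss_res / ss_tot
        dfe = npair - k - 1
        mse = ss_res / dfe
        xtx_inv = np.linalg.inv(Xd.T @ Xd)
        se = np.sqrt(mse * np.diag(xtx_inv))[1:]
        t = coef[1:] / se
        if 1 - r2 < 1e-14:
            f = math.inf  # exact linear combination
        else:
            f = (r2 / k) / ((1 - r2) / dfe)
        return coef[1:], t, r2, f

    beta, t_obs, r2, f_obs = fit(Yfull[iu])
    rng = np.random.default_rng(seed)
    hits_t = np.zeros(k)
    hits_f = 0
    for _ in range(perms):
        _, t_p, _, f_p = fit(_permute(Yfull, rng)[iu])
        hits_t += np.abs(t_p) >= np.abs(t_obs)
        hits_f += f_p >= f_obs
    p = {name: (hits_t[i] + 1) / (perms + 1) for i, name in enumerate(names)}
    p["F"] = (hits_f + 1) / (perms + 1)
    return MatrixTestResult(
        "mmrr",
        {name: float(beta[i]) for i, name in enumerate(names)},
        p, perms, r2=float(r2), f=float(f_obs),
        extras={"t": {name: float(t_obs[i]) for i, name in enumerate(names)}},
    )
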