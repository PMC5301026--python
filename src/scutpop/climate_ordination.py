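"""Climate-variable pruning, ordination, and the climate-on-genetics layer.

``vif_prune`` iteratively removes the most collinear bioclim variable until
all variance inflation factors fall under the threshold. ``climate_pca`` is
a correlation-matrix PCA with deterministic loading signs. The genetic
response for the constrained ordination is built by metric PCoA of the
individual-level allele-sharing distance; ``partial_dbrda`` then fits a
redundancy analysis of those axes on climate predictors conditioned on
geography (latitude/longitude), with marginal per-term pseudo-F statistics
and permutation-of-residuals p-values. Individuals carry the climate and
coordinates of their population's site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    MISSING,
    GenotypeTable,
    SiteTable,
    ValidationError,
)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


def vif_values(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) of each column regressed on the others
    (with intercept); perfect collinearity yields +inf."""
    out = {}
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    for j, col in enumerate(X.columns):
        y = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(climate: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the highest-VIF variable until all VIFs < threshold.

    Returns the retained variable names (original order); the drop order is
    recorded in the returned list's companion attribute via
    ``vif_prune.last_drop_order`` for logging.
    """
    if climate.shape[1] < 2:
        raise ValidationError("VIF pruning needs >= 2 variables")
    cols = list(climate.columns)
    dropped: list[str] = []
    while len(cols) >= 2:
        v = vif_values(climate[cols])
        worst = v.idxmax()
        if not np.isfinite(v[worst]) or v[worst] >= threshold:
            cols.remove(worst)
            dropped.append(worst)
        else:
            break
    vif_prune.last_drop_order = dropped  # type: ignore[attr-defined]
    return cols


# ---------------------------------------------------------------------------
# Climate PCA
# ---------------------------------------------------------------------------


def climate_pca(
    sites: list[SiteTable], variables: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA of climate variables across sites.

    Returns (loadings, site scores, explained variance fractions). Loading
    signs are fixed so each component's largest-magnitude loading is
    positive (deterministic orientation).
    """
    from sklearn.decomposition import PCA

    rows = [[s.climate[v] for v in variables] for s in sites]
    X = np.asarray(rows, dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero = [variables[i] for i in np.flatnonzero(sd == 0)]
    if zero:
        raise ValidationError(f"zero-variance variables: {zero}")
    Xs = (X - X.mean(axis=0)) / sd
    k = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    load = pca.components_.T  # variables x components
    for c in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, c])), c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    comp = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(load, index=list(variables), columns=comp),
        pd.DataFrame(scores, index=[s.population for s in sites], columns=comp),
        pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# Genetic PCoA response
# ---------------------------------------------------------------------------


def allele_sharing_distance(gt: GenotypeTable) -> np.ndarray:
    """1 - (shared alleles / 2) per locus, averaged over mutually scored loci."""
    n, L = gt.n_individuals, gt.n_loci
    D = np.zeros((n, n))
    G = gt.genotypes
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for l in range(L):
                a, b = G[i, l], G[j, l]
                if a[0] == MISSING or b[0] == MISSING:
                    continue
                shared = 0
                bb = list(b)
                for x in a:
                    if x in bb:
                        shared += 1
                        bb.remove(x)
                num += 1 - shared / 2.0
                den += 1
            D[i, j] = D[j, i] = num / den if den else 0.0
    return D


def metric_pcoa(D: np.ndarray, n_axes: int = 5) -> np.ndarray:
    """Classical (metric) PCoA scores on the leading positive eigen-axes."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > 1e-10
    w, V = w[pos], V[:, pos]
    k = min(n_axes, len(w))
    return V[:, :k] * np.sqrt(w[:k])


def genetic_components(gt: GenotypeTable, n_axes: int = 5) -> np.ndarray:
    """The first ``n_axes`` PCoA axes of the allele-sharing distance."""
    return metric_pcoa(allele_sharing_distance(gt), n_axes)


# ---------------------------------------------------------------------------
# Partial dbRDA
# ---------------------------------------------------------------------------


@dataclass
class DbrdaResult:
    inertia: dict[str, float]  # total/conditional/constrained/unconstrained
    proportions: dict[str, float]
    terms: pd.DataFrame  # per predictor: inertia, proportion, F, p
    site_scores: np.ndarray  # ordination axes 1..2


def _hat_fit(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ coef


def partial_dbrda(
    response: np.ndarray,
    predictors: pd.DataFrame,
    conditioners: pd.DataFrame | None = None,
    perms: int = 999,
    seed: int = 0,
) -> DbrdaResult:
    """Partial RDA of multivariate response axes on predictors given
    conditioners.

    Inertia is the sum of column variances (mean squared deviation per
    degree of freedom); the decomposition conditional + constrained +
    unconstrained = total holds exactly. Per-predictor statistics are
    marginal: the drop in constrained inertia when the term is removed,
    F = drop / (residual inertia / residual df), with p-values from
    permuting the rows of the conditioned response residuals.
    """
    Y = np.asarray(response, dtype=float)
    n = Y.shape[0]
    X = predictors.to_numpy(dtype=float)
    if conditioners is not None and conditioners.shape[1] > 0:
        Z = conditioners.to_numpy(dtype=float)
    else:
        Z = np.empty((n, 0))
    if X.shape[1] + Z.shape[1] > n - 1:
        raise ValidationError("more predictors+conditioners than sites - 1")
    Yc = Y - Y.mean(axis=0)
    denom = n - 1
    total = float(np.sum(Yc**2)) / denom
    ZI = np.column_stack([np.ones(n), Z])
    fit_z = _hat_fit(Yc, ZI) if Z.shape[1] else np.tile(Yc.mean(axis=0), (n, 1))
    conditional = float(np.sum(fit_z**2)) / denom if Z.shape[1] else 0.0
    Yr = Yc - fit_z
    Xc = X - X.mean(axis=0)
    Xr = Xc - _hat_fit(Xc, ZI) if Z.shape[1] else Xc
    fit_x = _hat_fit(Yr, Xr)
    constrained = float(np.sum(fit_x**2)) / denom
    resid = Yr - fit_x
    unconstrained = float(np.sum(resid**2)) / denom
    df_resid = n - 1 - Z.shape[1] - X.shape[1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    def constrained_inertia(Yres: np.ndarray, cols: list[int]) -> float:
        if not cols:
            return 0.0
        return float(np.sum(_hat_fit(Yres, Xr[:, cols]) ** 2)) / denom

    all_cols = list(range(X.shape[1]))
    rng = np.random.default_rng(seed)
    rows = []
    ms_resid = unconstrained * denom / df_resid
    drops = {}
    for j, name in enumerate(predictors.columns):
        without = [c for c in all_cols if c != j]
        drop = constrained - constrained_inertia(Yr, without)
        drops[name] = drop
        rows.append({
            "term": name, "inertia": drop, "proportion": drop / total,
            "F": (drop * denom) / (unconstrained * denom / df_resid),
        })
    # permutation of residuals of the conditioned (reduced) model
    hits = {name: 0 for name in predictors.columns}
    for _ in range(perms):
        Yp = Yr[rng.permutation(n)]
        c_full = float(np.sum(_hat_fit(Yp, Xr) ** 2)) / denom
        u_p = float(np.sum(Yp**2)) / denom - c_full
        for j, name in enumerate(predictors.columns):
            without = [c for c in all_cols if c != j]
            drop_p = c_full - constrained_inertia(Yp, without)
            f_p = (drop_p * denom) / (u_p * denom / df_resid)
            f_o = (drops[name] * denom) / (unconstrained * denom / df_resid)
            hits[name] += f_p >= f_o
    for r in rows:
        r["p"] = (hits[r["term"]] + 1) / (perms + 1)
    U, s, Vt = np.linalg.svd(fit_x, full_matrices=False)
    scores = (U * s)[:, :2]
    return DbrdaResult(
        inertia={"total": total, "conditional": conditional,
                 "constrained": constrained, "unconstrained": unconstrained},
        proportions={"conditional": conditional / total,
                     "constrained": constrained / total,
                     "unconstrained": unconstrained / total},
        terms=pd.DataFrame(rows),
        site_scores=scores,
    )


def climate_dbrda(
    gt: GenotypeTable,
    sites: list[SiteTable],
    variables: tuple[str, ...],
    n_axes: int = 5,
    perms: int = 999,
    seed: int = 0,
) -> DbrdaResult:
    """Partial dbRDA of genetic PCoA axes on climate, conditioned on
    latitude/longitude; individuals inherit their site's values."""
    site_of = {s.population: s for s in sites}
    missing = [d for d in gt.deme_names if d not in site_of]
    if missing:
        raise ValidationError(f"no site row for demes: {missing}")
    Y = genetic_components(gt, n_axes)
    pred = pd.DataFrame(
        [[site_of[d].climate[v] for v in variables] for d in gt.demes],
        columns=list(variables),
    )
    cond = pd.DataFrame(
        [[site_of[d].latitude, site_of[d].longitude] for d in gt.demes],
        columns=["latitude", "longitude"],
    )
    return partial_dbrda(Y, pred, cond, perms=perms, seed=seed)


# ---------------------------------------------------------------------------
# GLM of a climate variable on ordination axes
# ---------------------------------------------------------------------------


def axis_glm(values: np.ndarray, axis_scores: np.ndarray) -> dict[str, float]:
    """OLS of a climate variable on ordination axes 1-2.

    Returns t per axis, the overall F with its p, and adjusted R^2.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    X = np.asarray(axis_scores, dtype=float)[:, :2]
    if len(y) < 3:
        raise ValidationError("axis GLM needs >= 3 observations")
    if np.ptp(y) == 0:
        raise ValidationError("constant variable: fit undefined")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return {
        "coef_axis1": float(model.params[1]),
        "coef_axis2": float(model.params[2]),
        "t_axis1": float(model.tvalues[1]),
        "p_axis1": float(model.pvalues[1]),
        "t_axis2": float(model.tvalues[2]),
        "p_axis2": float(model.pvalues[2]),
        "adj_r2": float(model.rsquared_adj),
        "F": float(model.fvalue),
        "p": float(model.f_pvalue),
    }
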