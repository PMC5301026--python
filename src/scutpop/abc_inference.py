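"""Approximate Bayesian computation over the four demographic scenarios.

Workflow: draw parameters from priors, simulate microsatellite datasets under
each scenario, reduce them to a fixed summary-statistic vector, retain the
simulations nearest the observed vector (rejection, MAD-standardized
Euclidean distance), and score each scenario by a GLM-adjusted marginal
density -- a multivariate-normal regression of summaries on parameters fitted
on the retained set and evaluated at the observed vector as a Monte-Carlo
mixture. Posterior model probabilities are the normalized marginal
densities; Bayes factors are their ratios.

Priors default to broad log-uniform envelopes (sizes 10..1e4, times
1..1e5 generations, migration 1e-5..1e-1, mutation rate 1e-5..1e-3); the
constraint T2 < T1 (and within-tpe splits more recent than founding) is
enforced by rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .core_data import GenotypeTable, MISSING, ValidationError
from . import coalsim
from .coalsim import ScenarioSpec

SUMMARY_DOC = (
    "per-deme mean allele number, per-deme expected heterozygosity, global "
    "F_IS/F_ST/F_IT, mean pairwise F_ST, total allele count, mean variance "
    "of allele size"
)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def summaries_from_arrays(
    alleles: np.ndarray, deme_idx: np.ndarray, deme_names: list[str]
) -> pd.Series:
    """Summary vector from raw allele arrays (fast path for simulation).

    ``alleles`` is (n_loci, n_individuals, 2); ``deme_idx`` assigns each
    individual to a deme. Undefined F-statistics (monomorphic data) are
    null-coded as 0.0 and flagged in ``attrs``.
    """
    n_loci, n_ind, _ = alleles.shape
    d = len(deme_names)
    copies = alleles.reshape(n_loci, n_ind * 2)
    copy_deme = np.repeat(deme_idx, 2)
    na = np.zeros((n_loci, d))
    he = np.zeros((n_loci, d))
    ho = np.zeros((n_loci, d))
    ht_loc = np.zeros(n_loci)
    hs_loc = np.zeros(n_loci)
    gst_pair = np.zeros((n_loci, d, d))
    ht_pair = np.zeros((n_loci, d, d))
    total_alleles = 0
    var_sizes = np.zeros(n_loci)
    for l in range(n_loci):
        col = copies[l]
        vals, inv = np.unique(col, return_inverse=True)
        K = len(vals)
        total_alleles += K
        var_sizes[l] = float(np.var(col))
        P = np.zeros((d, K))
        for k in range(d):
            sel = copy_deme == k
            cnt = np.bincount(inv[sel], minlength=K)
            P[k] = cnt / cnt.sum()
        s2 = np.sum(P**2, axis=1)
        na[l] = (P > 0).sum(axis=1)
        he[l] = 1.0 - s2
        g = alleles[l]
        for k in range(d):
            sel = deme_idx == k
            ho[l, k] = float(np.mean(g[sel, 0] != g[sel, 1]))
        pbar = P.mean(axis=0)
        ht_loc[l] = 1.0 - np.sum(pbar**2)
        hs_loc[l] = float(np.mean(he[l]))
        cross = P @ P.T
        ht_ij = 1.0 - (s2[:, None] + s2[None, :] + 2 * cross) / 4.0
        hs_ij = 1.0 - (s2[:, None] + s2[None, :]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            gst = np.where(ht_ij > 0, (ht_ij - hs_ij) / ht_ij, np.nan)
        gst_pair[l] = gst
        ht_pair[l] = ht_ij
    names, values = [], []
    for k, dn in enumerate(deme_names):
        names.append(f"na_{dn}")
        values.append(float(na[:, k].mean()))
    for k, dn in enumerate(deme_names):
        names.append(f"he_{dn}")
        values.append(float(he[:, k].mean()))
    ho_bar, hs_bar, ht_bar = float(ho.mean()), float(hs_loc.mean()), float(ht_loc.mean())
    monomorphic = ht_bar <= 0
    fis = 0.0 if (monomorphic or hs_bar <= 0) else 1 - ho_bar / hs_bar
    fst = 0.0 if monomorphic else 1 - hs_bar / ht_bar
    fit = 0.0 if monomorphic else 1 - ho_bar / ht_bar
    names += ["fis", "fst", "fit"]
    values += [fis, fst, fit]
    # pairwise F_ST per deme pair (averaged over usable loci) and their mean;
    # the per-pair entries carry the topology signal that separates
    # single-origin from multiple-origin histories
    iu = np.triu_indices(d, k=1)
    pair_means = []
    for a, b in zip(*iu):
        col = gst_pair[:, a, b]
        col = col[np.isfinite(col)]
        val = float(col.mean()) if col.size else 0.0
        pair_means.append(val)
        names.append(f"fst_{deme_names[a]}_{deme_names[b]}")
        values.append(val)
    names.append("mean_pairwise_fst")
    values.append(float(np.mean(pair_means)) if pair_means else 0.0)
    names.append("total_alleles")
    values.append(float(total_alleles))
    names.append("var_allele_size")
    values.append(float(var_sizes.mean()))
    out = pd.Series(values, index=names, dtype=float)
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("non-finite summary statistic")
    out.attrs["monomorphic"] = bool(monomorphic)
    return out


def compute_summaries(data: GenotypeTable | coalsim.SimulatedDataset) -> pd.Series:
    """Summary vector for an observed table or a simulated dataset."""
    gt = data.genotypes if isinstance(data, coalsim.SimulatedDataset) else data
    demes = gt.deme_names
    if len(demes) < 2:
        raise ValidationError("summaries need >= 2 demes")
    if (gt.genotypes == MISSING).any():
        raise ValidationError(
            "summary vector requires complete genotypes; drop missing first"
        )
    idx = np.array([demes.index(d) for d in gt.demes])
    alleles = gt.genotypes.transpose(1, 0, 2)
    return summaries_from_arrays(alleles, idx, demes)


# ---------------------------------------------------------------------------
# Priors and scenario models
# ---------------------------------------------------------------------------


@dataclass
class Prior:
    kind: str  # "log_uniform" | "uniform"
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi) and self.kind == "log_uniform":
            raise ValidationError("log-uniform bounds must be positive, ordered")
        if self.lo >= self.hi:
            raise ValidationError("prior bounds must be ordered")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "log_uniform":
            return float(10 ** rng.uniform(math.log10(self.lo), math.log10(self.hi)))
        return float(rng.uniform(self.lo, self.hi))


def _size_prior() -> Prior:
    return Prior("log_uniform", 10, 1e4)


def _time_prior() -> Prior:
    return Prior("log_uniform", 1, 1e5)


def _m_prior() -> Prior:
    return Prior("log_uniform", 1e-5, 1e-1)


def _mu_prior() -> Prior:
    return Prior("log_uniform", 1e-5, 1e-3)


@dataclass
class ScenarioModel:
    """A named scenario: priors plus a params -> ScenarioSpec builder."""

    name: str
    priors: dict[str, Prior]
    build: Callable[..., ScenarioSpec]
    loci_cfg: dict = field(default_factory=dict)

    def draw_params(self, rng: np.random.Generator, max_tries: int = 1000) -> dict:
        for _ in range(max_tries):
            params = {k: p.draw(rng) for k, p in self.priors.items()}
            try:
                self.build(**params, **self.loci_cfg)
            except ValidationError:
                continue
            return params
        raise ValidationError(f"prior of {self.name}: constraints never satisfied")

    def spec(self, params: dict) -> ScenarioSpec:
        return self.build(**params, **self.loci_cfg)


def default_models(n_msat_loci: int = 11) -> dict[str, ScenarioModel]:
    """The four competing scenarios with default priors."""
    cfg = {"n_msat_loci": n_msat_loci}
    return {
        "secondary_contact": ScenarioModel(
            "secondary_contact",
            {
                "n_anc": _size_prior(), "n_bar": _size_prior(),
                "n_bar_bottleneck": _size_prior(), "n_tpe": _size_prior(),
                "n_tpe_bottleneck": _size_prior(),
                "t_divergence": _time_prior(), "t_bar_bottleneck": _time_prior(),
                "t_tpe_bottleneck": _time_prior(),
                "t_migration_onset": _time_prior(),
                "m": _m_prior(), "mu": _mu_prior(),
            },
            coalsim.scenario_secondary_contact, cfg,
        ),
        "founder": ScenarioModel(
            "founder",
            {
                "n_anc": _size_prior(), "n_bar_bottleneck": _size_prior(),
                "n_bar": _size_prior(), "n_tpe": _size_prior(),
                "t1": _time_prior(), "t2": _time_prior(),
                "m": _m_prior(), "mu": _mu_prior(),
            },
            coalsim.scenario_founder, cfg,
        ),
        "multiple_origins": ScenarioModel(
            "multiple_origins",
            {
                "n_bar": _size_prior(), "n_tpe1": _size_prior(),
                "n_tpe2": _size_prior(), "n_tpe3": _size_prior(),
                "t1": _time_prior(), "t2": _time_prior(), "t3": _time_prior(),
                "m": _m_prior(), "mu": _mu_prior(),
            },
            lambda n_bar, n_tpe1, n_tpe2, n_tpe3, t1, t2, t3, m, mu, **k:
                coalsim.scenario_multiple_origins(
                    n_bar=n_bar, n_tpe=(n_tpe1, n_tpe2, n_tpe3),
                    t_founding=(t1, t2, t3), m=m, mu=mu, **k),
            cfg,
        ),
        "single_origin": ScenarioModel(
            "single_origin",
            {
                "n_bar": _size_prior(), "n_tpe1": _size_prior(),
                "n_tpe2": _size_prior(), "n_tpe3": _size_prior(),
                "t_founding": _time_prior(),
                "t_split1": _time_prior(), "t_split2": _time_prior(),
                "m": _m_prior(), "mu": _mu_prior(),
            },
            lambda n_bar, n_tpe1, n_tpe2, n_tpe3, t_founding, t_split1,
                   t_split2, m, mu, **k:
                coalsim.scenario_single_origin(
                    n_bar=n_bar, n_tpe=(n_tpe1, n_tpe2, n_tpe3),
                    t_founding=t_founding, t_splits=(t_split1, t_split2),
                    m=m, mu=mu, **k),
            cfg,
        ),
    }


def simulate_reference_table(
    model: ScenarioModel,
    sample_sizes: dict[str, int],
    n_sims: int,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Prior draws + simulations: (params table, summary matrix, names)."""
    rng = np.random.default_rng(seed)
    params_rows = []
    summaries = []
    names: list[str] | None = None
    for i in range(n_sims):
        params = model.draw_params(rng)
        spec = model.spec(params)
        sim_seed = int(rng.integers(1, 2**31 - 1))
        alleles, deme_idx, demes, _ = coalsim.simulate_msat_arrays(
            spec, sample_sizes, sim_seed
        )
        s = summaries_from_arrays(alleles, deme_idx, demes)
        if names is None:
            names = list(s.index)
        params_rows.append(params)
        summaries.append(s.to_numpy())
    return pd.DataFrame(params_rows), np.asarray(summaries), names or []


# ---------------------------------------------------------------------------
# PLS transform
# ---------------------------------------------------------------------------


def pls_transform(
    sim_summaries: np.ndarray, sim_params: np.ndarray, k: int
):
    """Fit a PLS reduction of summaries maximizing covariance with parameters.

    Summaries are standardized internally (constant columns dropped); returns
    (transformed simulations, transform function reusable on new vectors).
    """
    from sklearn.cross_decomposition import PLSRegression

    if k <= 0:
        raise ValidationError("PLS needs k >= 1 components")
    X = np.asarray(sim_summaries, dtype=float)
    Y = np.asarray(sim_params, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if k > keep.sum():
        raise ValidationError("k exceeds number of informative summaries")
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(Xs, Y - Y.mean(axis=0))

    def transform(v: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(v, dtype=float))
        vs = (v[:, keep] - mean[keep]) / sd[keep]
        out = pls.transform(vs)
        return out[0] if out.shape[0] == 1 else out

    return pls.transform(Xs), transform


# ---------------------------------------------------------------------------
# Rejection, GLM marginal density, model posterior
# ---------------------------------------------------------------------------


@dataclass
class RejectionResult:
    params: pd.DataFrame
    summaries: np.ndarray
    distances: np.ndarray
    indices: np.ndarray


def abc_reject(
    observed: np.ndarray,
    sim_summaries: np.ndarray,
    sim_params: pd.DataFrame,
    retain_k: int,
) -> RejectionResult:
    """Retain the ``retain_k`` simulations nearest the observed vector.

    Distance: Euclidean after dividing each summary by its simulation-wide
    median absolute deviation (columns with zero MAD are dropped). Ties are
    broken by simulation index, so the result is deterministic.
    """
    S = np.asarray(sim_summaries, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if retain_k > len(S):
        raise ValidationError("retain_k exceeds number of simulations")
    med = np.median(S, axis=0)
    mad = np.median(np.abs(S - med), axis=0)
    keep = mad > 0
    if not keep.any():
        raise ValidationError("all summaries constant across simulations")
    dist = np.sqrt(np.sum(((S[:, keep] - obs[keep]) / mad[keep]) ** 2, axis=1))
    order = np.lexsort((np.arange(len(S)), dist))[:retain_k]
    return RejectionResult(
        sim_params.iloc[order].reset_index(drop=True),
        S[order], dist[order], order,
    )


def glm_marginal_density(retained: RejectionResult, observed: np.ndarray) -> float:
    """GLM-adjusted marginal density of the observed summaries.

    Fits s = a + B theta + eps (eps ~ N(0, Sigma)) on the retained set by
    least squares (parameters log10-transformed for stability) and evaluates
    the observed vector under the fitted mixture over retained parameter
    draws. Singular residual covariances are ridge-regularized.
    """
    if len(retained.params) < 100:
        raise ValidationError("GLM marginal density needs >= 100 retained draws")
    S = retained.summaries
    obs = np.asarray(observed, dtype=float)
    keep = S.std(axis=0) > 0
    S = S[:, keep]
    obs = obs[keep]
    theta = np.log10(retained.params.to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(theta)), theta])
    coef, *_ = np.linalg.lstsq(X, S, rcond=None)
    resid = S - X @ coef
    sigma = np.cov(resid.T)
    sigma = np.atleast_2d(sigma)
    d = sigma.shape[0]
    ridge = 1e-10 * np.trace(sigma) / d
    for _ in range(20):
        try:
            L = np.linalg.cholesky(sigma + ridge * np.eye(d))
            break
        except np.linalg.LinAlgError:
            ridge *= 10
    else:  # pragma: no cover
        raise ValidationError("residual covariance irreparably singular")
    preds = X @ coef
    diff = obs - preds
    z = np.linalg.solve(L, diff.T)
    logdet = 2 * np.sum(np.log(np.diag(L)))
    logpdf = -0.5 * (np.sum(z**2, axis=0) + logdet + d * math.log(2 * math.pi))
    return float(np.exp(logsumexp(logpdf) - math.log(len(preds))))


@dataclass
class ModelComparison:
    densities: dict[str, float]
    posteriors: dict[str, float]
    bayes_factors: dict[tuple[str, str], float]


def model_posterior(densities: dict[str, float]) -> ModelComparison:
    """Posterior model probabilities and Bayes factors from marginal
    densities (equal prior model weights)."""
    if len(densities) < 2:
        raise ValidationError("model comparison needs >= 2 scenarios")
    if any(d < 0 for d in densities.values()):
        raise ValidationError("densities must be non-negative")
    total = sum(densities.values())
    if total == 0:
        raise ValidationError("all marginal densities are zero")
    post = {k: v / total for k, v in densities.items()}
    bf = {}
    for a in densities:
        for b in densities:
            if a != b:
                bf[(a, b)] = densities[a] / densities[b] if densities[b] > 0 else math.inf
    return ModelComparison(dict(densities), post, bf)


def posterior_param_estimates(
    params: pd.DataFrame, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-parameter KDE mode and equal-tailed 95% interval.

    Constant columns get a degenerate zero-width interval and a warning flag.
    """
    if params.empty:
        raise ValidationError("retained parameter set is empty")
    rows = []
    for col in params.columns:
        x = params[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"parameter": col, "mode": float(x[0]),
                         "q025": float(x[0]), "q975": float(x[0]),
                         "degenerate": True})
            continue
        kde = gaussian_kde(x, weights=weights)
        grid = np.linspace(x.min(), x.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
        if weights is None:
            lo, hi = np.quantile(x, [0.025, 0.975])
        else:
            order = np.argsort(x)
            cw = np.cumsum(np.asarray(weights)[order])
            cw = cw / cw[-1]
            lo = float(np.interp(0.025, cw, x[order]))
            hi = float(np.interp(0.975, cw, x[order]))
        rows.append({"parameter": col, "mode": mode, "q025": float(lo),
                     "q975": float(hi), "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end model choice
# ---------------------------------------------------------------------------


def run_model_choice(
    observed: np.ndarray,
    models: dict[str, ScenarioModel],
    sample_sizes: dict[str, int],
    n_sims: int = 10_000,
    retain: int = 500,
    seed: int = 0,
    reference_tables: dict | None = None,
) -> ModelComparison:
    """Full pipeline: simulate (or reuse) reference tables, reject, score.

    ``reference_tables`` may carry precomputed ``(params, summaries, names)``
    per model name to amortize simulation cost across repeated calls.
    """
    densities = {}
    for i, (name, model) in enumerate(sorted(models.items())):
        if reference_tables is not None and name in reference_tables:
            params, summaries, _ = reference_tables[name]
        else:
            params, summaries, _ = simulate_reference_table(
                model, sample_sizes, n_sims, seed + 7919 * (i + 1)
            )
            if reference_tables is not None:
                reference_tables[name] = (params, summaries, None)
        retained = abc_reject(observed, summaries, params, retain)
        densities[name] = glm_marginal_density(retained, observed)
    return model_posterior(densities)
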