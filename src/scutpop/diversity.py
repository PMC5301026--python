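"""Diversity and neutrality statistics.

Sequence side: segregating sites, nucleotide diversity pi (mean pairwise
differences *per locus*, matching how short organellar fragments are usually
tabulated), Watterson's theta_W = S / a_{n-1}, and Tajima's D with two
p-values -- the beta-distribution approximation and a coalescent-simulation
null conditioned on S.

Microsatellite side: the standard per-deme diversity panel (polymorphic
loci, allele counts, effective alleles, Shannon's index, private alleles,
expected heterozygosity) and an Fdist-style F_ST-outlier scan against a
coalescent island-model null envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    MISSING,
    GenotypeTable,
    SequenceAlignment,
    ScutpopError,
    ValidationError,
    harmonic_number,
)
from .coalsim import smm_overlay


class InsufficientSampleError(ScutpopError):
    pass


# ---------------------------------------------------------------------------
# Tajima's D machinery
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's D."""
    if n < 2:
        raise InsufficientSampleError("Tajima's D needs n >= 2")
    a1 = harmonic_number(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, pi: float) -> float | None:
    """Tajima's D from (n, S, pi); None when undefined (S = 0, or the
    variance constants vanish, which happens for n < 4 with S = 1)."""
    if S == 0:
        return None
    c = tajima_constants(n)
    denom = c["e1"] * S + c["e2"] * S * (S - 1)
    if denom <= 0:
        return None
    return (pi - S / c["a1"]) / math.sqrt(denom)


def tajima_beta_p(n: int, d: float) -> float:
    """Two-sided p for Tajima's D under the scaled-beta approximation.

    D is assumed to follow a beta distribution rescaled to [Dmin, Dmax]
    with mean 0 and variance 1. Undefined for n < 4 (the rescaled variance
    constant vanishes at n = 3).
    """
    c = tajima_constants(n)
    e2 = c["e2"]
    if e2 <= 1e-15:
        raise InsufficientSampleError("beta approximation needs n >= 4")
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(e2)
    alpha = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1 + dmin * dmax) * dmin / (dmax - dmin)
    x = (d - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2 * min(cdf, 1 - cdf))


# ---------------------------------------------------------------------------
# Sequence diversity
# ---------------------------------------------------------------------------


@dataclass
class SeqDiversityResult:
    n: int
    S: int
    pi: float
    theta_w: float
    tajima_d: float | None
    p_beta: float | None
    p_coal: float | None = None


def _complete_sites(aln: SequenceAlignment) -> np.ndarray:
    m = aln.matrix()
    keep = ~np.any((m == "-") | (m == "N"), axis=0)
    return m[:, keep]


def seq_diversity(aln: SequenceAlignment, coal_reps: int = 0,
                  seed: int = 0) -> SeqDiversityResult:
    """Per-locus S, pi, theta_W, Tajima's D for one alignment.

    Sites containing a gap or N in any sequence are excluded entirely
    (complete-site deletion) before counting. With ``coal_reps`` > 0 the
    coalescent-simulation p-value for D (null conditioned on S) is also
    computed and stored in ``p_coal``.
    """
    n = aln.n
    if n < 2:
        raise InsufficientSampleError("sequence diversity needs n >= 2")
    m = _complete_sites(aln)
    npairs = n * (n - 1) / 2.0
    S = 0
    pi_total = 0.0
    for col in m.T:
        vals, cnts = np.unique(col, return_counts=True)
        if len(vals) > 1:
            S += 1
            same = sum(c * (c - 1) / 2.0 for c in cnts)
            pi_total += (npairs - same) / npairs
    theta_w = S / harmonic_number(n - 1) if S else 0.0
    d = tajimas_d(n, S, pi_total)
    p_coal = None
    if coal_reps > 0 and d is not None:
        _, _, p_coal = tajima_coalescent_test(n, S, d, reps=coal_reps, seed=seed)
    return SeqDiversityResult(
        n=n, S=S, pi=pi_total, theta_w=theta_w, tajima_d=d,
        p_beta=tajima_beta_p(n, d) if (d is not None and n >= 4) else None,
        p_coal=p_coal,
    )


def seq_diversity_by_deme(aln: SequenceAlignment) -> pd.DataFrame:
    """Table of per-deme sequence statistics (demes with n >= 2)."""
    rows = []
    for deme in aln.deme_names:
        sub = aln.subset_deme(deme)
        if sub.n < 2:
            continue
        r = seq_diversity(sub)
        rows.append({"deme": deme, "n": r.n, "S": r.S, "pi": r.pi,
                     "theta_w": r.theta_w, "tajima_d": r.tajima_d,
                     "p_beta": r.p_beta})
    return pd.DataFrame(rows)


def tajima_coalescent_test(
    n: int, S: int, observed_d: float, reps: int = 10_000, seed: int = 0
) -> tuple[float, tuple[float, float], float]:
    """Null distribution of D conditioned on S mutations.

    Neutral genealogies of ``n`` tips are simulated and exactly ``S``
    mutations are dropped uniformly on branches (probability proportional to
    branch length); the null is scale-free so the population size cancels.
    Returns (null mean D, central 95% interval, two-sided p). The p-value is
    the add-one fraction of |null D| >= |observed D|.
    """
    if S == 0:
        raise ValidationError("coalescent D test undefined for S = 0")
    if reps < 1000:
        raise ValidationError("use >= 1,000 replicates")
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    c = tajima_constants(n)
    denom_base = c["e1"] * S + c["e2"] * S * (S - 1)
    npairs = n * (n - 1) / 2.0
    ds = np.empty(reps)
    reps_iter = msprime.sim_ancestry(
        n, ploidy=1, population_size=1.0, sequence_length=1,
        num_replicates=reps, random_seed=ms_seed, record_provenance=False,
    )
    for k, ts in enumerate(reps_iter):
        tree = ts.first()
        nodes = np.array([u for u in tree.nodes() if tree.parent(u) != -1])
        blen = np.array([tree.branch_length(u) for u in nodes])
        nleaves = np.array([tree.num_samples(u) for u in nodes])
        probs = blen / blen.sum()
        picks = rng.choice(len(nodes), size=S, p=probs)
        j = nleaves[picks]
        pi = float(np.sum(j * (n - j)) / npairs)
        ds[k] = (pi - S / c["a1"]) / math.sqrt(denom_base)
    lo, hi = np.quantile(ds, [0.025, 0.975])
    p = (int(np.sum(np.abs(ds) >= abs(observed_d))) + 1) / (reps + 1)
    return float(ds.mean()), (float(lo), float(hi)), float(p)


# ---------------------------------------------------------------------------
# Microsatellite diversity
# ---------------------------------------------------------------------------


@dataclass
class MsatDiversityResult:
    """Per-deme summary table; means +/- SE are across loci."""

    table: pd.DataFrame  # one row per deme


def _freqs(gt: GenotypeTable, deme_mask: np.ndarray, locus: int) -> np.ndarray | None:
    copies = gt.genotypes[deme_mask, locus, :].ravel()
    copies = copies[copies != MISSING]
    if copies.size == 0:
        return None
    _, cnts = np.unique(copies, return_counts=True)
    return cnts / cnts.sum()


def msat_diversity(gt: GenotypeTable) -> MsatDiversityResult:
    """Standard per-deme microsatellite diversity panel.

    A private allele is an allele observed in exactly one deme across the
    whole table. Loci with no scored copies in a deme are skipped for that
    deme's means; a deme with zero scored copies at every locus is an error.
    """
    demes = gt.deme_names
    demes_arr = np.asarray(gt.demes)
    # which demes carry each allele, per locus
    carriers: list[dict[int, set[str]]] = []
    for l in range(gt.n_loci):
        d: dict[int, set[str]] = {}
        for deme in demes:
            for a in gt.allele_counts(deme, l):
                d.setdefault(a, set()).add(deme)
        carriers.append(d)
    rows = []
    for deme in demes:
        mask = demes_arr == deme
        na, ne, sh, he, priv = [], [], [], [], []
        n_poly = 0
        for l in range(gt.n_loci):
            p = _freqs(gt, mask, l)
            if p is None:
                continue
            k = len(p)
            na.append(k)
            ne.append(1.0 / np.sum(p**2))
            sh.append(float(-np.sum(p * np.log(p))))
            he.append(float(1.0 - np.sum(p**2)))
            if k > 1:
                n_poly += 1
            own = gt.allele_counts(deme, l)
            priv.append(sum(1 for a in own if carriers[l][a] == {deme}))
        if not na:
            raise ValidationError(f"deme {deme!r} has no scored copies at any locus")
        def mse(x):
            x = np.asarray(x, dtype=float)
            se = x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
            return float(x.mean()), float(se)
        rows.append({
            "deme": deme, "n": int(mask.sum()), "n_polymorphic_loci": n_poly,
            "na_mean": mse(na)[0], "na_se": mse(na)[1],
            "ne_mean": mse(ne)[0], "ne_se": mse(ne)[1],
            "shannon_mean": mse(sh)[0], "shannon_se": mse(sh)[1],
            "private_mean": mse(priv)[0], "private_se": mse(priv)[1],
            "he_mean": mse(he)[0], "he_se": mse(he)[1],
        })
    return MsatDiversityResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Fdist outlier scan
# ---------------------------------------------------------------------------


def _locus_he_fst(freqs_by_deme: list[np.ndarray | None]) -> tuple[float, float] | None:
    """(total He, Nei G_ST) for one locus from per-deme allele-frequency maps.

    ``freqs_by_deme`` holds dicts allele -> frequency; demes without data are
    None. Returns None for loci scored in < 2 demes or monomorphic overall.
    """
    fs = [f for f in freqs_by_deme if f is not None]
    if len(fs) < 2:
        return None
    alleles = sorted(set().union(*[set(f) for f in fs]))
    P = np.array([[f.get(a, 0.0) for a in alleles] for f in fs])
    hs = float(np.mean(1.0 - np.sum(P**2, axis=1)))
    pbar = P.mean(axis=0)
    ht = float(1.0 - np.sum(pbar**2))
    if ht <= 0:
        return None
    return ht, (ht - hs) / ht


def _freq_dict(gt: GenotypeTable, deme: str, locus: int) -> dict[int, float] | None:
    cnts = gt.allele_counts(deme, locus)
    tot = sum(cnts.values())
    if tot == 0:
        return None
    return {a: c / tot for a, c in cnts.items()}


def observed_he_fst(gt: GenotypeTable) -> pd.DataFrame:
    """Per-locus (He, F_ST) across all demes (Nei G_ST)."""
    demes = gt.deme_names
    rows = []
    for l, name in enumerate(gt.loci):
        res = _locus_he_fst([_freq_dict(gt, d, l) for d in demes])
        if res is None:
            rows.append({"locus": name, "he": np.nan, "fst": np.nan})
        else:
            rows.append({"locus": name, "he": res[0], "fst": res[1]})
    return pd.DataFrame(rows)


def _island_sims(
    n_demes: int, samples_per_deme: list[int], mig: float,
    thetas: np.ndarray, seed: int,
) -> np.ndarray:
    """Simulate (He, F_ST) pairs under a finite island model, one locus per
    replicate, SMM mutation with per-locus theta."""
    N = 1000.0
    dem = msprime.Demography()
    for i in range(n_demes):
        dem.add_population(name=f"d{i}", initial_size=N)
    dem.set_symmetric_migration_rate([f"d{i}" for i in range(n_demes)], mig / (4 * N))
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    out = np.full((len(thetas), 2), np.nan)
    reps = msprime.sim_ancestry(
        {f"d{i}": samples_per_deme[i] for i in range(n_demes)},
        demography=dem, ploidy=2, sequence_length=1,
        num_replicates=len(thetas), random_seed=ms_seed,
        record_provenance=False,
    )
    bounds = np.cumsum([0] + [2 * s for s in samples_per_deme])
    for k, ts in enumerate(reps):
        mu = thetas[k] / (4 * N)
        alleles, _ = smm_overlay(ts.first(), mu, rng)
        fs = []
        for i in range(n_demes):
            copies = alleles[bounds[i]:bounds[i + 1]]
            vals, cnts = np.unique(copies, return_counts=True)
            fs.append(dict(zip(vals.tolist(), (cnts / cnts.sum()).tolist())))
        res = _locus_he_fst(fs)
        if res is not None:
            out[k] = res
    return out


def fdist_outlier_test(
    gt: GenotypeTable, reps: int = 10_000, seed: int = 0,
    envelope: tuple[float, float] = (0.025, 0.975), n_bins: int = 20,
) -> pd.DataFrame:
    """Fdist-style outlier scan of per-locus F_ST against He.

    A finite island model (deme count and sample sizes as observed) is
    calibrated so the simulated mean F_ST matches the observed mean, then
    ``reps`` single-locus datasets are simulated with per-locus theta drawn
    log-uniformly to populate the He range. Simulated (He, F_ST) pairs are
    cut into equal-count He bins; within-bin envelope quantiles are smoothed
    by a 3-bin moving average and interpolated at each observed He. Loci
    outside the envelope are flagged high-/low-outlier.
    """
    if reps < 10_000:
        raise ValidationError("Fdist needs >= 10,000 simulations")
    obs = observed_he_fst(gt)
    usable = obs.dropna()
    if usable.empty:
        raise ValidationError("all loci monomorphic: no outlier test possible")
    target = float(usable["fst"].mean())
    target = min(max(target, 1e-3), 0.95)
    d = len(gt.deme_names)
    samples = [len(gt.individuals_in(x)) for x in gt.deme_names]
    rng = np.random.default_rng(seed)
    # calibrate scaled migration 4Nm so simulated mean F_ST matches target
    corr = (d / (d - 1)) ** 2
    mig = (1.0 / target - 1.0) / corr
    for it in range(4):
        thetas = 10 ** rng.uniform(np.log10(0.05), np.log10(20.0), size=2000)
        batch = _island_sims(d, samples, mig, thetas,
                             int(rng.integers(1, 2**31 - 1)))
        got = float(np.nanmean(batch[:, 1]))
        if abs(got - target) < 0.005:
            break
        mig *= (1.0 / target - 1.0) / max(1.0 / got - 1.0, 1e-6)
    thetas = 10 ** rng.uniform(np.log10(0.05), np.log10(20.0), size=reps)
    sims = _island_sims(d, samples, mig, thetas, int(rng.integers(1, 2**31 - 1)))
    sims = sims[~np.isnan(sims[:, 0])]
    order = np.argsort(sims[:, 0])
    sims = sims[order]
    edges = np.array_split(np.arange(len(sims)), n_bins)
    centers, qlo, qhi = [], [], []
    for idx in edges:
        centers.append(float(np.mean(sims[idx, 0])))
        qlo.append(float(np.quantile(sims[idx, 1], envelope[0])))
        qhi.append(float(np.quantile(sims[idx, 1], envelope[1])))
    def smooth(v):
        v = np.asarray(v)
        return np.convolve(np.pad(v, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    qlo, qhi = smooth(qlo), smooth(qhi)
    rows = []
    for _, r in obs.iterrows():
        if not np.isfinite(r["he"]):
            rows.append({**r, "q_low": np.nan, "q_high": np.nan, "flag": "monomorphic"})
            continue
        lo = float(np.interp(r["he"], centers, qlo))
        hi = float(np.interp(r["he"], centers, qhi))
        if r["fst"] > hi:
            flag = "high-outlier"
        elif r["fst"] < lo:
            flag = "low-outlier"
        else:
            flag = "neutral"
        rows.append({"locus": r["locus"], "he": r["he"], "fst": r["fst"],
                     "q_low": lo, "q_high": hi, "flag": flag})
    out = pd.DataFrame(rows)
    out.attrs["calibrated_mean_fst"] = float(np.nanmean(sims[:, 1]))
    out.attrs["target_mean_fst"] = target
    return out
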