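"""Hierarchical AMOVA, Nei pairwise F_ST, and global fixation indices.

The AMOVA is the standard nested decomposition on gene copies with the
allele-identity metric: the squared distance between two gene copies is the
number of loci at which they carry different alleles (loci with a missing
copy in either individual are skipped for that pair). Variance components
use the unequal-sample-size coefficients of the classical three-level
design; negative components are reported as-is, never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    MISSING,
    DistanceMatrix,
    GenotypeTable,
    ValidationError,
)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    table: pd.DataFrame  # stratum rows: df, SS, variance component, % variation
    f_ct: float | None  # among groups
    f_sc: float | None  # among populations within groups
    f_st: float  # among populations relative to total
    p_ct: float | None
    p_sc: float | None
    p_st: float | None


def _copy_matrix(gt: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """(gene copies x loci) allele matrix and the individual index of each copy."""
    n, L = gt.n_individuals, gt.n_loci
    copies = gt.genotypes.transpose(0, 2, 1).reshape(n * 2, L)
    ind_of = np.repeat(np.arange(n), 2)
    return copies, ind_of


def _pairwise_d2(copies: np.ndarray) -> np.ndarray:
    """Squared allele-identity distances between gene copies."""
    N, L = copies.shape
    d2 = np.zeros((N, N))
    for l in range(L):
        col = copies[:, l]
        scored = col != MISSING
        both = np.outer(scored, scored)
        neq = col[:, None] != col[None, :]
        d2 += (neq & both).astype(float)
    return d2


def _block_sums(d2: np.ndarray, labels: np.ndarray, groups: list) -> np.ndarray:
    """B[p, q] = sum of d2 over ordered copy pairs (i in p, j in q)."""
    k = len(groups)
    B = np.zeros((k, k))
    idx = [np.flatnonzero(labels == g) for g in groups]
    for a in range(k):
        for b in range(a, k):
            s = d2[np.ix_(idx[a], idx[b])].sum()
            B[a, b] = B[b, a] = s
    return B


def _amova_components(
    B: np.ndarray, pop_sizes: np.ndarray, group_of_pop: np.ndarray
):
    """Variance components from deme-block pair sums.

    ``B`` is the (pops x pops) matrix of summed squared distances over
    ordered copy pairs; ``pop_sizes`` counts gene copies per pop.
    """
    P = len(pop_sizes)
    groups = np.unique(group_of_pop)
    G = len(groups)
    N = pop_sizes.sum()
    # within-pop, within-group and total pair sums (unordered pairs)
    ss_wp = sum(B[p, p] / 2.0 / pop_sizes[p] for p in range(P))
    ss_wg = 0.0
    Ng = {}
    for g in groups:
        pg = np.flatnonzero(group_of_pop == g)
        Ng[g] = pop_sizes[pg].sum()
        ss_wg += B[np.ix_(pg, pg)].sum() / 2.0 / Ng[g]
    ss_tot = B.sum() / 2.0 / N
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_tot - ss_wg
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp
    sigma_c = ms_wp
    sum_n2_over_Ng = sum(
        (pop_sizes[np.flatnonzero(group_of_pop == g)] ** 2).sum() / Ng[g]
        for g in groups
    )
    sum_n2 = float((pop_sizes**2).sum())
    if df_ap > 0:
        n_prime = (N - sum_n2_over_Ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_n2_over_Ng - sum_n2 / N) / df_ag
        n_tprime = (N - sum(Ng[g] ** 2 for g in groups) / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    return (ss_ag, ss_ap, ss_wp), (df_ag, df_ap, df_wp), (sigma_a, sigma_b, sigma_c)


def amova(
    gt: GenotypeTable,
    grouping: dict[str, str] | None = None,
    perms: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA (among groups / among pops within groups / within pops).

    ``grouping`` maps deme label to group (species); with no grouping (or a
    single group) the among-group stratum is dropped and a two-level AMOVA is
    returned. Permutation p-values (add-one convention), one per F-statistic:

    * F_ST -- individuals permuted among all demes;
    * F_SC -- individuals permuted among demes within their group;
    * F_CT -- demes permuted among groups.
    """
    demes = gt.deme_names
    if len(demes) < 2:
        raise ValidationError("AMOVA needs >= 2 demes")
    if grouping is None:
        grouping = {d: "all" for d in demes}
    missing = [d for d in demes if d not in grouping]
    if missing:
        raise ValidationError(f"grouping lacks demes: {missing}")
    copies, ind_of = _copy_matrix(gt)
    d2 = _pairwise_d2(copies)
    pop_of_copy = np.repeat(np.array([demes.index(d) for d in gt.demes]), 2)
    pop_sizes = np.array([2 * len(gt.individuals_in(d)) for d in demes])
    group_labels = sorted({grouping[d] for d in demes})
    group_of_pop = np.array([group_labels.index(grouping[d]) for d in demes])
    G = len(group_labels)
    two_level = G < 2
    single_deme_groups = [
        g for g in range(G) if (group_of_pop == g).sum() < 2
    ]

    B = _block_sums(d2, pop_of_copy, list(range(len(demes))))
    (ss_ag, ss_ap, ss_wp), (df_ag, df_ap, df_wp), (sa, sb, sc) = _amova_components(
        B, pop_sizes, group_of_pop if not two_level else np.zeros(len(demes), int)
    )
    total = sa + sb + sc
    f_ct = sa / total if not two_level else None
    f_sc = sb / (sb + sc) if not two_level else None
    f_st = (sa + sb) / total

    rng = np.random.default_rng(seed)
    n_ind = gt.n_individuals
    ind_pop = np.array([demes.index(d) for d in gt.demes])

    def stats_for(ind_pop_perm: np.ndarray, gop: np.ndarray):
        pop_copy = np.repeat(ind_pop_perm, 2)
        Bp = _block_sums(d2, pop_copy, list(range(len(demes))))
        sizes = np.array([2 * (ind_pop_perm == p).sum() for p in range(len(demes))])
        _, _, (a, b, c) = _amova_components(Bp, sizes, gop)
        tot = a + b + c
        return a / tot if tot else 0.0, b / (b + c) if (b + c) else 0.0, \
            (a + b) / tot if tot else 0.0

    p_st = p_sc = p_ct = None
    if perms > 0:
        gop0 = group_of_pop if not two_level else np.zeros(len(demes), int)
        # F_ST: individuals among all demes
        cnt = 0
        for _ in range(perms):
            perm = rng.permutation(ind_pop)
            _, _, fst_p = stats_for(perm, gop0)
            cnt += fst_p >= f_st
        p_st = (cnt + 1) / (perms + 1)
        if not two_level:
            # F_SC: individuals among demes within groups
            cnt = 0
            group_of_ind = group_of_pop[ind_pop]
            for _ in range(perms):
                perm = ind_pop.copy()
                for g in range(G):
                    sel = np.flatnonzero(group_of_ind == g)
                    perm[sel] = perm[rng.permutation(sel)]
                _, fsc_p, _ = stats_for(perm, gop0)
                cnt += fsc_p >= f_sc
            p_sc = (cnt + 1) / (perms + 1)
            # F_CT: demes among groups
            cnt = 0
            for _ in range(perms):
                gop = rng.permutation(group_of_pop)
                fct_p, _, _ = stats_for(ind_pop, gop)
                cnt += fct_p >= f_ct
            p_ct = (cnt + 1) / (perms + 1)

    rows = []
    if not two_level:
        rows.append({"source": "among_groups", "df": df_ag, "ss": ss_ag,
                     "sigma2": sa, "pct": 100 * sa / total, "F": f_ct, "p": p_ct})
        rows.append({"source": "among_pops_within_groups", "df": df_ap, "ss": ss_ap,
                     "sigma2": sb, "pct": 100 * sb / total, "F": f_sc, "p": p_sc})
    else:
        rows.append({"source": "among_pops", "df": df_ap, "ss": ss_ap,
                     "sigma2": sb, "pct": 100 * sb / total, "F": None, "p": None})
    rows.append({"source": "within_pops", "df": df_wp, "ss": ss_wp,
                 "sigma2": sc, "pct": 100 * sc / total, "F": f_st, "p": p_st})
    rows.append({"source": "total", "df": df_ag + df_ap + df_wp,
                 "ss": ss_ag + ss_ap + ss_wp, "sigma2": total,
                 "pct": 100.0, "F": None, "p": None})
    res = AmovaResult(pd.DataFrame(rows), f_ct, f_sc, f_st, p_ct, p_sc, p_st)
    if single_deme_groups and not two_level:
        res.table.attrs["warning"] = (
            "group(s) with a single deme: among-group test is weak/ill-defined"
        )
    return res


# ---------------------------------------------------------------------------
# Nei pairwise F_ST and Rousset linearization
# ---------------------------------------------------------------------------


def _pair_gst(gt: GenotypeTable, d1: str, d2_: str) -> float:
    """Nei G_ST for one deme pair, averaged over polymorphic loci."""
    vals = []
    for l in range(gt.n_loci):
        c1, c2 = gt.allele_counts(d1, l), gt.allele_counts(d2_, l)
        t1, t2 = sum(c1.values()), sum(c2.values())
        if t1 == 0 or t2 == 0:
            continue
        alleles = sorted(set(c1) | set(c2))
        p1 = np.array([c1.get(a, 0) / t1 for a in alleles])
        p2 = np.array([c2.get(a, 0) / t2 for a in alleles])
        hs = 1.0 - (np.sum(p1**2) + np.sum(p2**2)) / 2.0
        pbar = (p1 + p2) / 2.0
        ht = 1.0 - np.sum(pbar**2)
        if ht > 0:
            vals.append((ht - hs) / ht)
    if not vals:
        raise ValidationError(
            f"demes {d1!r}/{d2_!r} share no scored polymorphic locus"
        )
    return float(np.mean(vals))


def pairwise_fst_nei(gt: GenotypeTable) -> DistanceMatrix:
    """Pairwise Nei F_ST (G_ST) matrix over demes."""
    demes = gt.deme_names
    if len(demes) < 2:
        raise ValidationError("need >= 2 demes")
    n = len(demes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _pair_gst(gt, demes[i], demes[j])
    return DistanceMatrix(demes, m, kind="fst")


def rousset_linearize(fst: DistanceMatrix, clamp: float = 0.999) -> DistanceMatrix:
    """Elementwise F_ST / (1 - F_ST); entries >= ``clamp`` map to x/(1-clamp)
    evaluated at the clamp (avoids infinities on fixed pairs)."""
    x = fst.values.copy()
    x = np.minimum(x, clamp)
    lin = x / (1.0 - x)
    np.fill_diagonal(lin, 0.0)
    return DistanceMatrix(list(fst.labels), lin, kind="linearized")


# ---------------------------------------------------------------------------
# Global F-statistics
# ---------------------------------------------------------------------------


def global_f_statistics(gt: GenotypeTable) -> tuple[float | None, float | None, float | None]:
    """Nei-style (F_IS, F_ST, F_IT) from H_O, H_S, H_T averaged over loci.

    H_S is the unweighted mean per-deme expected heterozygosity; H_T uses the
    unweighted mean allele frequencies across demes. Returns (None, None,
    None) when every locus is monomorphic (H_T = 0). The algebraic identity
    (1 - F_IT) = (1 - F_IS)(1 - F_ST) holds by construction.
    """
    demes = gt.deme_names
    ho_l, hs_l, ht_l = [], [], []
    for l in range(gt.n_loci):
        freqs = []
        hos = []
        for d in demes:
            idx = gt.individuals_in(d)
            g = gt.genotypes[idx, l, :]
            scored = g[:, 0] != MISSING
            if scored.sum() == 0:
                continue
            g = g[scored]
            hos.append(float(np.mean(g[:, 0] != g[:, 1])))
            copies = g.ravel()
            vals, cnts = np.unique(copies, return_counts=True)
            freqs.append(dict(zip(vals.tolist(), (cnts / cnts.sum()).tolist())))
        if not freqs:
            continue
        alleles = sorted(set().union(*[set(f) for f in freqs]))
        P = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs])
        ho_l.append(float(np.mean(hos)))
        hs_l.append(float(np.mean(1 - np.sum(P**2, axis=1))))
        pbar = P.mean(axis=0)
        ht_l.append(float(1 - np.sum(pbar**2)))
    ho, hs, ht = map(lambda v: float(np.mean(v)), (ho_l, hs_l, ht_l))
    if ht <= 0:
        return None, None, None
    fis = 1 - ho / hs if hs > 0 else None
    fst = 1 - hs / ht
    fit = 1 - ho / ht
    return fis, fst, fit
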