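"""Packaged fixtures and synthetic-data builders.

Two kinds of data ship with the package:

* the nine Taiwanese sampling sites with coordinates, altitude and the six
  retained bioclim variables (a small CSV fixture);
* synthetic genetic data generated at run time -- a cpDNA-style alignment
  whose per-population sample sizes and segregating-site counts match the
  published diversity table (real sequences are in GenBank, not printed), and
  a nine-deme microsatellite panel simulated under a founder-style history
  (six progenitor demes, three recently founded demes, small effective
  sizes, low migration).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .core_data import SequenceAlignment, SiteTable, read_site_table
from .coalsim import Event, ScenarioSpec, SimulatedDataset, simulate_coalescent

#: (sample size, segregating sites) of the cpDNA panel per population
CPDNA_PROFILE = {
    "YH": (14, 1), "CL": (4, 0), "YL": (22, 0), "TC": (9, 0), "XH": (12, 0),
    "WL": (19, 0), "MK": (13, 1), "EG": (39, 1), "DA": (23, 0),
}

#: microsatellite sample sizes (individuals) per population
MSAT_SAMPLE_SIZES = {
    "YH": 12, "CL": 4, "YL": 22, "TC": 9, "XH": 12,
    "WL": 21, "MK": 12, "EG": 40, "DA": 23,
}

BAR_DEMES = ("YH", "CL", "YL", "TC", "XH", "WL")
TPE_DEMES = ("MK", "DA", "EG")

SPECIES_OF = {**{d: "bar" for d in BAR_DEMES}, **{d: "tpe" for d in TPE_DEMES}}


def taiwan_sites() -> list[SiteTable]:
    """The nine sampling sites with six bioclim variables."""
    path = resources.files("scutpop.data") / "taiwan_sites.csv"
    with resources.as_file(path) as p:
        return read_site_table(p)


def synthetic_cpdna_alignment(length: int = 500, seed: int = 0) -> SequenceAlignment:
    """Synthetic haploid alignment shaped to the observed cpDNA panel.

    Sample sizes per population and the segregating-site counts (one
    singleton in YH, MK and EG; all other populations monomorphic) match the
    published diversity table; the sequences themselves are synthetic (the
    real ones are deposited in GenBank and not printed). Within-population
    statistics (S, pi, theta_W, Tajima's D) therefore reproduce the table.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=length)
    ids, demes, seqs = [], [], []
    mut_sites = iter(rng.choice(length, size=len(CPDNA_PROFILE), replace=False))
    for deme, (n, S) in CPDNA_PROFILE.items():
        site = next(mut_sites)
        for i in range(n):
            seq = backbone.copy()
            if S == 1 and i == 0:  # one singleton carrier per polymorphic deme
                seq[site] = (seq[site] + 1) % 4
            ids.append(f"{deme}_{i + 1}")
            demes.append(deme)
            seqs.append("".join(bases[seq]))
    return SequenceAlignment(ids, demes, seqs)


def scenario_taiwan_panel(
    m: float = 5e-4,
    mu: float = 5.274e-4,
    n_msat_loci: int = 11,
    n_seq_loci: int = 2,
) -> ScenarioSpec:
    """Nine-deme founder-style history emulating the sampled panel.

    Six small progenitor (*bar*) demes diverge 2,000-11,145 generations ago
    from the YH lineage (the species' estimated island coalescent time);
    three *tpe* demes are founded more recently (95-5,537 generations) with
    small effective sizes (N_T < 100); migration is low (m < 0.01) and the
    root lineage carries the bottleneck-plus-recovery history (N_A = 597 ->
    N_B' = 199). Under these defaults the simulated panel shows the small
    within-population diversity (mean He ~ 0.25) and strong differentiation
    characteristic of the sampled populations.
    """
    demes = {
        "YH": 100, "CL": 60, "YL": 90, "TC": 70, "XH": 80, "WL": 85,
        "MK": 40, "DA": 50, "EG": 60,
    }
    events = [
        Event(95, "split", {"derived": ["MK"], "ancestral": "YH"}),
        Event(900, "split", {"derived": ["DA"], "ancestral": "YH"}),
        Event(5537, "split", {"derived": ["EG"], "ancestral": "WL"}),
        Event(2000, "split", {"derived": ["CL"], "ancestral": "YH"}),
        Event(3500, "split", {"derived": ["TC"], "ancestral": "YH"}),
        Event(5000, "split", {"derived": ["YL"], "ancestral": "YH"}),
        Event(8000, "split", {"derived": ["WL"], "ancestral": "YH"}),
        Event(11145, "split", {"derived": ["XH"], "ancestral": "YH"}),
        Event(5572, "size_change", {"deme": "YH", "size": 199}),
        Event(11145, "size_change", {"deme": "YH", "size": 597}),
    ]
    return ScenarioSpec(
        "taiwan_panel", demes, events, migration=m,
        n_msat_loci=n_msat_loci, mu=mu,
        n_seq_loci=n_seq_loci, mu_seq=2e-4,
    )


def example_dataset(seed: int = 1) -> SimulatedDataset:
    """A complete nine-population synthetic dataset (genotypes + sequences)
    with the observed per-population sample sizes."""
    spec = scenario_taiwan_panel()
    seq_sizes = {d: n for d, (n, _) in CPDNA_PROFILE.items()}
    return simulate_coalescent(spec, MSAT_SAMPLE_SIZES, seed, seq_sizes)
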