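"""Structured-coalescent simulation under the four demographic scenarios.

Genealogies are drawn with msprime (structured coalescent with population
splits, size changes and symmetric migration). Mutations are overlaid on the
genealogies as:

* microsatellites -- strict stepwise mutation model (SMM): Poisson(mu * branch
  length) mutations per branch, each a +/-1 step with equal probability, from
  a root repeat score of 100 (keeps alleles inside the 3-digit GenePop range
  for realistic mutation loads);
* haploid sequence loci -- infinite sites (msprime ``sim_mutations`` on a
  continuous genome, binary model), rendered into an A/C/G/T alignment.

The four scenario builders encode the competing histories of the widespread
progenitor (*bar*) and the putative island endemic (*tpe*):

1. secondary contact -- old split into two species, independent bottlenecks,
   gene flow only since a recent onset time;
2. founder -- *tpe* founded from *bar* recently (T2) while *bar* itself went
   through a colonization bottleneck (N_A -> N_B' -> N_B) ending at T1;
3. multiple origins -- three *tpe* demes founded independently from *bar*;
4. single origin -- one founding of a *tpe* ancestor followed by within-*tpe*
   splits (monophyly of *tpe*).

This module doubles as the repository's synthetic-data generator: simulated
datasets are ordinary :class:`~scutpop.core_data.GenotypeTable` /
:class:`~scutpop.core_data.SequenceAlignment` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from .core_data import (
    GenotypeTable,
    SequenceAlignment,
    ValidationError,
)

ROOT_ALLELE = 100
SAMPLE_SIZE_CAP = 10_000

_BASES = np.array(list("ACGT"))


@dataclass
class Event:
    """A demographic event, time in generations backward from the present."""

    time: float
    kind: str  # "size_change" | "split" | "migration_change"
    params: dict


@dataclass
class ScenarioSpec:
    """A demographic history plus its mutation configuration.

    ``demes`` maps deme label to present-day effective size (diploid
    individuals). ``migration`` is the symmetric backward migration rate per
    pair of coexisting demes. ``mu`` is the per-locus per-generation
    microsatellite mutation rate; sequence loci use ``mu_seq`` per locus.
    """

    name: str
    demes: dict[str, float]
    events: list[Event]
    migration: float = 0.0
    n_msat_loci: int = 11
    mu: float = 5e-4
    n_seq_loci: int = 0
    mu_seq: float = 5e-4
    seq_length: int = 500

    def __post_init__(self) -> None:
        if not self.demes:
            raise ValidationError("scenario needs >=1 deme")
        if any(s < 1 for s in self.demes.values()):
            raise ValidationError("all deme sizes must be >= 1")
        if not 0.0 <= self.migration <= 1.0:
            raise ValidationError("migration rate must be in [0, 1]")
        if self.mu <= 0 or self.mu_seq <= 0:
            raise ValidationError("mutation rates must be positive")
        times = [e.time for e in self.events]
        if any(t <= 0 for t in times):
            raise ValidationError("event times must be positive")
        if sorted(times) != times:
            self.events = sorted(self.events, key=lambda e: e.time)
        for e in self.events:
            if e.kind not in ("size_change", "split", "migration_change"):
                raise ValidationError(f"unknown event kind {e.kind!r}")
        if len(self.demes) > 1:
            merged = set()
            for e in self.events:
                if e.kind == "split":
                    merged.update(e.params["derived"])
            unmerged = set(self.demes) - merged
            if len(unmerged) != 1:
                raise ValidationError(
                    "all demes but one ancestral lineage must merge by the "
                    f"largest event time (unmerged: {sorted(unmerged)})"
                )

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name, size in self.demes.items():
            dem.add_population(name=name, initial_size=size)
        if self.migration > 0 and len(self.demes) > 1:
            dem.set_symmetric_migration_rate(list(self.demes), self.migration)
        for e in self.events:
            if e.kind == "size_change":
                dem.add_population_parameters_change(
                    time=e.time,
                    population=e.params["deme"],
                    initial_size=e.params["size"],
                )
            elif e.kind == "split":
                # classic ms-style merge: move all lineages of the derived
                # deme(s) into the ancestor and stop migration involving the
                # emptied deme(s); demes are never deactivated, which keeps
                # arbitrary merge orders valid
                for d in e.params["derived"]:
                    dem.add_mass_migration(
                        time=e.time, source=d, dest=e.params["ancestral"],
                        proportion=1.0,
                    )
                    if self.migration > 0:
                        for other in self.demes:
                            if other != d:
                                dem.add_migration_rate_change(
                                    time=e.time, rate=0.0, source=d, dest=other
                                )
                                dem.add_migration_rate_change(
                                    time=e.time, rate=0.0, source=other, dest=d
                                )
            elif e.kind == "migration_change":
                dem.add_migration_rate_change(time=e.time, rate=e.params["rate"])
        dem.sort_events()
        return dem

    def to_json(self) -> str:
        import json

        return json.dumps({
            "name": self.name,
            "demes": self.demes,
            "events": [{"time": e.time, "kind": e.kind, "params": e.params}
                       for e in self.events],
            "migration": self.migration,
            "n_msat_loci": self.n_msat_loci,
            "mu": self.mu,
            "n_seq_loci": self.n_seq_loci,
            "mu_seq": self.mu_seq,
            "seq_length": self.seq_length,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        import json

        d = json.loads(text)
        events = [Event(e["time"], e["kind"], e["params"])
                  for e in d.pop("events")]
        return cls(events=events, **d)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeTable
    sequences: SequenceAlignment | None
    seed: int
    scenario: ScenarioSpec
    msat_mutation_counts: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------


def scenario_secondary_contact(
    *,
    n_anc: float,
    n_bar: float,
    n_bar_bottleneck: float,
    t_bar_bottleneck: float,
    n_tpe: float,
    n_tpe_bottleneck: float,
    t_tpe_bottleneck: float,
    t_divergence: float,
    t_migration_onset: float,
    m: float,
    mu: float = 5e-4,
    **loci_cfg,
) -> ScenarioSpec:
    """Old species split with per-species bottlenecks and recent gene flow.

    Backward in time: migration ``m`` is active on [0, t_migration_onset);
    each species drops to its bottleneck size at t_*_bottleneck and both merge
    into the ancestor (size ``n_anc``) at ``t_divergence``.
    """
    if t_migration_onset >= t_divergence:
        raise ValidationError("migration onset must be more recent than divergence")
    if not (0 < t_bar_bottleneck < t_divergence and 0 < t_tpe_bottleneck < t_divergence):
        raise ValidationError("bottleneck times must lie inside (0, t_divergence)")
    events = [
        Event(t_migration_onset, "migration_change", {"rate": 0.0}),
        Event(t_bar_bottleneck, "size_change", {"deme": "bar", "size": n_bar_bottleneck}),
        Event(t_tpe_bottleneck, "size_change", {"deme": "tpe", "size": n_tpe_bottleneck}),
        Event(t_divergence, "split", {"derived": ["tpe"], "ancestral": "bar"}),
        Event(t_divergence, "size_change", {"deme": "bar", "size": n_anc}),
    ]
    return ScenarioSpec(
        "secondary_contact",
        {"bar": n_bar, "tpe": n_tpe},
        events,
        migration=m,
        mu=mu,
        **loci_cfg,
    )


def scenario_founder(
    *,
    n_anc: float,
    n_bar_bottleneck: float,
    n_bar: float,
    n_tpe: float,
    t1: float,
    t2: float,
    m: float,
    mu: float = 5e-4,
    recovery_fraction: float = 0.5,
    **loci_cfg,
) -> ScenarioSpec:
    """Recent founder origin of *tpe* from *bar* with continuous gene flow.

    *bar* history (forward): N_A -> bottleneck N_B' at colonization (T1) ->
    recovery to N_B at ``recovery_fraction * t1`` before the present. *tpe*
    is founded from *bar* at T2 < T1 with size N_T; symmetric migration ``m``
    runs from the founding to the present.
    """
    if t2 >= t1:
        raise ValidationError("founding time t2 must be more recent than t1")
    if not 0.0 < recovery_fraction < 1.0:
        raise ValidationError("recovery_fraction must be in (0, 1)")
    t_recovery = recovery_fraction * t1
    events = [
        Event(t2, "split", {"derived": ["tpe"], "ancestral": "bar"}),
        Event(t_recovery, "size_change", {"deme": "bar", "size": n_bar_bottleneck}),
        Event(t1, "size_change", {"deme": "bar", "size": n_anc}),
    ]
    return ScenarioSpec(
        "founder",
        {"bar": n_bar, "tpe": n_tpe},
        events,
        migration=m,
        mu=mu,
        **loci_cfg,
    )


def scenario_multiple_origins(
    *,
    n_bar: float,
    n_tpe: tuple[float, float, float],
    t_founding: tuple[float, float, float],
    m: float,
    mu: float = 5e-4,
    **loci_cfg,
) -> ScenarioSpec:
    """Three *tpe* demes founded independently from *bar* (polyphyly)."""
    if len(n_tpe) != 3 or len(t_founding) != 3:
        raise ValidationError("multiple-origins scenario needs three tpe demes")
    demes = {"bar": n_bar, "tpe1": n_tpe[0], "tpe2": n_tpe[1], "tpe3": n_tpe[2]}
    events = [
        Event(t, "split", {"derived": [f"tpe{i + 1}"], "ancestral": "bar"})
        for i, t in enumerate(t_founding)
    ]
    return ScenarioSpec(
        "multiple_origins", demes, events, migration=m, mu=mu, **loci_cfg
    )


def scenario_single_origin(
    *,
    n_bar: float,
    n_tpe: tuple[float, float, float],
    t_founding: float,
    t_splits: tuple[float, float],
    m: float,
    mu: float = 5e-4,
    **loci_cfg,
) -> ScenarioSpec:
    """One founding of a *tpe* ancestor (carried by deme tpe1), then two
    within-*tpe* splits (monophyly of *tpe*)."""
    if len(n_tpe) != 3 or len(t_splits) != 2:
        raise ValidationError("single-origin scenario needs three tpe demes, two splits")
    if any(t >= t_founding for t in t_splits):
        raise ValidationError("within-tpe split times must be more recent than founding")
    demes = {"bar": n_bar, "tpe1": n_tpe[0], "tpe2": n_tpe[1], "tpe3": n_tpe[2]}
    events = [
        Event(t_splits[0], "split", {"derived": ["tpe2"], "ancestral": "tpe1"}),
        Event(t_splits[1], "split", {"derived": ["tpe3"], "ancestral": "tpe1"}),
        Event(t_founding, "split", {"derived": ["tpe1"], "ancestral": "bar"}),
    ]
    return ScenarioSpec("single_origin", demes, events, migration=m, mu=mu, **loci_cfg)


# ---------------------------------------------------------------------------
# Mutation overlays
# ---------------------------------------------------------------------------


def smm_overlay(tree: tskit.Tree, mu: float, rng: np.random.Generator,
                root_allele: int = ROOT_ALLELE) -> tuple[np.ndarray, int]:
    """Drop strict-SMM mutations on one genealogy.

    Per branch the mutation count is Poisson(mu * branch length); the net
    displacement of k equiprobable +/-1 steps is 2*Binomial(k, 1/2) - k.
    Returns (allele per sample node, total mutation count) -- the count is the
    instrumentation hook for the Poisson/branch-length invariant.
    """
    ts = tree.tree_sequence
    parent = tree.parent_array
    times = ts.tables.nodes.time
    order = tree.preorder()  # roots first, parents before children
    par = parent[order]
    has_parent = par != tskit.NULL
    blen = np.where(has_parent, times[par] - times[order], 0.0)
    counts = rng.poisson(mu * blen)
    steps = np.where(counts > 0, 2 * rng.binomial(counts, 0.5) - counts, 0)
    alleles = np.zeros(ts.num_nodes, dtype=np.int64)
    for i in range(len(order)):
        u = order[i]
        p = par[i]
        alleles[u] = root_allele + steps[i] if p == tskit.NULL else alleles[p] + steps[i]
    out = alleles[ts.samples()]
    if (out <= 0).any():
        # extreme mutation loads can walk below 1; reflect at 1
        out = np.abs(out - 1) + 1
    return out, int(counts.sum())


def _seq_overlay(ts: tskit.TreeSequence, mu: float, length: int,
                 rng: np.random.Generator) -> list[str]:
    """Infinite-sites sequence mutations rendered as an A/C/G/T alignment."""
    seed = int(rng.integers(1, 2**31 - 1))
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed,
    )
    S = mts.num_sites
    if S > length:
        raise ValidationError(
            f"{S} segregating sites exceed sequence length {length}"
        )
    n = mts.num_samples
    anc = rng.integers(0, 4, size=length)
    seqs = np.tile(_BASES[anc], (n, 1))
    if S > 0:
        positions = rng.choice(length, size=S, replace=False)
        G = mts.genotype_matrix()  # (S, n)
        for s in range(S):
            derived = (anc[positions[s]] + int(rng.integers(1, 4))) % 4
            carriers = G[s] > 0
            seqs[carriers, positions[s]] = _BASES[derived]
    return ["".join(row) for row in seqs]


# ---------------------------------------------------------------------------
# Simulation front ends
# ---------------------------------------------------------------------------


def _check_samples(spec: ScenarioSpec, sample_sizes: dict[str, int]) -> None:
    for deme, n in sample_sizes.items():
        if deme not in spec.demes:
            raise ValidationError(f"unknown deme {deme!r}")
        if n < 1:
            raise ValidationError("sample sizes must be >= 1")
        if n > SAMPLE_SIZE_CAP:
            raise ValidationError(f"sample size {n} exceeds cap {SAMPLE_SIZE_CAP}")


def simulate_msat_arrays(
    spec: ScenarioSpec, sample_sizes: dict[str, int], seed: int
) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
    """Fast path: simulate microsatellite alleles without container overhead.

    Returns (alleles (n_loci, n_ind, 2), deme index per individual, deme
    names, per-locus mutation counts). Deterministic for a fixed seed.
    """
    _check_samples(spec, sample_sizes)
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    demes = [d for d in spec.demes if sample_sizes.get(d, 0) > 0]
    n_ind = sum(sample_sizes[d] for d in demes)
    deme_idx = np.repeat(np.arange(len(demes)), [sample_sizes[d] for d in demes])
    alleles = np.empty((spec.n_msat_loci, n_ind, 2), dtype=np.int64)
    counts: list[int] = []
    reps = msprime.sim_ancestry(
        {d: sample_sizes[d] for d in demes},
        demography=spec.to_demography(),
        ploidy=2,
        sequence_length=1,
        num_replicates=spec.n_msat_loci,
        random_seed=ms_seed,
        record_provenance=False,
    )
    for l, ts in enumerate(reps):
        out, c = smm_overlay(ts.first(), spec.mu, rng)
        alleles[l] = out.reshape(n_ind, 2)
        counts.append(c)
    return alleles, deme_idx, demes, counts


def simulate_coalescent(
    spec: ScenarioSpec,
    sample_sizes: dict[str, int],
    seed: int,
    seq_sample_sizes: dict[str, int] | None = None,
) -> SimulatedDataset:
    """Simulate a full dataset (GenotypeTable + optional SequenceAlignment).

    ``sample_sizes`` are diploid individuals per deme for microsatellites;
    ``seq_sample_sizes`` (defaulting to the same numbers) are haploid
    sequences per deme for the cpDNA-style loci.
    """
    alleles, deme_idx, demes, counts = simulate_msat_arrays(spec, sample_sizes, seed)
    ids = []
    deme_labels = []
    for k, d in enumerate(demes):
        n = int((deme_idx == k).sum())
        ids.extend(f"{d}_{i + 1}" for i in range(n))
        deme_labels.extend([d] * n)
    gt = GenotypeTable(
        ids,
        deme_labels,
        [f"msat{l + 1}" for l in range(spec.n_msat_loci)],
        np.transpose(alleles, (1, 0, 2)),
    )
    aln = None
    if spec.n_seq_loci > 0:
        rng = np.random.default_rng((seed, 977))
        ms_seed = int(rng.integers(1, 2**31 - 1))
        sss = seq_sample_sizes or sample_sizes
        _check_samples(spec, sss)
        sdemes = [d for d in spec.demes if sss.get(d, 0) > 0]
        segments: list[list[str]] = []
        reps = msprime.sim_ancestry(
            {d: sss[d] for d in sdemes},
            demography=spec.to_demography(),
            ploidy=1,
            sequence_length=1,
            num_replicates=spec.n_seq_loci,
            random_seed=ms_seed,
            record_provenance=False,
        )
        for ts in reps:
            segments.append(_seq_overlay(ts, spec.mu_seq, spec.seq_length, rng))
        n_seq = len(segments[0])
        seqs = ["".join(seg[i] for seg in segments) for i in range(n_seq)]
        sids, sdeme_labels = [], []
        for d in sdemes:
            sids.extend(f"{d}_{i + 1}" for i in range(sss[d]))
            sdeme_labels.extend([d] * sss[d])
        aln = SequenceAlignment(sids, sdeme_labels, seqs)
    return SimulatedDataset(gt, aln, seed, spec, counts)
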