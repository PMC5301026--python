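# scutpop

Population- and landscape-genetic analysis of two insular *Scutellaria*
taxa — the widespread *S. barbata* ("bar") and the putative Taipei-Basin
endemic *S. taipeiensis* ("tpe") — as one tested pipeline. The scientific
question is whether the endemic is a distinct species or a set of recent
founder populations of the progenitor, and how much of the population
genetic structure local climate explains.

The package is aimed at population geneticists and landscape geneticists
who want the full analysis chain runnable and testable end to end:

- **Diversity and neutrality** — per-population S, nucleotide diversity π
  (mean pairwise differences per locus), Watterson's θ_W = S/a_{n−1},
  Tajima's D with a beta-approximation p and a coalescent null conditioned
  on S; the standard microsatellite panel (alleles, effective alleles,
  Shannon's I, private alleles, H_e = 1 − Σp²); an Fdist-style F_ST-outlier
  scan against a calibrated island-model envelope.
- **Structure** — three-level AMOVA on gene copies (allele-identity
  distance, negative components reported un-truncated), Nei pairwise G_ST,
  Rousset's linearization F_ST/(1 − F_ST), global F_IS/F_ST/F_IT.
- **Demographic inference** — a structured-coalescent simulator (msprime
  genealogies, strict ±1 stepwise mutations for microsatellites, infinite
  sites for cpDNA-style loci) under four competing scenarios: secondary
  contact, founder speciation, multiple origins, single origin; ABC with
  MAD-standardized rejection, optional PLS, GLM-adjusted marginal
  densities, posterior model probabilities p_i = d_i/Σd_j and Bayes factors
  BF_ij = d_i/d_j, and KDE posterior parameter summaries.
- **Climate–genetics association** — 3-D geographic and bioclim
  environmental distances, Spearman Mantel/partial Mantel/MMRR with
  permutation tests, VIF-based climate-variable pruning, climate PCA, and
  partial dbRDA of genetic PCoA components on climate conditioned on
  geography.

A built-in generator ships the nine sampling sites (coordinates plus
bio2/bio8/bio9/bio13/bio18/bio19) and produces synthetic genetic data
shaped to the study system, so everything runs offline.

## Worked example

```python
import scutpop
from scutpop import datasets

# per-population cpDNA statistics on the packaged synthetic alignment
aln = datasets.synthetic_cpdna_alignment()
print(scutpop.seq_diversity_by_deme(aln).round(3).to_string(index=False))

# a nine-population synthetic microsatellite panel + AMOVA by species
ds = datasets.example_dataset(seed=1)
grouping = {d: datasets.SPECIES_OF[d] for d in ds.genotypes.deme_names}
res = scutpop.amova(ds.genotypes, grouping, perms=999, seed=2)
print(res.table.round(3).to_string(index=False))

# posterior model probabilities from two marginal densities
mc = scutpop.model_posterior({"secondary_contact": 9.24e-13,
                              "founder": 4.63e-10})
```

This prints (abridged):

```
deme  n  S    pi  theta_w  tajima_d  p_beta
  YH 14  1 0.143    0.314    -1.155   0.269
  MK 13  1 0.154    0.322    -1.149   0.274
  EG 39  1 0.051    0.237    -1.126   0.271
...
                  source  df      ss  sigma2     pct     F     p
            among_groups   1  60.004   0.042   1.633 0.016 0.290
among_pops_within_groups   7 249.550   1.107  43.407 0.441 0.001
             within_pops 301 421.756   1.401  54.960 0.450 0.001
                   total 309 731.310   2.549 100.000
```

Reading the output: the three polymorphic populations each carry a single
singleton site, giving small π, θ_W ≈ 0.24–0.32 and mildly negative
Tajima's D (excess rare variation, consistent with recent founding or
growth). The AMOVA on the synthetic panel shows what the real system
shows qualitatively: essentially no variation between the two nominal
species (1.6%, p = 0.29) but strong differentiation among populations
(43%, p = 0.001) — population structure without species-level divergence.
The model comparison turns the two printed marginal densities into
posterior probabilities 0.199% (secondary contact) vs 99.801% (founder).

A thin CLI wraps the same functions:

```bash
scutpop simulate --scenario taiwan_panel --seed 7 --out sim/
scutpop diversity --genepop sim/genotypes.gen --fasta sim/sequences.fasta
scutpop amova --genepop sim/genotypes.gen --perms 9999 --seed 1
scutpop mantel --genepop sim/genotypes.gen --sites sites.csv --perms 9999 --seed 2
scutpop dbrda  --genepop sim/genotypes.gen --sites sites.csv --perms 999 --seed 3
scutpop abc    --observed sim/genotypes.gen --sims 10000 --retain 500 --seed 4 --out abc/
```

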