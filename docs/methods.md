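# Methods

`scutpop` reimplements, as one tested pipeline, the population- and
landscape-genetic analysis of two insular *Scutellaria* taxa: the widespread
progenitor *S. barbata* ("bar") and the putative Taipei-Basin endemic
*S. taipeiensis* ("tpe"). The pipeline spans diversity and neutrality
statistics, hierarchical AMOVA, an F_ST-outlier scan, coalescent simulation
under four competing demographic scenarios, ABC model choice with
GLM-adjusted marginal densities, and a climate–genetics association layer
(Mantel/partial Mantel/MMRR, VIF pruning, climate PCA, partial dbRDA). A
built-in coalescent generator supplies synthetic data so every stage runs
with no downloads.

## Containers and conventions

Microsatellite genotypes are diploid integer repeat scores (GenePop 2- or
3-digit dialects; `0` is the missing marker, and both copies of a genotype
are missing together). Statistics use pairwise deletion: a locus missing in
an individual is skipped for that individual only. Haploid cpDNA-style
sequences are equal-length strings over `{A,C,G,T,-,N}`; sites containing a
gap or `N` in any sequence are removed entirely (complete-site deletion)
before counting. Distance matrices are label-ordered and symmetric with a
zero diagonal; only Rousset-linearized matrices may carry negative entries
(inherited from negative F_ST estimates). The strict upper triangle is
unfolded row-major (`numpy.triu_indices` order) and refolds exactly.

## Sequence statistics

π is the mean number of pairwise differences per locus (not per site), the
convention used for short organellar fragments; θ_W = S / a_{n−1} with
a_k = Σ_{i≤k} 1/i; Tajima's D uses the standard constants
(a1, a2, b1, b2, c1, c2, e1, e2). D is undefined (reported as null) when
S = 0 or when its variance constants vanish (n < 4 with S = 1). Two
p-values are offered: the scaled-beta approximation (undefined for n < 4)
and a coalescent null conditioned on S — neutral genealogies of n tips with
exactly S mutations dropped on branches with probability proportional to
branch length; the timescale cancels, so the null is scale-free. The
conditional null's mean D is slightly negative at small n, which the test
suite checks as a sign property. The coalescent p is the add-one two-sided
fraction |D_null| ≥ |D_obs|.

## Microsatellite statistics

Per deme and locus, from non-missing gene copies: number of alleles,
effective alleles 1/Σp², Shannon's index −Σp ln p, expected heterozygosity
H_e = 1 − Σp² (uncorrected; the bias-corrected variant is not used because
the published table cannot discriminate the two), and private alleles
(alleles observed in exactly one deme across the whole table). Means ±
standard errors are across loci.

Global fixation indices are Nei-style: H_O (observed heterozygote fraction),
H_S (mean within-deme 1 − Σp²), H_T (from unweighted mean allele frequencies
across demes), each averaged over loci, giving F_IS = 1 − H_O/H_S,
F_ST = 1 − H_S/H_T, F_IT = 1 − H_O/H_T; the identity
(1 − F_IT) = (1 − F_IS)(1 − F_ST) holds to machine precision by
construction. Pairwise genetic distance is Nei's G_ST per deme pair averaged
over polymorphic loci, linearized as F_ST/(1 − F_ST) for the
isolation-by-distance layer; entries ≥ 0.999 are clamped (linearized value
≈ 999) to avoid infinities on fixed pairs.

## AMOVA

Three-level decomposition on gene copies (among species, among populations
within species, within populations) with the allele-identity metric: the
squared distance between two gene copies is the number of loci at which they
differ (repeat-size-squared R_ST-style distances are a documented
alternative, not the default, since the original analysis mode is
unstated). Degrees of freedom follow gene-copy accounting (total = 2·N_ind −
1). Variance components use the classical unequal-sample-size coefficients;
negative components are reported as-is — the study system itself prints a
negative among-species component, which is diagnostic of grouping that cuts
across the real structure. Permutation tests (add-one convention, 10,000
default): individuals among all demes for F_ST, individuals among demes
within groups for F_SC, whole demes among groups for F_CT. The test suite
verifies the sums of squares against an independent coordinate-space oracle
(one-hot allele encodings; identity distance equals half the squared
Euclidean distance between encodings).

## Coalescent simulator

Genealogies are drawn with msprime's structured coalescent; a
`ScenarioSpec` (deme sizes, time-ordered size changes and merges, a
symmetric migration rate, mutation configuration) compiles to an msprime
`Demography`. Merges use classic mass-migration semantics (all lineages of
the derived deme move to the ancestor; migration involving the emptied deme
stops at the same instant), which keeps arbitrary merge orders valid.

Time is in generations. Population sizes are diploid individuals:
autosomal microsatellites are simulated with two gene copies per individual
(pairwise coalescence rate 1/(2N), θ = 4Nμ), haploid organellar loci with
one copy per individual (rate 1/N, θ = 2Nμ). Microsatellite mutation is a
strict stepwise model implemented as an overlay on the genealogy: each
branch receives Poisson(μ · length) mutations, each an equiprobable ±1 step
from a root repeat score of 100 (no range constraint; the root value keeps
alleles in the 3-digit GenePop range at realistic mutation loads). The
overlay exposes the realized mutation count, which the tests use to verify
the Poisson/branch-length relationship. Sequence loci use msprime's
infinite-sites mutations (continuous genome, binary model), rendered into an
A/C/G/T alignment with one new site per mutation. Closed-form checks:
E[S] = θ·a_{n−1} under infinite sites and E[H_e] = 1 − 1/√(1 + 2θ) at SMM
equilibrium, both within Monte-Carlo tolerance at 2,000 replicates.

The four demographic scenarios:

1. **Secondary contact** — old species split, independent bottlenecks in
   each species, migration active only more recently than an onset time
   (onset ≥ divergence is rejected).
2. **Founder** — *bar* runs N_A → bottleneck N_B′ → recovery N_B; *tpe* is
   founded from *bar* at T2 < T1 with size N_T and continuous symmetric
   migration since. The source estimates include no bottleneck-recovery time, so the
   recovery is placed at `recovery_fraction · T1` (default 0.5) — a package
   design choice, exposed as a parameter.
3. **Multiple origins** — three *tpe* demes founded independently from
   *bar* at free times (polyphyly).
4. **Single origin** — one founding of a *tpe* ancestor followed by two
   within-*tpe* splits, all more recent than the founding (monophyly).

## ABC

Summary statistics per dataset: per-deme mean allele number, per-deme H_e,
global F_IS/F_ST/F_IT, every pairwise F_ST (plus their mean), total allele
count and mean variance of allele size. The per-pair F_ST entries carry the
topology signal that separates single- from multiple-origin histories; with
only the mean, the two scenarios are nearly indistinguishable at desk
scale. Monomorphic datasets are kept with F-statistics null-coded as 0 and
flagged.

Priors are broad log-uniform envelopes (sizes 10–10⁴, times 1–10⁵
generations, migration 10⁻⁵–10⁻¹, mutation rate 10⁻⁵–10⁻³ per locus per
generation); ordering constraints (T2 < T1; within-*tpe* splits more recent
than the founding) are enforced by rejection at draw time. These envelopes
contain the published 95% credible intervals; the original priors are not
printed, so this is an explicit modelling assumption.

Rejection retains the k simulations nearest the observed vector in
Euclidean distance after dividing each summary by its simulation-wide median
absolute deviation (robust to the heavy-tailed summaries; columns with zero
MAD are dropped); ties break by simulation index, making the retained set
deterministic. An optional PLS reduction (sklearn, standardized inputs,
default k = 5, off by default because the summary set is small) can be
fitted on simulations and reused on the observed vector.

Model evidence follows the ABC-GLM idea: on the retained set, summaries are
regressed linearly on log₁₀-parameters with a multivariate-normal residual;
the marginal density is the fitted mixture evaluated at the observed vector,
averaged over retained parameter draws. Singular residual covariances are
ridge-regularized (escalating ε until the Cholesky succeeds). On a conjugate
1-D Gaussian toy with full retention this estimator matches the analytic
evidence within a few percent (the test asserts 10%). Posterior model
probabilities normalize the densities under equal model weights; Bayes
factors are density ratios and multiply transitively. Posterior parameter
summaries are Gaussian-KDE modes plus equal-tailed 2.5–97.5% intervals.

Default simulation budget is 10,000 draws per scenario with 500 retained —
a deliberate desk-scale reduction of the original 10⁶/5,000 workflow; flags
restore any scale. At this scale the test suite demonstrates (i) scenario
recovery: pseudo-observed data generated under the multiple-origins history
at the published point estimates is assigned the highest posterior to that
scenario in ≥ 70% of 30 replicates, and (ii) parameter-recovery coverage:
the 95% interval for N_T covers the prior-drawn truth in ≥ 90% of 50
founder-scenario replicates. Reference tables are simulated once and shared
across replicates; this changes nothing statistically because each table is
an i.i.d. prior sample.

## Fdist outlier scan

Per locus the observed (H_e, F_ST) pair (Nei G_ST across all demes) is
compared with a null envelope from a finite island model with the observed
deme count and sample sizes. The scaled migration rate is calibrated
iteratively so the simulated mean F_ST matches the observed mean (within
0.005, with the 1/(1 + 4Nm(d/(d−1))²) relation as the starting point);
per-locus θ is drawn log-uniformly on [0.05, 20] to populate the H_e range.
Simulated pairs are cut into 20 equal-count H_e bins; the 2.5% and 97.5%
within-bin F_ST quantiles are smoothed with a 3-bin moving average and
interpolated at each observed H_e. On data simulated wholly under the
island model the envelope flags ≈ 5% (±2%) of loci, which the acceptance
suite verifies on a 200-locus dataset. No multiple-testing correction is
applied to the per-locus flags (none was applied in the original analysis).

## Distance matrices and matrix tests

Geographic distance is 3-D. The default `projected` mode converts
latitude/longitude to kilometres by a local equirectangular projection and
altitude to kilometres; the `raw` mode reproduces the mixed-unit
convention (decimal degrees + metres) because the published correlations
depend on that unstated choice. Environmental distance is Euclidean over the
six retained bioclim variables (z-scored by default; the standardization
flag exists because the original choice is unstated).

The Mantel statistic is the Spearman correlation of unfolded upper
triangles; the null permutes rows and columns of one matrix jointly;
p-values are one-tailed (positive association) with the add-one rule at
9,999 permutations by default. The partial Mantel statistic is the
first-order partial correlation of rank vectors; significance permutes the
residuals of A's ranks on C's ranks (refolded so rows/columns permute
jointly) against B's residuals on C. MMRR regresses the standardized
unfolded response on standardized unfolded predictors (standardized β, R²,
F); the response matrix is permuted and |t| (two-tailed) and F (upper tail)
are recomputed. With a single predictor the MMRR coefficient equals the
Pearson Mantel correlation to 10⁻¹⁰, and on 4×4 instances the permutation p
matches exhaustive enumeration of all 24 relabelings — both are acceptance
checks. The genetic input to this layer is the Rousset-linearized Nei
pairwise F_ST.

## Climate ordination

VIF pruning iteratively drops the variable with the highest variance
inflation factor (1/(1 − R²) against the remaining variables) until all are
below 10; perfect collinearity is treated as infinite VIF and dropped
first, with ties broken by column order (documented, deterministic).
Climate PCA is correlation-matrix PCA with loading signs fixed so each
component's largest-magnitude loading is positive.

The "genetic components" response is the first five axes of a metric PCoA
of the individual-level allele-sharing distance (1 − shared alleles/2 per
locus, averaged over mutually scored loci); the distance choice and axis
count are configurable since the original derivation is not fully
specified. Partial dbRDA residualizes both response and predictors on the
conditioners (latitude/longitude; individuals inherit their population's
site values), then ordinates the fitted values of the response-on-predictors
regression. Inertia is the sum of column variances; conditional +
constrained + unconstrained equals the total exactly, which the tests assert
on arbitrary inputs. Per-predictor statistics are marginal (type-III-like):
the drop in constrained inertia when the term is removed, with
pseudo-F = drop/(residual inertia/residual df) and p-values from permuting
the rows of the conditioned residuals (999 default). The per-variable GLM
regresses a climate variable on ordination axes 1–2 by OLS (t per axis,
overall F, adjusted R²).

## Synthetic data

The packaged site table carries the nine sampling sites (coordinates,
altitude, bio2/bio8/bio9/bio13/bio18/bio19). The cpDNA alignment is
synthetic — the real sequences are in GenBank and not printed — shaped to
the published per-population profile (sample sizes; one singleton site each
in YH, MK and EG; all other populations monomorphic), so within-population
S, π, θ_W and D reproduce the published table exactly. The nine-deme
microsatellite panel (`scenario_taiwan_panel`) emulates the study
conditions: six small progenitor demes (N = 60–100) diverging 2,000–11,145
generations ago, three recently founded demes (95–5,537 generations,
N_T < 100), migration m = 5·10⁻⁴, μ = 5.274·10⁻⁴ per locus, and the
bottleneck-plus-recovery history (597 → 199) on the root lineage. Under
these defaults the simulated panel shows mean H_e ≈ 0.25 and strong
population differentiation, matching the published ranges.

What the generator does not emulate: genotyping error and allelic dropout,
null alleles, departures from strict single-step mutation, selection,
recombination or sequence indels, and any spatial/environmental dependence
of gene flow. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated neutral models, not the field
realism of any particular dataset.

## Problem sizes and numerical choices

The test suite runs the ABC checks at 10,000 simulations per scenario with
500 retained, 30 scenario-recovery and 50 coverage replicates; simulator
closed forms use 2,000 replicates; the Fdist calibration uses 10,000 null
simulations and a 200-locus dataset; Mantel/MMRR default to 9,999
permutations in the CLI and smaller counts inside the tests. Tolerances:
published sequence statistics to 3 decimals (exact at printed precision);
Monte-Carlo checks at 5–6% relative or stated absolute bands; algebraic
identities at 10⁻⁹–10⁻¹². Every stochastic routine takes an explicit seed
and is bit-reproducible for a fixed seed.

## Known limitations

- The ABC-GLM evidence conditions on the retained set (truncated-prior
  density), the standard practice for this estimator family; absolute
  density values are not comparable across different retention fractions,
  only model rankings at a fixed budget.
- Nei G_ST (not Weir–Cockerham θ) is the F_ST estimator throughout,
  matching the original toolchain; the two can differ at small sample
  sizes.
- The island-model Fdist envelope inherits the original method's
  assumptions (equal deme sizes, equilibrium migration); its flags are
  screening evidence, not tests of selection.
- `raw` geographic distances mix degrees and metres and are provided
  only to mirror the published convention; use `projected` for anything
  quantitative.
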