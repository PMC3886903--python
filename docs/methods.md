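# Methods

This note documents the models and procedures implemented in
`chemevolve`, the parameter choices that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Population model

The simulator (`chemevolve.synthdata`) represents an asexual population
in a chemostat as discrete, non-overlapping generations with
Wright–Fisher resampling: each generation, genotype counts are drawn
from a multinomial with probabilities proportional to frequency ×
fitness weight at constant population size *N*. Chemostat continuity is
abstracted away because time is reported in generations throughout; the
dilution rate *D* (default 0.12 hr⁻¹) enters only through the
generation-to-wall-clock conversion t_double = ln2/D ≈ 5.8 hr.

**Fitness weights are Malthusian.** A genotype with selection
coefficient *s* gets resampling weight e^s, not 1 + s. This is the
self-consistent choice: *s* is defined operationally as the
per-generation slope of the log abundance ratio (that is what the
competition-assay regression measures), and with e^s weights a single
mutant follows the haploid logistic closed form
x_t = x₀e^{st}/(1 − x₀ + x₀e^{st}) exactly, which the tests verify to
1e-6. With 1 + s weights the same trajectory would follow (1+s)^t and
the simulated dynamics would disagree with the estimator's definition of
*s* by O(s²) per generation. Relative fitness is still reported as
1 + s. Genotype fitness is additive in per-locus coefficients unless an
explicit epistatic override replaces the sum for a specific locus set.

Mutations arise at most once per lineage per generation, either at a
Poisson rate (effects drawn from a point-mass or exponential
distribution, with an optional large-effect CNV-like class) or as
*scheduled* mutations with fixed origin times — the latter is how the
benchmark scenarios pin down ground truth. Recurrent mutations at one
locus become distinct genotype-tree nodes, mirroring the way the same
gene can be hit independently in competing lineages.

**Population size.** The real populations hold ~10¹⁰ cells; the
simulator defaults to N = 10⁵. For the strongly beneficial mutations of
interest (s ≈ 0.05–0.25) selection dominates drift at either size, and
the effective size relevant to drift in a chemostat is unknown anyway
(dilution culls half the population every generation), so N is a free
desk-scale parameter rather than an attempt at realism.

## Observation models

Two layers mimic how allele frequencies are actually measured:

- **Sanger-like**: truth + Gaussian noise (default sd 0.02), clipped to
  [0,1], with values below a 5% detection floor reported as 0 — a
  quantification of electropherogram noise, not an electropherogram
  model. The floor applies to reporting only; the underlying truth is
  untouched.
- **Deep-sequencing-like**: alternative-read counts are
  Binomial(depth, truth) at default 160× (the average clone/population
  coverage); the observed frequency is count/depth. A terminal
  deep-sequencing frequency is attached to every trajectory because the
  final population sample is sequenced deeply regardless of how the time
  series was obtained.

## Selection-coefficient estimation

`estimate_selection_coefficient` fits OLS of ln(ratio) on generations;
the slope is *s*, the CI is Student-*t* with n − 2 df. Points are never
dropped; counts where the rarer strain falls below 100 cells are flagged
unreliable instead. No per-point weighting is applied (an optional
weighted mode was considered and rejected: the flow-cytometry counts are
large enough, ≥10⁵ cells, that per-point variance differences are
negligible). The default simulated assay mixes at 1:5 and samples every
2–3 generations over ~20 generations (8–9 points).

Because the pivot (ŝ − s)/se is exactly t₇ at the 9-point design, the
2-se empirical coverage is 91.4%, not 95%; the unit tests assert the
sharp *t* value and the separate CI-coverage benchmark checks the
nominal 95% at [0.93, 0.97] over 1,000 assays.

## Trajectory clustering and genotype nesting

Clustering is average-linkage agglomerative with an **all-pairs**
criterion: a merge is allowed only if every cross pair satisfies both
thresholds (Pearson r > 0.97 on the shared grid; terminal
deep-sequencing frequencies within 4%). All-pairs was chosen over plain
average linkage because it cannot chain dissimilar trajectories through
intermediates. Candidate merges are applied in descending average
correlation with lexicographic tie-breaks, so the result is
deterministic and permutation-invariant. Constant trajectories have
undefined correlation and are never merged (a warning is emitted). The
terminal-difference threshold is 4% by default with the 5% variant
available as a parameter, since both values are defensible readings of
the source procedure. An optional same-clone requirement restricts
merges to mutations co-observed in at least one clone.

Nesting is greedy containment: clusters are attached, in descending
order of *time-integrated* frequency, to the deepest existing node whose
raw frequency dominates the cluster within an absolute tolerance of 0.05
at every timepoint and whose children leave headroom (sibling-sum
constraint). Descending *maximum* frequency was the first choice of
processing order but is noise-fragile: when a sublineage sweeps through
its parent, both maxima converge and observation noise can invert the
order, orphaning the parent. The integrated frequency is strictly larger
for parents (containment implies it) and averages noise across the grid,
so it is used instead. A cluster that fits nowhere (noise can break
every containment) becomes an independent lineage under the root rather
than an error. Clone memberships, when available, veto parents whose
clone sets do not cover the child's.

Introduction times are the first sampled generation at which a cluster
reaches the 5% floor (optionally linearly interpolated; off by default
because detection is only defined at sampled generations). Lineages
already detectable at the first sample are flagged left-censored.
Exclusive (Muller) frequencies are raw minus summed children, clipped at
0; deficits beyond the 0.05 tolerance raise an error naming the node and
generation.

**Recovery benchmark.** The bundled scenario has two competing founder
lineages (s = 0.10 and 0.12, each with a neutral hitchhiking co-marker)
that each later gain a nested mutation (+0.06 at generation 45, +0.12 at
generation 95), tuned so every lineage exceeds the detection floor at
several sampled generations while none fixes. On noiseless observations
the inferred tree equals the simulator truth exactly. Under Sanger-like
noise the benchmark scores *ancestry consistency* per mutation: the
inferred ancestor set must contain a true ancestor and nothing foreign.
Markers with identical true trajectories (a driver and its hitchhiker)
are one genotype whose internal order is unidentifiable from frequency
data — the terminal frequencies that would order them differ by binomial
sampling at sequencing depth — so order within such marker groups is not
scored. Mean recovery is ~96% at sd 0.02 with the 5% floor.

## Fitness landscapes

Epistasis is defined on the additive *s* scale (the expectation for a
combination is the sum of single-mutant coefficients), matching the
convention in which *s* values from a common-reference competition are
directly comparable. The decomposition ε_S = Σ_{T⊆S} (−1)^{|S|−|T|} s_T
is the Möbius inversion of s_S = Σ_{T⊆S} ε_T and is exact (round-trip
tested to 1e-12). Standard errors propagate as root-sum-squares;
significance of fitness steps uses the normal *z* (regression df are
large enough that the refinement to *t* is immaterial). Measurements
made against a non-ancestral reference (e.g. a triple-mutant competitor)
are re-based to the ancestral scale by adding the reference's own *s*,
with errors in quadrature, and flagged.

Path analysis enumerates all k! orderings (refused above k = 12); a step
is favored when Δs > 0, significantly at α when given, by point estimate
with α = None. Exact zero steps are neutral, never favored. Raising
strictness never unblocks a path (tested). The bundled three-locus
landscape is a synthetic construction reproducing a qualitative
sign-epistasis pattern — two individually beneficial alleles, a third
that is neutral alone, synergistic with either single mutant, and
deleterious on their double — under which exactly the two orderings
placing the third allele second are accessible. Its numeric values are
this package's own choices; only the sign structure is meaningful.

## Variant heuristics and spectrum statistics

The upstream variant caller is out of scope; calls arrive with a caller
p-value and dual base-quality-tier flags, and the module implements the
downstream rules only (rule order: ancestor, uniqueness, tiers, p ≤
10⁻⁸, depth ≥ 50% of mean, frequency ≥ 5%; first failing rule logged).
A labelled non-caller binomial score against a sequencing-error null is
provided for synthetic panels. Exact binomial tests use the
minimal-likelihood two-sided convention (the common "exact binomial
test"); the sidedness of the classical spectrum results is not always
stated, so both are computed — the printed coding-bias and
nonsynonymous-fraction p-values match the two-sided form. Zygosity bands
quantify "near 0.5" as [0.35, 0.65] and "close to 1" as ≥ 0.90; these
two cutoffs are this package's decisions. Coordinates are 1-based
inclusive (VCF convention); CNV length is end − start + 1, and BED input
is converted on ingest.

## Expression statistics

The gene-set divergence test draws same-size gene sets without
replacement from the measured genes and uses the add-one estimator
p = (1 + #{null ≥ obs})/(n_perm + 1), which cannot return 0 and is
exactly valid (type-I error ≤ nominal) under exchangeability; the plain
fraction is available by flag. The enrichment Fisher table counts
mutation *events* in the hit margin (a locus with three independent
alleles contributes three; intergenic variants are expanded to both
neighboring genes by the caller) and genes in the universe margin; loci
with no annotation are excluded before testing, and terms outside 2–100
annotated genes are dropped. Whether the original procedure's universe
margin counted events or genes is ambiguous; counting genes there was
chosen and is noted here as an interpretation.

## Numerical and reproducibility choices

Single seeded NumPy generator per run; every CLI entry point and the
acceptance script derive all sub-seeds from one integer, and reruns are
byte-identical (manifest checksums are SHA-256). Tolerances: logistic
closed form 1e-6 (float accumulation over 250 steps), epistasis
round-trip 1e-12, Muller conservation 1e-6, containment 0.05 absolute.
Ties are broken lexicographically by mutation id everywhere ordering
matters.

## Problem sizes

The default benchmarks use N = 10⁵ simulated cells, 1,000 competition
assays, 100 noisy-lineage replicates, 1,000 permutation-test replicates
at 199 permutations over 400 genes, and variant panels of 20–60 sites.
These sizes make the full test suite and the acceptance script each run
in seconds on a single core while leaving the Monte-Carlo intervals
(±2% on coverage, ±1.4% on type-I error) well inside the asserted
bands.

## Limitations

- The simulator's generations are discrete and its effective population
  size is a free parameter; it does not model chemostat physiology,
  bottlenecks, or frequency-dependent selection.
- The Sanger layer is Gaussian-with-floor, not a peak-calling model;
  correlated measurement errors across timepoints are not represented.
- Passing lineage benchmarks on synthetic sweeps shows the
  reconstruction logic is correct under its stated noise model, not that
  real trajectories (with batch effects, uneven coverage, or shared
  PCR artifacts) would reconstruct equally well.
- The enrichment module uses flat term lists; no ontology-graph
  propagation.
- Landscape significance assumes independent measurement errors between
  genotypes; shared-reference correlations are ignored.
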