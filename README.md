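# chemevolve

Analysis toolkit for experimental evolution in nutrient-limited
chemostats, built around the data types of a yeast nitrogen-limitation
selection: pairwise competition assays, Sanger/deep-sequencing allele
frequency time series, pooled-population variant calls, aCGH-style copy
number segments, and log₂-ratio expression profiles.

It is written for researchers who run (or reanalyze) chemostat selection
experiments and want a tested, scriptable implementation of the standard
downstream analyses:

- **Fitness estimation** — the selection coefficient *s* of a genotype
  competed against a fluorescent reference is the OLS slope of
  ln(evolved/reference) against time in generations; relative fitness is
  1 + *s*. Standard errors and Student-*t* 95% CIs (df = n − 2) come from
  the regression; estimates are compared with a normal *z* on pooled
  standard errors.
- **Lineage reconstruction** — allele trajectories are clustered when
  every pair has Pearson *r* > 0.97 and terminal deep-sequencing
  frequencies within 4%; clusters are nested into a genotype tree by
  frequency containment (a mutation can never outnumber its carriers);
  introduction times are read off at the 5% detection floor; exclusive
  (Muller) genotype frequencies are exported for plotting.
- **Fitness landscapes and epistasis** — for all 2^k combinations of k
  alleles, epistatic terms are the inclusion–exclusion residuals
  ε_S = Σ_{T⊆S} (−1)^{|S|−|T|} s_T on the additive *s* scale (exactly
  invertible); pairwise interactions are classified
  (none/magnitude/sign/reciprocal sign) and all k! mutational orderings
  are labelled accessible or blocked by per-step significance.
- **Variant filtering and mutation spectrum** — the pooled-sequencing
  heuristics (absent in ancestor, unique to one population, called at
  both BQ20/BQ30 tiers, caller p ≤ 10⁻⁸, depth ≥ 50% of the sample mean,
  frequency ≥ 5%), zygosity bands, CNV segment display filters (≥10 kb,
  |log₂| > 0.5), exact binomial tests for coding bias and the
  nonsynonymous fraction, and per-clone summaries.
- **Expression divergence and enrichment** — gene-set divergence by
  permutation (mean |log₂ ratio| of a set, e.g. the 38-gene NCR regulon,
  against random same-size draws), flat-term Fisher-exact enrichment
  with multi-allele and intergenic-neighbor counting and Bonferroni
  correction, copy-number/expression correlation, and pairwise
  transcriptome divergence.
- **Synthetic data** — a Wright–Fisher chemostat simulator (genotype
  tree + frequency truth, scheduled or random beneficial mutations,
  optional epistatic overrides), observation models for Sanger-like
  noise with a 5% floor and binomial read counts at ~160×, competition
  and expression generators, and a toy genome annotation — so every
  stage is testable without external data.

## Worked example

Run the bundled end-to-end demo (a simulated 250-generation selection
with two clonally interfering lineages, each acquiring a nested second
mutation):

```sh
chemevolve run --seed 1 --out demo/
```

which logs, among other things:

```
[lineage] {"n_trajectories": 6, "n_clusters": 4, "n_edges": 4}
[landscape] {"n_accessible": 2, "n_blocked": 4, "n_edges": 12}
```

Six mutation trajectories collapse into four clusters (each driver
mutation plus its hitchhiker), and the genotype tree has four edges: two
competing lineages under the ancestor, each with one nested sublineage —
alternating soft sweeps, with no genotype fixing.

`demo/fitness_estimates.tsv` holds the regression estimates for the
eight combinations of the three interacting alleles (gat1-, mep2- and
lst4-like), e.g.

```
assay_id        s        se       relative_fitness
gat1            0.2659   0.0024   1.2659
lst4            0.0057   0.0042   1.0057
gat1+mep2       0.4671   0.0026   1.4671
gat1+lst4+mep2  0.4444   0.0026   1.4444
```

gat1 and mep2 are individually beneficial, lst4 is neutral on its own,
and the triple mutant is *less* fit than the gat1+mep2 double.
`demo/epistasis.tsv` quantifies this: strong positive pairwise terms for
lst4 with either partner (ε ≈ +0.13) and a negative three-way term
(ε ≈ −0.30). The consequence appears in `demo/paths.tsv`:

```
order            accessible  first_blocking_step
gat1>lst4>mep2   True
mep2>lst4>gat1   True
gat1>mep2>lst4   False       lst4
lst4>gat1>mep2   False       lst4
...
```

Only the orderings that place the lst4-like allele *second* — after one
of the individually beneficial mutations but before the other — are
selectively accessible: sign epistasis constrains the order in which the
three-locus genotype can evolve. `demo/fitness_graph.dot` renders the
cube with solid (favored) and dashed (disfavored) edges whose widths are
proportional to |Δs|.

Each stage can also be run standalone on your own TSV/VCF/GFF files;
see `chemevolve --help` for the `simulate`, `fitness`, `lineage`,
`landscape`, `variants` and `enrich` subcommands.

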