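"""Synthetic chemostat-evolution data generator.

Emulates the data layers of a nitrogen-limited chemostat selection
experiment: an asexual population evolving for ~250 generations under
continuous dilution, observed as (i) time-series allele frequencies of
nested/competing lineages (Sanger-like noisy estimates with a detection
floor, or binomial read counts at deep-sequencing depth), (ii) two-strain
competition time courses, (iii) log2-ratio expression matrices with a
shifted regulon-like gene set, and (iv) a toy genome annotation with
gene/term assignments.

The population model is discrete-generation Wright-Fisher resampling of
genotype counts with fitness-weighted multinomial sampling at constant
population size.  A genotype's selective advantage is the sum of its
per-locus selection coefficients (relative fitness 1 + s) unless a locus
subset carries an explicit epistatic override; the resampling weight is
the Malthusian exp(s).  Mutations arise on parent genotypes
proportionally to their frequency; recurrent mutations at one locus are
tracked as distinct genotype-tree nodes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "EffectDistribution",
    "ScheduledMutation",
    "SimConfig",
    "GenotypeNode",
    "EvolutionResult",
    "ObservationModel",
    "simulate_chemostat_evolution",
    "observe_allele_frequencies",
    "simulate_competition",
    "simulate_expression",
    "generate_annotation",
    "simulate_variant_panel",
    "AnnotationSet",
]

DEFAULT_SAMPLE_GENERATIONS = (24, 61, 102, 137, 173, 213, 250)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class EffectDistribution:
    """Distribution of per-mutation selection coefficients.

    ``kind`` is ``"point"`` (draw from ``values`` with ``probs``) or
    ``"exponential"`` (mean ``mean``).  With probability ``cnv_prob`` a
    mutation is instead drawn from a large-effect CNV-like class with
    point effect ``cnv_s`` (transporter-amplification alleles dominate
    adaptation in nutrient-limited chemostats, so this class is distinct).
    """

    kind: str = "exponential"
    mean: float = 0.05
    values: tuple[float, ...] = ()
    probs: tuple[float, ...] | None = None
    cnv_prob: float = 0.0
    cnv_s: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("point", "exponential"):
            raise ConfigError(f"unknown effect distribution kind: {self.kind!r}")
        if self.kind == "point" and not self.values:
            raise ConfigError("point-mass effect distribution needs values")
        if not (0.0 <= self.cnv_prob <= 1.0):
            raise ConfigError("cnv_prob must be in [0, 1]")

    def draw(self, rng: np.random.Generator) -> float:
        if self.cnv_prob > 0 and rng.random() < self.cnv_prob:
            return float(self.cnv_s)
        if self.kind == "point":
            return float(rng.choice(np.asarray(self.values), p=self.probs))
        return float(rng.exponential(self.mean))


@dataclass(frozen=True)
class ScheduledMutation:
    """A mutation introduced deterministically at a fixed generation.

    ``parent_loci`` names the genotype (by its set of mutant loci) on which
    the new ``locus`` arises; ``s`` is the per-locus selection coefficient.
    ``init_freq`` defaults to one cell (1/population_size).
    """

    generation: int
    parent_loci: tuple[str, ...]
    locus: str
    s: float
    init_freq: float | None = None


@dataclass
class SimConfig:
    """Configuration of a chemostat evolution run.

    population_size
        Number of cells resampled each generation.  The study system holds
        ~1e10 cells; the default 1e5 is a desk-scale effective size that
        preserves the deterministic sweep dynamics of strongly beneficial
        mutations while keeping simulation cost trivial.
    n_generations
        Length of the selection (default 250 generations).
    dilution_rate
        Chemostat dilution rate in 1/hr (default 0.12); informational,
        used to convert generations to wall-clock time.
    mutation_rate
        Beneficial mutations per genome per generation.
    """

    population_size: int = 100_000
    n_generations: int = 250
    dilution_rate: float = 0.12
    mutation_rate: float = 0.0
    effect_distribution: EffectDistribution = field(default_factory=EffectDistribution)
    epistasis_overrides: Mapping[frozenset[str], float] | None = None
    scheduled_mutations: Sequence[ScheduledMutation] = ()
    deterministic: bool = False
    seed: int | None = None
    sample_generations: Sequence[int] = DEFAULT_SAMPLE_GENERATIONS
    founder_loci: Sequence[tuple[tuple[str, ...], float, float]] = ()
    """Optional non-clonal founder population: (loci, per-genotype s sum, freq)."""

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigError("population_size must be >= 1")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.mutation_rate < 0:
            raise ConfigError("mutation_rate must be >= 0")
        if any(g > self.n_generations for g in self.sample_generations):
            raise ConfigError("sample_generations must all be <= n_generations")
        known = {m.locus for m in self.scheduled_mutations}
        for loci, _ in (self.epistasis_overrides or {}).items():
            unknown = set(loci) - known
            if unknown:
                raise ConfigError(
                    f"epistasis_overrides reference unknown loci: {sorted(unknown)}"
                )


@dataclass
class GenotypeNode:
    """One node of the genotype tree: a genotype created by one mutation."""

    id: int
    parent: int | None
    locus: str | None
    s_locus: float
    loci: frozenset[str]
    s_genotype: float  # total selective advantage over the founder
    origin_generation: int


class EvolutionResult:
    """Ground truth of a simulated evolution: genotype tree + frequencies."""

    def __init__(
        self,
        nodes: list[GenotypeNode],
        frequency_matrix: np.ndarray,
        config: SimConfig,
    ) -> None:
        self.nodes = nodes
        self.frequency_matrix = frequency_matrix  # (n_nodes, n_generations + 1)
        self.config = config
        self.generations = np.arange(frequency_matrix.shape[1])
        self._by_id = {n.id: n for n in nodes}

    def node(self, node_id: int) -> GenotypeNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[GenotypeNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def carrier_ids(self, node_id: int) -> list[int]:
        """Node ids of the subtree rooted at node_id (carriers of its mutation)."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(c.id for c in self.children(nid))
        return out

    def mutation_frequency(self, node_id: int, generation: int | None = None):
        """Frequency of carriers of the mutation that created ``node_id``."""
        rows = [self._index(nid) for nid in self.carrier_ids(node_id)]
        total = self.frequency_matrix[rows].sum(axis=0)
        if generation is None:
            return total
        return float(total[generation])

    def allele_frequency(self, locus: str, generation: int | None = None):
        """Summed frequency of all genotypes carrying any mutation at ``locus``."""
        rows = [
            self._index(n.id) for n in self.nodes if locus in n.loci
        ]
        if not rows:
            raise KeyError(f"unknown locus: {locus}")
        total = self.frequency_matrix[rows].sum(axis=0)
        if generation is None:
            return total
        return float(total[generation])

    def _index(self, node_id: int) -> int:
        return next(i for i, n in enumerate(self.nodes) if n.id == node_id)

    def to_json(self) -> str:
        payload = {
            "seed": self.config.seed,
            "nodes": [
                {
                    "id": n.id,
                    "parent": n.parent,
                    "locus": n.locus,
                    "s_locus": n.s_locus,
                    "s_genotype": n.s_genotype,
                    "loci": sorted(n.loci),
                    "origin_generation": n.origin_generation,
                }
                for n in self.nodes
            ],
            "frequency_matrix": self.frequency_matrix.tolist(),
        }
        return json.dumps(payload)


def _genotype_weight(
    loci: frozenset[str], s_sum: float, overrides: Mapping[frozenset[str], float] | None
) -> float:
    """Per-generation resampling weight exp(s).

    The selection coefficient is defined as the per-generation change of
    the log abundance ratio (that is what the competition-assay
    regression measures), so the Wright-Fisher weight is the Malthusian
    exp(s); for one mutant this yields the logistic closed form
    x_t = x0*exp(s*t) / (1 - x0 + x0*exp(s*t)) exactly.  Relative fitness
    reported elsewhere remains 1 + s.
    """
    s = overrides[loci] if overrides and loci in overrides else s_sum
    return math.exp(s)


def simulate_chemostat_evolution(config: SimConfig) -> EvolutionResult:
    """Run a discrete-generation Wright-Fisher simulation of the chemostat.

    Each generation the genotype counts are resampled multinomially with
    probabilities proportional to ``count * fitness`` at constant
    population size (``deterministic=True`` replaces the sampling with the
    expectation update, which follows the haploid logistic closed form for
    a single mutant).  Returns the complete truth: genotype tree and the
    genotype-by-generation frequency matrix.
    """
    rng = np.random.default_rng(config.seed)
    N = config.population_size
    overrides = (
        {frozenset(k): v for k, v in config.epistasis_overrides.items()}
        if config.epistasis_overrides
        else None
    )

    nodes: list[GenotypeNode] = [
        GenotypeNode(0, None, None, 0.0, frozenset(), 0.0, 0)
    ]
    # frequencies as float vector aligned with `nodes`
    if config.founder_loci:
        freqs = []
        nodes = []
        next_id = 0
        for loci, s_sum, fr in config.founder_loci:
            nodes.append(
                GenotypeNode(
                    next_id, None, None, 0.0, frozenset(loci), s_sum, 0
                )
            )
            freqs.append(fr)
            next_id += 1
        freq = np.asarray(freqs, dtype=float)
        if not math.isclose(freq.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("founder frequencies must sum to 1")
    else:
        freq = np.array([1.0])
        next_id = 1

    scheduled: dict[int, list[ScheduledMutation]] = {}
    for m in config.scheduled_mutations:
        scheduled.setdefault(m.generation, []).append(m)

    history = [freq.copy()]
    n_nodes_at = [len(nodes)]
    auto_locus = 0

    for gen in range(1, config.n_generations + 1):
        # introduce scheduled mutations at the start of the generation
        for m in scheduled.get(gen, ()):
            parent_idx = _find_genotype(nodes, frozenset(m.parent_loci))
            if parent_idx is None:
                raise ConfigError(
                    f"scheduled mutation {m.locus} at generation {gen}: "
                    f"parent genotype {set(m.parent_loci) or '{founder}'} not present"
                )
            init = m.init_freq if m.init_freq is not None else 1.0 / N
            init = min(init, freq[parent_idx])
            parent = nodes[parent_idx]
            child_loci = parent.loci | {m.locus}
            child_s_sum = parent.s_genotype + m.s
            nodes.append(
                GenotypeNode(
                    next_id, parent.id, m.locus, m.s, child_loci, child_s_sum, gen
                )
            )
            next_id += 1
            freq = np.append(freq, init)
            freq[parent_idx] -= init

        # random mutations, at most one per lineage (cell) per generation
        if config.mutation_rate > 0:
            n_new = rng.poisson(config.mutation_rate * N)
            n_new = int(min(n_new, N))
            if n_new > 0:
                parents = rng.choice(len(nodes), size=n_new, p=freq / freq.sum())
                for parent_idx in parents:
                    parent = nodes[parent_idx]
                    if freq[parent_idx] < 1.0 / N:
                        continue
                    s_new = config.effect_distribution.draw(rng)
                    locus = f"L{auto_locus}"
                    auto_locus += 1
                    nodes.append(
                        GenotypeNode(
                            next_id,
                            parent.id,
                            locus,
                            s_new,
                            parent.loci | {locus},
                            parent.s_genotype + s_new,
                            gen,
                        )
                    )
                    next_id += 1
                    freq = np.append(freq, 1.0 / N)
                    freq[parent_idx] -= 1.0 / N

        w = np.array(
            [_genotype_weight(n.loci, n.s_genotype, overrides) for n in nodes]
        )
        p = freq * w
        p /= p.sum()
        if config.deterministic:
            freq = p
        else:
            counts = rng.multinomial(N, p)
            freq = counts / N
        history.append(freq.copy())
        n_nodes_at.append(len(nodes))

    matrix = np.zeros((len(nodes), config.n_generations + 1))
    for gen, (f, k) in enumerate(zip(history, n_nodes_at)):
        matrix[:k, gen] = f
    return EvolutionResult(nodes, matrix, config)


def _find_genotype(nodes: list[GenotypeNode], loci: frozenset[str]) -> int | None:
    for i, n in enumerate(nodes):
        if n.loci == loci:
            return i
    return None


@dataclass(frozen=True)
class ObservationModel:
    """How the true allele frequencies are observed.

    ``sanger`` adds Gaussian noise (sd ``noise_sd``) and reports values
    below ``detection_floor`` as 0 — frequencies under ~5% are below the
    background noise of Sanger-electropherogram quantification.
    ``deepseq`` draws a binomial alternative-read count at ``read_depth``
    (the study's populations averaged ~160x coverage).
    """

    mode: str = "sanger"
    noise_sd: float = 0.02
    detection_floor: float = 0.05
    read_depth: int = 160

    def __post_init__(self) -> None:
        if self.mode not in ("sanger", "deepseq"):
            raise ConfigError(f"unknown observation mode: {self.mode!r}")
        if not (0.0 <= self.detection_floor < 1.0):
            raise ConfigError("detection_floor must be in [0, 1)")
        if self.read_depth < 1:
            raise ConfigError("read_depth must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def observe_allele_frequencies(
    result: EvolutionResult,
    model: ObservationModel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observe every mutation's frequency trajectory at the sampled generations.

    Returns a long-format table with columns ``mutation_id, locus,
    generation, frequency, final_deepseq_freq``.  One trajectory per
    mutation event (recurrent alleles at one locus yield distinct
    trajectories).  The terminal deep-sequencing frequency is attached to
    every trajectory regardless of mode.
    """
    gens = list(result.config.sample_generations)
    if not gens:
        raise ConfigError("sample_generations is empty")
    rng = np.random.default_rng(seed)
    rows = []
    final_gen = result.frequency_matrix.shape[1] - 1
    for node in result.nodes:
        if node.locus is None:
            continue
        truth = np.array([result.mutation_frequency(node.id, g) for g in gens])
        if model.mode == "sanger":
            obs = truth + rng.normal(0.0, model.noise_sd, size=len(gens))
            obs = np.clip(obs, 0.0, 1.0)
            obs[obs < model.detection_floor] = 0.0
        else:
            alt = rng.binomial(model.read_depth, truth)
            obs = alt / model.read_depth
        p_final = result.mutation_frequency(node.id, final_gen)
        final_deepseq = rng.binomial(model.read_depth, p_final) / model.read_depth
        for g, f in zip(gens, obs):
            rows.append(
                {
                    "mutation_id": f"m{node.id}",
                    "locus": node.locus,
                    "generation": g,
                    "frequency": float(f),
                    "final_deepseq_freq": float(final_deepseq),
                }
            )
    return pd.DataFrame(rows)


def simulate_competition(
    s_true: float,
    init_ratio: float = 0.2,
    n_generations: float = 20.0,
    sampling_interval: float = 2.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "assay",
    reference_genotype: str = "ancestor",
):
    """Simulate a pairwise competition against a fluorescent reference.

    The assay mixes the test strain with the labelled reference at a 1:5
    ratio and samples every 2-3 generations over ~20 generations; the log
    abundance ratio drifts linearly at rate ``s_true`` with Gaussian
    measurement noise:  ln r(t) = ln r(0) + s*t + N(0, noise_sd).
    """
    from .fitness import CompetitionSeries

    if init_ratio <= 0:
        raise ConfigError("init_ratio must be > 0")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, n_generations + 1e-9, sampling_interval)
    log_ratio = math.log(init_ratio) + s_true * t + rng.normal(0, noise_sd, len(t))
    return CompetitionSeries(
        generations=t,
        ratio=np.exp(log_ratio),
        label=label,
        reference_genotype=reference_genotype,
    )


def simulate_expression(
    n_genes: int = 6000,
    target_set_size: int = 38,
    shift: float = 2.0,
    noise_sd: float = 0.5,
    n_samples: int = 1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a log2-ratio expression matrix with a shifted gene set.

    Background genes are N(0, noise_sd); the ``target_set_size`` target
    genes (default 38, the size of the nitrogen catabolite repression
    regulon set used for divergence testing) receive an additional +/-
    ``shift`` with random sign, constant across samples for a gene.
    Returns (genes x samples DataFrame, list of target gene ids).
    """
    if target_set_size > n_genes:
        raise ConfigError("target_set_size must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    mat = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    target_idx = rng.choice(n_genes, size=target_set_size, replace=False)
    signs = rng.choice([-1.0, 1.0], size=target_set_size)
    mat[target_idx] += (signs * shift)[:, None]
    df = pd.DataFrame(
        mat, index=genes, columns=[f"sample{j+1}" for j in range(n_samples)]
    )
    df.index.name = "gene"
    return df, [genes[i] for i in sorted(target_idx)]


@dataclass
class AnnotationSet:
    """Toy linear-genome annotation: gene intervals plus term assignments."""

    genes: pd.DataFrame  # gene_id, start, end (1-based inclusive), strand
    terms: dict[str, set[str]]
    genome_length: int

    @property
    def coding_fraction(self) -> float:
        span = (self.genes["end"] - self.genes["start"] + 1).sum()
        return float(span) / self.genome_length

    def gene_at(self, position: int) -> str | None:
        """Gene containing a 1-based position, or None if intergenic."""
        hit = self.genes[
            (self.genes["start"] <= position) & (self.genes["end"] >= position)
        ]
        return None if hit.empty else str(hit.iloc[0]["gene_id"])

    def neighbors(self, position: int) -> tuple[str | None, str | None]:
        """Flanking genes of an intergenic 1-based position (left, right)."""
        left = self.genes[self.genes["end"] < position]
        right = self.genes[self.genes["start"] > position]
        return (
            None if left.empty else str(left.iloc[-1]["gene_id"]),
            None if right.empty else str(right.iloc[0]["gene_id"]),
        )


def generate_annotation(
    n_genes: int = 200,
    coding_fraction: float = 0.72,
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (2, 30),
    genome_length: int = 1_000_000,
    seed: int | None = None,
) -> AnnotationSet:
    """Generate a toy single-chromosome annotation.

    Non-overlapping gene intervals cover ~``coding_fraction`` of the
    genome (default 0.72, the coding fraction of the yeast genome); genes
    are assigned to functional terms with sizes drawn uniformly from
    ``term_size_range``.
    """
    if not (0 < coding_fraction <= 1):
        raise ConfigError("coding_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    coding_total = int(round(coding_fraction * genome_length))
    if coding_total < n_genes:
        raise ConfigError("infeasible packing: fewer coding bases than genes")
    gap_total = genome_length - coding_total
    gene_lens = _partition(coding_total, n_genes, rng)
    # n_genes + 1 gaps (ends may be zero when coding_fraction == 1)
    gap_lens = (
        _partition(gap_total, n_genes + 1, rng, allow_zero=True)
        if gap_total > 0
        else np.zeros(n_genes + 1, dtype=int)
    )
    rows = []
    pos = 1
    for i in range(n_genes):
        pos += int(gap_lens[i])
        start = pos
        end = pos + int(gene_lens[i]) - 1
        rows.append(
            {
                "gene_id": f"g{i:05d}",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        pos = end + 1
    genes = pd.DataFrame(rows)
    gene_ids = genes["gene_id"].tolist()
    lo, hi = term_size_range
    terms: dict[str, set[str]] = {}
    for j in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_genes)
        members = rng.choice(n_genes, size=size, replace=False)
        terms[f"T{j:04d}"] = {gene_ids[k] for k in members}
    return AnnotationSet(genes=genes, terms=terms, genome_length=genome_length)


def _partition(
    total: int, k: int, rng: np.random.Generator, allow_zero: bool = False
) -> np.ndarray:
    """Split ``total`` into ``k`` integer parts with Dirichlet-ish weights."""
    w = rng.dirichlet(np.ones(k))
    parts = np.floor(w * total).astype(int)
    if not allow_zero:
        parts = np.maximum(parts, 1)
    # fix the rounding remainder on the largest part
    parts[int(np.argmax(parts))] += total - parts.sum()
    return parts


def simulate_variant_panel(
    n_variants: int = 20,
    mean_depth: float = 160.0,
    seed: int | None = None,
    ancestor_fraction: float = 0.2,
    shared_fraction: float = 0.2,
    low_p_fraction: float = 0.3,
    genome_length: int = 1_000_000,
):
    """Random panel of population variant calls with known rule violations.

    Produces a list of :class:`chemevolve.variants.VariantCall` where a
    known fraction is present in the ancestor, shared across populations,
    carries a weak caller p-value, sits on shallow coverage, or falls
    below the 5% frequency floor — for exercising the population filter
    against brute-force predicate evaluation.

    Returns ``(calls, ancestor_keys, other_population_keys)``.
    """
    from .variants import VariantCall

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    calls: list[VariantCall] = []
    ancestor_keys: set[tuple[str, int, str]] = set()
    other_keys: set[tuple[str, int, str]] = set()
    positions = rng.choice(genome_length, size=n_variants, replace=False) + 1
    for i in range(n_variants):
        pos = int(positions[i])
        ref, alt = rng.choice(bases, size=2, replace=False)
        depth = max(1, int(rng.normal(mean_depth, mean_depth / 8)))
        if rng.random() < 0.3:
            depth = int(mean_depth * 0.3)  # shallow site
        freq = float(rng.uniform(0.01, 0.6))
        alt_count = int(rng.binomial(depth, freq))
        caller_p = 10.0 ** rng.uniform(-20, -9)
        if rng.random() < low_p_fraction:
            caller_p = 10.0 ** rng.uniform(-7, -2)  # fails the 1e-8 cutoff
        both_tiers = rng.random() > 0.2
        key = ("chrI", pos, str(alt))
        if rng.random() < ancestor_fraction:
            ancestor_keys.add(key)
        if rng.random() < shared_fraction:
            other_keys.add(key)
        calls.append(
            VariantCall(
                chromosome="chrI",
                position=pos,
                ref=str(ref),
                alt=str(alt),
                alt_count=alt_count,
                total_count=depth,
                caller_p=caller_p,
                in_both_bq_tiers=both_tiers,
                sample_id="pop1",
                sample_kind="population",
            )
        )
    return calls, ancestor_keys, other_keys
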