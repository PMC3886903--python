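"""Expression-divergence and functional-enrichment statistics.

Covers the transcriptome-level analyses of an adaptive-evolution study:
ancestor normalization of log2 expression ratios, the gene-set
divergence permutation test (mean absolute log2 ratio of a set, e.g. the
38-gene nitrogen catabolite repression regulon, against random same-size
gene draws), a flat-term Fisher-exact enrichment with multi-allele and
intergenic-neighbor counting plus Bonferroni correction, copy-number vs
expression correlation, pairwise-correlation transcriptome divergence,
and the responsive-gene display filter (|log2| > 1.5).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionProfile",
    "GeneSet",
    "EnrichmentInput",
    "normalize_to_ancestor",
    "gene_set_divergence_test",
    "functional_enrichment",
    "copy_number_expression_correlation",
    "transcriptome_divergence",
    "expression_response_filter",
]


@dataclass
class ExpressionProfile:
    """Per-gene log2 ratios of one sample against the common reference."""

    sample_id: str
    environment: str
    log2_ratio: pd.Series  # indexed by unique gene ids

    def __post_init__(self) -> None:
        if self.log2_ratio.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.log2_ratio.to_numpy(dtype=float))):
            raise ValueError("non-finite expression values")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))


@dataclass
class EnrichmentInput:
    """Mutated loci (as a multiset of independent alleles) plus annotation."""

    locus_counts: Mapping[str, int]  # locus id -> number of independent alleles
    term_genes: Mapping[str, Iterable[str]]  # term -> annotated genes
    min_term_size: int = 2
    max_term_size: int = 100

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.locus_counts.values()):
            raise ValueError("allele counts must be >= 1")


def normalize_to_ancestor(
    clone: ExpressionProfile, ancestor: ExpressionProfile
) -> ExpressionProfile:
    """Subtract the ancestor's response in the same environment.

    Both profiles are log2 ratios against a common reference, so the
    clone-specific signal is the difference in log space; this removes
    the environment main effect shared with the ancestor.
    """
    if clone.environment != ancestor.environment:
        raise ValueError(
            f"environment mismatch: clone {clone.environment!r} vs "
            f"ancestor {ancestor.environment!r}"
        )
    if set(clone.log2_ratio.index) != set(ancestor.log2_ratio.index):
        raise ValueError("profiles measure different gene universes")
    adj = clone.log2_ratio - ancestor.log2_ratio.reindex(clone.log2_ratio.index)
    return ExpressionProfile(
        sample_id=f"{clone.sample_id}_vs_ancestor",
        environment=clone.environment,
        log2_ratio=adj,
    )


def gene_set_divergence_test(
    profile: ExpressionProfile,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    add_one: bool = True,
) -> dict:
    """Permutation test of a gene set's expression divergence.

    The statistic is the mean absolute log2 ratio over the set's members;
    the null distribution is the same statistic on ``n_perm`` random
    equally sized gene sets drawn without replacement from the measured
    genes.  p = (1 + #{null >= observed}) / (n_perm + 1) with the add-one
    estimator (``add_one=False`` gives the plain fraction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    missing = sorted(gene_set.members - set(profile.log2_ratio.index))
    if missing:
        raise ValueError(f"set members missing from profile: {missing}")
    values = profile.log2_ratio
    stat = float(values.loc[sorted(gene_set.members)].abs().mean())

    rng = np.random.default_rng(seed)
    absvals = values.abs().to_numpy(dtype=float)
    k = len(gene_set.members)
    n = len(absvals)
    # vectorized draws without replacement: argpartition of uniform keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = absvals[idx].mean(axis=1)
    n_ge = int(np.sum(null >= stat))
    if add_one:
        p = (1 + n_ge) / (n_perm + 1)
    else:
        p = n_ge / n_perm
    return {
        "statistic": stat,
        "p": float(p),
        "n_perm": n_perm,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        "null_q95": float(np.quantile(null, 0.95)),
    }


def count_term_hits(
    locus_counts: Mapping[str, int], term_members: frozenset[str]
) -> int:
    """Mutation events hitting a term: multi-allele loci contribute their
    full allele count; intergenic events should already be expanded to
    both neighboring genes by the caller."""
    return sum(c for g, c in locus_counts.items() if g in term_members)


def functional_enrichment(
    enrichment_input: EnrichmentInput,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-tailed Fisher exact enrichment over flat functional terms.

    Terms outside the size bounds (default 2..100 annotated genes) are
    dropped before testing; mutated loci without any annotation are
    excluded from the hit margin.  The 2x2 table counts mutation *events*
    in the hit margin (a locus with three independent alleles contributes
    three) and genes in the universe margin.  Bonferroni multiplies by
    the number of terms actually tested.
    """
    if not enrichment_input.locus_counts:
        raise ValueError("empty mutated-locus set")
    universe = set(universe)
    term_sets = {
        t: frozenset(g) & universe for t, g in enrichment_input.term_genes.items()
    }
    annotated = set().union(*term_sets.values()) if term_sets else set()
    # drop mutated loci without any annotation
    counts = {
        g: c for g, c in enrichment_input.locus_counts.items() if g in annotated
    }
    if not counts:
        raise ValueError("no mutated locus carries any term annotation")
    tested = {
        t: genes
        for t, genes in term_sets.items()
        if enrichment_input.min_term_size
        <= len(genes)
        <= enrichment_input.max_term_size
    }
    m = len(tested)
    n_events = sum(counts.values())
    n_universe = len(universe)
    rows = []
    for term, genes in sorted(tested.items()):
        hits = count_term_hits(counts, genes)
        # hit margin counts events; non-hit margin counts unhit genes
        a = hits
        b = n_events - hits
        c = len(genes - set(counts))
        d = n_universe - len(genes) - len(set(counts) - genes)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        expected = n_events * len(genes) / n_universe
        odds = (a * d) / (b * c) if b * c > 0 else math.inf
        rows.append(
            {
                "term": term,
                "term_size": len(genes),
                "count": hits,
                "expected": expected,
                "odds_ratio": odds,
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


def copy_number_expression_correlation(
    cnv_log2: pd.Series, expr_log2: pd.Series
) -> dict:
    """Pearson correlation between per-gene DNA copy number and mRNA
    abundance (both as log2 ratios); two-sided t-test p."""
    shared = cnv_log2.index.intersection(expr_log2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired genes")
    x = cnv_log2.loc[shared].to_numpy(dtype=float)
    y = expr_log2.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": int(len(shared))}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(shared))}


def transcriptome_divergence(profiles: Sequence[ExpressionProfile]) -> dict:
    """Distribution of pairwise Pearson correlations between profiles.

    Low pairwise correlation means divergent transcriptional states.
    Returns all C(n,2) correlations plus summary quantiles.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    genes = profiles[0].log2_ratio.index
    mat = np.vstack(
        [p.log2_ratio.reindex(genes).to_numpy(dtype=float) for p in profiles]
    )
    if np.any(~np.isfinite(mat)):
        raise ValueError("profiles do not share a common gene universe")
    pairs = []
    values = []
    for i, j in itertools.combinations(range(len(profiles)), 2):
        r = float(np.corrcoef(mat[i], mat[j])[0, 1])
        pairs.append((profiles[i].sample_id, profiles[j].sample_id))
        values.append(r)
    arr = np.asarray(values)
    return {
        "pairs": pairs,
        "correlations": values,
        "quantiles": {
            q: float(np.quantile(arr, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
        "mean": float(arr.mean()),
    }


def expression_response_filter(
    profiles: Sequence[ExpressionProfile] | pd.DataFrame,
    gene_set: GeneSet,
    min_abs_log2: float = 1.5,
) -> list[str]:
    """Set members with at least one observation of |log2 ratio| above the
    threshold (default 1.5) in any sample — the display filter that keeps
    responsive genes only."""
    if isinstance(profiles, pd.DataFrame):
        mat = profiles
    else:
        mat = pd.DataFrame({p.sample_id: p.log2_ratio for p in profiles})
    missing = sorted(gene_set.members - set(mat.index))
    if missing:
        raise ValueError(f"set members missing from profiles: {missing}")
    sub = mat.loc[sorted(gene_set.members)].abs()
    keep = sub.max(axis=1) > min_abs_log2
    return sorted(sub.index[keep])
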