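"""Combinatorial fitness-landscape analysis over allele combinations.

Given fitness estimates for all 2^k combinations of k alleles (for the
study system, gat1-2 / mep2-2 / lst4-2 on the ancestral background), this
module decomposes the landscape into additive and epistatic terms,
classifies pairwise epistasis (none / magnitude / sign / reciprocal
sign), and enumerates which mutational orderings are selectively
accessible — the route by which sign epistasis constrains the order of
mutation acquisition.

Epistasis is defined on the additive s scale: the expectation for a
combination is the *sum* of its single-mutant selection coefficients, and
epistatic terms are the inclusion-exclusion residuals

    eps_S = sum_{T subseteq S} (-1)^{|S|-|T|} s_T,      s_empty = 0,

which is exactly invertible (s_S = sum of eps over subsets of S).
Standard errors propagate as root-sum-squares of the contributing
measurement errors; significance of fitness differences between measured
genotypes uses a normal z on the propagated se.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitness import FitnessEstimate

__all__ = [
    "FitnessLandscape",
    "FitnessGraph",
    "additive_expectation",
    "epistasis_terms",
    "reconstruct_from_epistasis",
    "classify_pairwise_epistasis",
    "accessible_paths",
    "build_fitness_graph",
    "gnp_sign_epistasis_landscape",
]

MAX_PATH_LOCI = 12


def _key(loci) -> frozenset[str]:
    return frozenset(loci)


@dataclass
class FitnessLandscape:
    """Map from allele combinations to fitness estimates.

    All s values are relative to a common reference (normally the wild
    type, which carries s = 0 by construction).  A measurement made
    against a non-ancestral reference can be re-based by adding the
    reference's own s; such entries are flagged in ``rebased``.
    """

    loci: tuple[str, ...]
    estimates: dict[frozenset[str], FitnessEstimate]
    reference: str = "ancestor"
    rebased: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.estimates = {_key(k): v for k, v in self.estimates.items()}
        for combo in self.estimates:
            unknown = combo - set(self.loci)
            if unknown:
                raise ValueError(f"estimate for unknown loci: {sorted(unknown)}")

    @classmethod
    def from_estimates(
        cls, loci, pairs, reference: str = "ancestor"
    ) -> "FitnessLandscape":
        """Build from ``{loci-iterable: FitnessEstimate}``; adds a wild type
        with s = 0, se = 0 when absent and the reference is ancestral."""
        est = {_key(k): v for k, v in pairs.items()}
        if _key(()) not in est:
            est[_key(())] = FitnessEstimate(0.0, 0.0, (0.0, 0.0), 0, label="wt")
        return cls(loci=tuple(loci), estimates=est, reference=reference)

    def rebase(self, combo, reference_estimate: FitnessEstimate) -> None:
        """Re-express an s measured against a non-ancestral reference on the
        ancestral scale by adding the reference's own s (errors add in
        quadrature)."""
        k = _key(combo)
        e = self.estimates[k]
        s = e.s + reference_estimate.s
        se = math.hypot(e.se, reference_estimate.se)
        half = 1.959963984540054 * se
        self.estimates[k] = FitnessEstimate(
            s, se, (s - half, s + half), e.n_points, e.label, "ancestor"
        )
        self.rebased.add(k)

    def s(self, combo) -> float:
        return self.estimates[_key(combo)].s

    def se(self, combo) -> float:
        return self.estimates[_key(combo)].se

    def is_complete(self) -> bool:
        return all(
            _key(c) in self.estimates
            for r in range(len(self.loci) + 1)
            for c in itertools.combinations(self.loci, r)
        )

    def missing(self) -> list[frozenset[str]]:
        return [
            _key(c)
            for r in range(len(self.loci) + 1)
            for c in itertools.combinations(self.loci, r)
            if _key(c) not in self.estimates
        ]


def additive_expectation(landscape: FitnessLandscape, genotype) -> float:
    """Expected s of a combination by summing single-mutant effects."""
    combo = _key(genotype)
    total = 0.0
    for locus in combo:
        k = _key({locus})
        if k not in landscape.estimates:
            raise ValueError(f"single mutant for {locus} not measured")
        total += landscape.estimates[k].s
    return total


def epistasis_terms(landscape: FitnessLandscape) -> dict[frozenset[str], dict]:
    """Inclusion-exclusion decomposition of a complete hypercube.

    Returns for every non-empty locus subset S its epistatic term eps_S
    and a root-sum-square propagated standard error.  Singleton terms are
    the single-mutant effects themselves; |S| >= 2 terms vanish iff the
    landscape is additive.
    """
    if not landscape.is_complete():
        raise ValueError(
            f"incomplete landscape; missing genotypes: "
            f"{[sorted(m) for m in landscape.missing()]}"
        )
    out: dict[frozenset[str], dict] = {}
    for r in range(1, len(landscape.loci) + 1):
        for combo in itertools.combinations(landscape.loci, r):
            S = _key(combo)
            eps = 0.0
            var = 0.0
            for sub_r in range(len(S) + 1):
                for sub in itertools.combinations(sorted(S), sub_r):
                    sign = (-1) ** (len(S) - len(sub))
                    eps += sign * landscape.s(sub)
                    var += landscape.se(sub) ** 2
            out[S] = {"epsilon": eps, "se": math.sqrt(var)}
    return out


def reconstruct_from_epistasis(
    loci, terms: dict[frozenset[str], dict]
) -> dict[frozenset[str], float]:
    """Invert the decomposition: s_S = sum of eps_T over subsets T of S."""
    out = {_key(()): 0.0}
    for r in range(1, len(loci) + 1):
        for combo in itertools.combinations(loci, r):
            S = _key(combo)
            s = 0.0
            for sub_r in range(1, len(S) + 1):
                for sub in itertools.combinations(sorted(S), sub_r):
                    s += terms[_key(sub)]["epsilon"]
            out[S] = s
    return out


def _delta(landscape: FitnessLandscape, background, locus) -> tuple[float, float]:
    """Effect of adding ``locus`` to ``background``: (delta s, propagated se)."""
    b = _key(background)
    w = b | {locus}
    ds = landscape.s(w) - landscape.s(b)
    se = math.hypot(landscape.se(w), landscape.se(b))
    return ds, se


def classify_pairwise_epistasis(
    landscape: FitnessLandscape,
    locus_pair: tuple[str, str],
    background=(),
    alpha: float = 0.05,
) -> dict:
    """Classify the interaction between two loci in a fixed background.

    Each mutation's effect is measured in both backgrounds (with and
    without the partner); z-tests on the propagated errors decide
    significance.  Sign epistasis: one locus's effect is significantly
    positive in one background and significantly negative in the other;
    reciprocal sign: true for both loci; magnitude: effects share sign
    but differ significantly; none otherwise.
    """
    a, b = locus_pair
    bg = _key(background)
    needed = [bg, bg | {a}, bg | {b}, bg | {a, b}]
    missing = [sorted(k) for k in needed if k not in landscape.estimates]
    if missing:
        raise ValueError(f"missing genotypes for pair classification: {missing}")
    zcrit = stats.norm.ppf(1 - alpha / 2)

    def effect(locus, other_present):
        base = bg | ({a, b} - {locus} if other_present else set())
        ds, se = _delta(landscape, base, locus)
        z = ds / se if se > 0 else math.copysign(math.inf, ds) if ds else 0.0
        return {"delta_s": ds, "se": se, "z": z}

    report = {
        a: {"without_partner": effect(a, False), "with_partner": effect(a, True)},
        b: {"without_partner": effect(b, False), "with_partner": effect(b, True)},
    }

    def sign_flips(locus):
        e0 = report[locus]["without_partner"]
        e1 = report[locus]["with_partner"]
        pos0, neg0 = e0["z"] > zcrit, e0["z"] < -zcrit
        pos1, neg1 = e1["z"] > zcrit, e1["z"] < -zcrit
        return (pos0 and neg1) or (neg0 and pos1)

    def magnitude_differs(locus):
        e0 = report[locus]["without_partner"]
        e1 = report[locus]["with_partner"]
        dd = e1["delta_s"] - e0["delta_s"]
        se = math.hypot(e0["se"], e1["se"])
        return se > 0 and abs(dd / se) > zcrit

    flips = {locus: sign_flips(locus) for locus in (a, b)}
    if flips[a] and flips[b]:
        kind = "reciprocal_sign"
    elif flips[a] or flips[b]:
        kind = "sign"
    elif magnitude_differs(a) or magnitude_differs(b):
        kind = "magnitude"
    else:
        kind = "none"
    return {"classification": kind, "effects": report, "alpha": alpha}


def accessible_paths(
    landscape: FitnessLandscape,
    source=(),
    target=None,
    alpha: float | None = 0.05,
) -> dict:
    """Enumerate mutational orderings from source to target genotype.

    All orderings of the remaining loci are enumerated (k! of them).  A
    step is *favored* when the fitness gain is positive — significantly
    at ``alpha`` using the propagated z when alpha is given, by point
    estimate when ``alpha=None``.  A path is accessible iff every step is
    favored.  Returns the accessible and blocked orderings, the latter
    with their first blocking step.
    """
    src = _key(source)
    tgt = _key(target) if target is not None else _key(landscape.loci)
    steps_loci = sorted(tgt - src)
    if len(steps_loci) > MAX_PATH_LOCI:
        raise ValueError(
            f"{len(steps_loci)} loci would enumerate {math.factorial(len(steps_loci))} "
            "orderings; restrict the locus set below "
            f"{MAX_PATH_LOCI + 1} loci or analyze the fitness graph instead"
        )
    zcrit = stats.norm.ppf(1 - alpha / 2) if alpha is not None else None

    accessible, blocked = [], []
    for order in itertools.permutations(steps_loci):
        current = set(src)
        verdicts = []
        first_block = None
        for locus in order:
            ds, se = _delta(landscape, current, locus)
            if zcrit is None:
                favored = ds > 0
            else:
                favored = se > 0 and ds / se > zcrit
            verdicts.append({"locus": locus, "delta_s": ds, "favored": favored})
            if not favored and first_block is None:
                first_block = locus
            current.add(locus)
        entry = {"order": order, "steps": verdicts}
        if first_block is None:
            accessible.append(entry)
        else:
            entry["first_blocking_step"] = first_block
            blocked.append(entry)
    return {
        "accessible": accessible,
        "blocked": blocked,
        "n_orderings": math.factorial(len(steps_loci)),
        "alpha": alpha,
    }


@dataclass
class FitnessGraph:
    """Hypercube of genotypes with per-edge fitness differences."""

    nodes: list[frozenset[str]]
    edges: list[dict]  # low, high, delta_s, se, z, favored, weight

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "from": "+".join(sorted(e["low"])) or "wt",
                    "to": "+".join(sorted(e["high"])) or "wt",
                    "delta_s": e["delta_s"],
                    "se": e["se"],
                    "z": e["z"],
                    "favored": e["favored"],
                    "weight": e["weight"],
                }
                for e in self.edges
            ]
        )

    def to_dot(self) -> str:
        """DOT text for the cube diagram: solid favored edges, dashed
        disfavored, penwidth proportional to |delta s|."""
        lines = ["digraph fitness_landscape {", "  rankdir=BT;"]
        for n in self.nodes:
            name = "+".join(sorted(n)) or "wt"
            lines.append(f'  "{name}";')
        max_w = max((e["weight"] for e in self.edges), default=1.0) or 1.0
        for e in self.edges:
            lo = "+".join(sorted(e["low"])) or "wt"
            hi = "+".join(sorted(e["high"])) or "wt"
            style = "solid" if e["favored"] else "dashed"
            penwidth = 0.5 + 4.5 * e["weight"] / max_w
            lines.append(
                f'  "{lo}" -> "{hi}" [style={style}, penwidth={penwidth:.2f}, '
                f'label="{e["delta_s"]:+.3f}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_fitness_graph(
    landscape: FitnessLandscape, alpha: float | None = 0.05
) -> FitnessGraph:
    """Annotate every Hamming-distance-1 genotype pair with its fitness step.

    A complete k-locus landscape yields the k-hypercube with k * 2^(k-1)
    edges.  An edge is favored when the gain from low to high genotype is
    positive (significant at ``alpha`` when given); a gain of exactly 0 is
    neutral, not favored.  Edge weight is |delta s|.
    """
    combos = [
        _key(c)
        for r in range(len(landscape.loci) + 1)
        for c in itertools.combinations(landscape.loci, r)
        if _key(c) in landscape.estimates
    ]
    zcrit = stats.norm.ppf(1 - alpha / 2) if alpha is not None else None
    edges = []
    for low in combos:
        for locus in sorted(set(landscape.loci) - low):
            high = low | {locus}
            if high not in landscape.estimates:
                continue
            ds, se = _delta(landscape, low, locus)
            z = ds / se if se > 0 else (math.copysign(math.inf, ds) if ds else 0.0)
            if zcrit is None:
                favored = ds > 0
            else:
                favored = se > 0 and z > zcrit
            edges.append(
                {
                    "low": low,
                    "high": high,
                    "delta_s": ds,
                    "se": se,
                    "z": z,
                    "favored": favored,
                    "weight": abs(ds),
                }
            )
    return FitnessGraph(nodes=combos, edges=edges)


def gnp_sign_epistasis_landscape(se: float = 0.01) -> FitnessLandscape:
    """Synthetic three-locus landscape with the gene-network-polymorphism
    sign-epistasis pattern.

    A constructed (synthetic) landscape over loci named gat1 / mep2 /
    lst4 reproducing the qualitative interaction structure of the
    recurrently selected three-locus genotype: gat1 and mep2 are
    individually beneficial, lst4 is neutral alone, shows positive
    epistasis with either single mutant, and is deleterious on the
    gat1+mep2 double — so only mutational orderings that place lst4
    second are selectively accessible.  The s values are this package's
    own choices (the source measurements are not tabulated numerically);
    only the sign pattern is meaningful.
    """
    values = {
        (): 0.0,
        ("gat1",): 0.27,
        ("mep2",): 0.18,
        ("lst4",): 0.005,
        ("gat1", "mep2"): 0.47,
        ("gat1", "lst4"): 0.40,
        ("mep2", "lst4"): 0.33,
        ("gat1", "mep2", "lst4"): 0.44,
    }
    pairs = {}
    for combo, s in values.items():
        err = 0.0 if combo == () else se
        half = 1.959963984540054 * err
        pairs[combo] = FitnessEstimate(
            s=s, se=err, ci95=(s - half, s + half), n_points=9,
            label="+".join(combo) or "wt",
        )
    return FitnessLandscape.from_estimates(("gat1", "lst4", "mep2"), pairs)
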