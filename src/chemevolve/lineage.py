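"""Allele-trajectory clustering and genotype-dynamics reconstruction.

Mutations that arise on the same genetic background move through an
asexual population together, so their allele-frequency trajectories are
nearly identical.  Trajectories are merged into clusters when every pair
satisfies both criteria: Pearson correlation of the time series above
``r_min`` (default 0.97) and terminal deep-sequencing frequencies within
``max_final_diff`` (default 4%).  Cluster representatives are nested into
a genotype tree by frequency containment (a mutation arising inside a
lineage can never exceed its carrier's frequency), introduction times are
read off at the 5% detection floor, and exclusive ("Muller") genotype
frequencies are exported by subtracting each node's children.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlleleTrajectory",
    "TrajectoryCluster",
    "GenotypeTree",
    "TreeNode",
    "trajectories_from_table",
    "cluster_trajectories",
    "order_within_cluster",
    "infer_genotype_nesting",
    "estimate_introduction_times",
    "to_muller_table",
]

ROOT_ID = "ancestor"


@dataclass
class AlleleTrajectory:
    """Observed frequency time series of one mutation."""

    mutation_id: str
    locus: str
    freq_by_generation: dict[int, float]
    final_deepseq_freq: float | None = None
    clone_memberships: frozenset[str] | None = None

    def __post_init__(self) -> None:
        bad = {g: f for g, f in self.freq_by_generation.items() if not 0 <= f <= 1}
        if bad:
            raise ValueError(f"{self.mutation_id}: frequencies outside [0,1]: {bad}")

    @property
    def generations(self) -> list[int]:
        return sorted(self.freq_by_generation)

    def values(self, grid: list[int] | None = None) -> np.ndarray:
        grid = grid if grid is not None else self.generations
        return np.array([self.freq_by_generation[g] for g in grid])

    def is_constant(self) -> bool:
        v = self.values()
        return bool(np.all(v == v[0]))


def trajectories_from_table(df: pd.DataFrame) -> list[AlleleTrajectory]:
    """Build trajectories from a long table.

    Expects columns ``mutation_id, locus, generation, frequency`` and
    optionally ``final_deepseq_freq`` and ``clones`` (comma-separated
    clone ids carrying the mutation).
    """
    out = []
    for mid, grp in df.groupby("mutation_id", sort=True):
        final = None
        if "final_deepseq_freq" in grp.columns:
            final = float(grp["final_deepseq_freq"].iloc[0])
        clones = None
        if "clones" in grp.columns and isinstance(grp["clones"].iloc[0], str):
            clones = frozenset(grp["clones"].iloc[0].split(","))
        out.append(
            AlleleTrajectory(
                mutation_id=str(mid),
                locus=str(grp["locus"].iloc[0]),
                freq_by_generation={
                    int(g): float(f)
                    for g, f in zip(grp["generation"], grp["frequency"])
                },
                final_deepseq_freq=final,
                clone_memberships=clones,
            )
        )
    return out


@dataclass
class TrajectoryCluster:
    """A group of co-moving mutations treated as one genotype marker."""

    members: list[AlleleTrajectory]
    grid: list[int]

    @property
    def cluster_id(self) -> str:
        return min(m.mutation_id for m in self.members)

    @property
    def representative(self) -> np.ndarray:
        """Pointwise mean frequency of the members over the shared grid."""
        return np.mean([m.values(self.grid) for m in self.members], axis=0)

    @property
    def final_deepseq_freq(self) -> float:
        vals = [m.final_deepseq_freq for m in self.members if m.final_deepseq_freq is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def clone_memberships(self) -> frozenset[str] | None:
        sets = [m.clone_memberships for m in self.members if m.clone_memberships]
        if not sets:
            return None
        return frozenset().union(*sets)

    def ordered_member_ids(self) -> list[str]:
        return [m.mutation_id for m in order_within_cluster(self)[0]]


def _pair_mergeable(
    a: AlleleTrajectory,
    b: AlleleTrajectory,
    grid: list[int],
    r_min: float,
    max_final_diff: float,
    require_same_clone: bool,
) -> tuple[bool, float]:
    va, vb = a.values(grid), b.values(grid)
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        return False, float("nan")  # Pearson r undefined for a constant series
    r = float(np.corrcoef(va, vb)[0, 1])
    if not r > r_min:
        return False, r
    if a.final_deepseq_freq is None or b.final_deepseq_freq is None:
        return False, r
    if not abs(a.final_deepseq_freq - b.final_deepseq_freq) < max_final_diff:
        return False, r
    if require_same_clone:
        if not (a.clone_memberships and b.clone_memberships):
            return False, r
        if not a.clone_memberships & b.clone_memberships:
            return False, r
    return True, r


def cluster_trajectories(
    trajs: list[AlleleTrajectory],
    r_min: float = 0.97,
    max_final_diff: float = 0.04,
    require_same_clone: bool = False,
) -> list[TrajectoryCluster]:
    """Agglomerative average-linkage merging of co-moving trajectories.

    A merge of two clusters is allowed only if *every* cross pair of
    members satisfies both thresholds (and shares a clone when
    ``require_same_clone``); the all-pairs criterion prevents chaining of
    dissimilar trajectories through intermediates.  Merges are applied in
    order of descending average cross correlation with lexicographic
    mutation-id tie-breaks, so the result is deterministic and independent
    of input order.
    """
    trajs = sorted(trajs, key=lambda t: t.mutation_id)
    grids = {tuple(t.generations) for t in trajs}
    if len(grids) > 1:
        raise ValueError("all trajectories must share one timepoint grid")
    grid = list(grids.pop()) if grids else []

    for t in trajs:
        if t.is_constant():
            warnings.warn(
                f"trajectory {t.mutation_id} is constant; Pearson correlation is "
                "undefined and it will never be merged",
                stacklevel=2,
            )

    n = len(trajs)
    ok = np.zeros((n, n), dtype=bool)
    corr = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        mergeable, r = _pair_mergeable(
            trajs[i], trajs[j], grid, r_min, max_final_diff, require_same_clone
        )
        ok[i, j] = ok[j, i] = mergeable
        corr[i, j] = corr[j, i] = r

    clusters: list[list[int]] = [[i] for i in range(n)]
    while True:
        best = None  # (avg_r, tie_id, ci, cj)
        for ci, cj in itertools.combinations(range(len(clusters)), 2):
            pairs = [(i, j) for i in clusters[ci] for j in clusters[cj]]
            if not all(ok[i, j] for i, j in pairs):
                continue
            avg_r = float(np.mean([corr[i, j] for i, j in pairs]))
            tie_id = min(trajs[i].mutation_id for i in clusters[ci] + clusters[cj])
            better = (
                best is None
                or avg_r > best[0]
                or (avg_r == best[0] and tie_id < best[1])
            )
            if better:
                best = (avg_r, tie_id, ci, cj)
        if best is None:
            break
        _, _, ci, cj = best
        clusters[ci] = sorted(clusters[ci] + clusters[cj])
        del clusters[cj]

    return [
        TrajectoryCluster(members=[trajs[i] for i in idxs], grid=grid)
        for idxs in sorted(clusters, key=lambda idxs: trajs[idxs[0]].mutation_id)
    ]


def order_within_cluster(
    cluster: TrajectoryCluster,
) -> tuple[list[AlleleTrajectory], list[tuple[str, str]]]:
    """Temporal order of a cluster's mutations from terminal frequencies.

    Within a clonal lineage the earlier mutation is carried by every cell
    that carries the later one, so the earlier mutation has the higher
    terminal deep-sequencing frequency.  Returns (members ordered by
    descending final frequency, list of tied pairs flagged as unordered).
    """
    missing = [m.mutation_id for m in cluster.members if m.final_deepseq_freq is None]
    if missing:
        raise ValueError(f"missing terminal deep-seq frequencies: {missing}")
    ordered = sorted(
        cluster.members,
        key=lambda m: (-m.final_deepseq_freq, m.mutation_id),
    )
    ties = [
        (a.mutation_id, b.mutation_id)
        for a, b in itertools.combinations(ordered, 2)
        if a.final_deepseq_freq == b.final_deepseq_freq
    ]
    return ordered, ties


@dataclass
class TreeNode:
    """One genotype (lineage) in the inferred genotype tree."""

    node_id: str
    cluster: TrajectoryCluster | None
    parent: str | None
    raw: np.ndarray  # cluster (inclusive) frequency over the grid
    children: list[str] = field(default_factory=list)
    introduction_generation: int | None = None
    left_censored: bool = False

    @property
    def depth_key(self) -> str:
        return self.node_id


class GenotypeTree:
    """Nested lineage structure with per-node inclusive frequencies."""

    def __init__(self, grid: list[int]) -> None:
        self.grid = list(grid)
        root = TreeNode(ROOT_ID, None, None, np.ones(len(grid)))
        self.nodes: dict[str, TreeNode] = {ROOT_ID: root}

    def add(self, node: TreeNode) -> None:
        self.nodes[node.node_id] = node
        self.nodes[node.parent].children.append(node.node_id)

    def depth(self, node_id: str) -> int:
        d, cur = 0, self.nodes[node_id]
        while cur.parent is not None:
            d += 1
            cur = self.nodes[cur.parent]
        return d

    def edges(self) -> set[tuple[str, str]]:
        return {
            (n.parent, n.node_id) for n in self.nodes.values() if n.parent is not None
        }

    def exclusive_frequency(self, node_id: str) -> np.ndarray:
        node = self.nodes[node_id]
        excl = node.raw.copy()
        for child in node.children:
            excl -= self.nodes[child].raw
        return excl

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": self.grid,
                "nodes": [
                    {
                        "id": n.node_id,
                        "parent": n.parent,
                        "raw_frequency": n.raw.tolist(),
                        "members": (
                            [m.mutation_id for m in n.cluster.members]
                            if n.cluster
                            else []
                        ),
                        "introduction_generation": n.introduction_generation,
                        "left_censored": n.left_censored,
                    }
                    for n in self.nodes.values()
                ],
            }
        )

    def to_newick(self) -> str:
        def render(node_id: str) -> str:
            node = self.nodes[node_id]
            label = node_id
            if node.introduction_generation is not None:
                label += f"[gen={node.introduction_generation}]"
            if not node.children:
                return label
            inner = ",".join(render(c) for c in sorted(node.children))
            return f"({inner}){label}"

        return render(ROOT_ID) + ";"


def infer_genotype_nesting(
    clusters: list[TrajectoryCluster],
    containment_tol: float = 0.05,
) -> GenotypeTree:
    """Greedy containment-based nesting of trajectory clusters.

    Clusters are attached in descending order of their maximum frequency.
    A node can host a cluster only if at every timepoint (i) the node's
    raw frequency dominates the cluster's within ``containment_tol`` and
    (ii) the node's existing children plus the cluster still fit inside
    the node (sibling-sum constraint).  Among admissible hosts the deepest
    is chosen; clusters that fit nowhere below the root become independent
    lineages.  Clone memberships, when present, veto parents whose clones
    do not cover the child's.
    """
    grids = {tuple(c.grid) for c in clusters}
    if len(grids) > 1:
        raise ValueError("clusters must share one timepoint grid")
    tree = GenotypeTree(list(grids.pop()) if grids else [])

    # Parents must be placed before their children.  Containment implies a
    # parent's time-integrated frequency exceeds any child's, and the sum
    # over timepoints averages observation noise, so descending area is a
    # noise-robust topological order (a bare max-frequency ordering ties
    # for parent/child pairs whose sweeps both complete).
    order = sorted(
        clusters,
        key=lambda c: (-float(np.sum(c.representative)), c.cluster_id),
    )
    for cluster in order:
        rep = cluster.representative
        if np.any(rep > 1.0 + containment_tol):
            raise ValueError(
                f"cluster {cluster.cluster_id} exceeds frequency 1: "
                f"max {float(np.max(rep)):.3f}"
            )
        candidates = []
        for node in tree.nodes.values():
            if np.any(node.raw + containment_tol < rep):
                continue
            sibling_sum = rep.copy()
            for child in node.children:
                sibling_sum = sibling_sum + tree.nodes[child].raw
            if np.any(sibling_sum > node.raw + containment_tol):
                continue
            if (
                node.cluster is not None
                and cluster.clone_memberships
                and node.cluster.clone_memberships
                and not cluster.clone_memberships <= node.cluster.clone_memberships
            ):
                continue
            candidates.append(node)
        if candidates:
            # deepest admissible host; ties broken by tightest fit then id
            host = max(
                candidates,
                key=lambda n: (
                    tree.depth(n.node_id),
                    -float(np.sum(n.raw - rep)),
                    n.node_id,
                ),
            )
        else:
            # fits nowhere (noise can break every containment): independent
            # lineage directly under the ancestor
            host = tree.nodes[ROOT_ID]
        tree.add(
            TreeNode(
                node_id=cluster.cluster_id,
                cluster=cluster,
                parent=host.node_id,
                raw=rep,
            )
        )
    return tree


def estimate_introduction_times(
    tree: GenotypeTree,
    detection_floor: float = 0.05,
    interpolate: bool = False,
) -> dict[str, dict]:
    """Earliest sampled generation at which each lineage is detectable.

    A lineage is introduced (for reporting purposes) at the first sampled
    generation where its raw frequency reaches the detection floor
    (default 5%, the reliability limit of Sanger-based frequency
    estimates).  Lineages already at/above the floor at the first sample
    are flagged left-censored; lineages that never reach the floor are
    omitted.  With ``interpolate`` the crossing is placed linearly between
    the flanking samples.
    """
    out: dict[str, dict] = {}
    grid = np.asarray(tree.grid, dtype=float)
    for node in tree.nodes.values():
        if node.parent is None:
            continue
        above = node.raw >= detection_floor
        if not above.any():
            node.introduction_generation = None
            continue
        idx = int(np.argmax(above))
        gen = float(grid[idx])
        censored = idx == 0
        if interpolate and idx > 0:
            f0, f1 = node.raw[idx - 1], node.raw[idx]
            if f1 > f0:
                gen = grid[idx - 1] + (detection_floor - f0) / (f1 - f0) * (
                    grid[idx] - grid[idx - 1]
                )
        node.introduction_generation = int(round(gen))
        node.left_censored = censored
        out[node.node_id] = {
            "generation": gen if interpolate else int(grid[idx]),
            "left_censored": censored,
        }
    return out


def to_muller_table(tree: GenotypeTree, negative_tol: float = 0.05) -> pd.DataFrame:
    """Long-format exclusive genotype frequencies for Muller plotting.

    Each node's exclusive frequency is its raw frequency minus the summed
    raw frequencies of its children; small negative values (observation
    noise) are clipped to 0, violations beyond ``negative_tol`` raise with
    the offending node and timepoint named.  The root row carries the
    residual ancestral fraction.
    """
    rows = []
    for node_id in sorted(tree.nodes, key=lambda k: (tree.depth(k), k)):
        node = tree.nodes[node_id]
        excl = tree.exclusive_frequency(node_id)
        for g, f in zip(tree.grid, excl):
            if f < -negative_tol:
                raise ValueError(
                    f"negative exclusive frequency {f:.3f} for genotype "
                    f"{node_id} at generation {g}"
                )
        excl = np.clip(excl, 0.0, None)
        for g, f in zip(tree.grid, excl):
            rows.append(
                {
                    "generation": int(g),
                    "genotype": node_id,
                    "frequency": float(f),
                    "parent": node.parent if node.parent is not None else "",
                }
            )
    return pd.DataFrame(rows)
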