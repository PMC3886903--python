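"""End-to-end pipeline orchestration.

Runs the stages in dependency order (simulate -> fitness / lineage /
variants / enrich -> landscape) on synthetic data, writing every
intermediate as a plain-text table and recording a JSON manifest with
parameters, seed and per-file checksums.  Reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichxpr, fitness, io, landscape, lineage, synthdata, variants

__all__ = [
    "ConfigValidationError",
    "StageError",
    "DEFAULT_CONFIG",
    "validate_config",
    "gnp_demo_sim_config",
    "true_lineage_tree",
    "run_pipeline",
]


class ConfigValidationError(ValueError):
    """Unknown or invalid configuration key."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "fitness": True,
        "lineage": True,
        "variants": True,
        "enrich": True,
        "landscape": True,
    },
    "simulate": {
        "population_size": 100_000,
        "n_generations": 250,
        "noise_sd": 0.02,
        "detection_floor": 0.05,
        "read_depth": 160,
        "n_genes": 2000,
        "target_set_size": 38,
        "expression_shift": 2.0,
        "expression_noise_sd": 0.5,
        "n_variants": 20,
        "mean_depth": 160.0,
    },
    "fitness": {"input": None},
    "lineage": {
        "input": None,
        "r_min": 0.97,
        "max_final_diff": 0.04,
        "detection_floor": 0.05,
        "containment_tol": 0.05,
    },
    "variants": {
        "input": None,
        "p_cutoff": 1e-8,
        "min_depth_fraction_of_mean": 0.5,
        "min_frequency": 0.05,
    },
    "enrich": {"input": None, "n_perm": 1000},
    "landscape": {"input": None, "alpha": 0.05},
}


def validate_config(config: dict, schema: dict = DEFAULT_CONFIG, prefix: str = "") -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    merged = {}
    for key, default in schema.items():
        if isinstance(default, dict) and key != "stages":
            merged[key] = validate_config(
                config.get(key, {}) or {}, default, prefix=f"{prefix}{key}."
            )
        elif key == "stages":
            user = config.get(key, {}) or {}
            for k in user:
                if k not in default:
                    raise ConfigValidationError(f"unknown stage: {prefix}stages.{k}")
            merged[key] = {**default, **user}
        else:
            merged[key] = config.get(key, default)
    for key in config:
        if key not in schema:
            raise ConfigValidationError(f"unknown configuration key: {prefix}{key}")
    return merged


def gnp_demo_sim_config(
    seed: int | None = None,
    population_size: int = 100_000,
    deterministic: bool = False,
    n_generations: int = 250,
) -> synthdata.SimConfig:
    """Simulation scenario of a clonally interfering three-locus genotype.

    Two competing lineages arise on the ancestral background (a gat1-like
    and a mep2-like driver, each with a tightly linked hitchhiker so that
    trajectory clustering has work to do); each later gains a second
    mutation nested inside it.  The sweep strengths and origin times are
    chosen so every lineage is detectable (>5%) at several of the sampled
    generations while none fixes — alternating partial (soft) sweeps.
    """
    S = synthdata.ScheduledMutation
    scheduled = [
        S(5, (), "gat1_a", 0.10, init_freq=2e-3),
        S(6, ("gat1_a",), "hitch_a", 0.0, init_freq=1.0),
        S(15, (), "mep2_b", 0.12, init_freq=2e-3),
        S(16, ("mep2_b",), "hitch_b", 0.0, init_freq=1.0),
        S(45, ("mep2_b", "hitch_b"), "gat1_b2", 0.06, init_freq=2e-3),
        S(95, ("gat1_a", "hitch_a"), "lst4_a", 0.12, init_freq=2e-3),
    ]
    return synthdata.SimConfig(
        population_size=population_size,
        n_generations=n_generations,
        scheduled_mutations=scheduled,
        deterministic=deterministic,
        seed=seed,
    )


def true_lineage_tree(result: synthdata.EvolutionResult) -> set[tuple[str, str]]:
    """Cluster-level truth edges of a simulation, for tree-recovery checks.

    Mutations whose carrier-frequency vectors coincide at every sampled
    generation belong to one cluster (they are indistinguishable markers
    of the same genotype); each cluster's parent is the cluster of its
    nearest mutated ancestor, or the ancestor root.  Edges are keyed the
    same way the inference names nodes: by the lexicographically smallest
    member mutation id.
    """
    gens = list(result.config.sample_generations)
    muts = [n for n in result.nodes if n.locus is not None]
    vecs = {
        n.id: np.array([result.mutation_frequency(n.id, g) for g in gens])
        for n in muts
    }
    cluster_of: dict[int, int] = {}
    clusters: list[list[int]] = []
    for n in muts:
        placed = False
        for ci, members in enumerate(clusters):
            if np.allclose(vecs[n.id], vecs[members[0]], atol=1e-9):
                # only co-lineage mutations may share a cluster
                anc = _mutated_ancestors(result, n)
                if members[0] in anc or n.id in _mutated_ancestors(
                    result, result.node(members[0])
                ):
                    members.append(n.id)
                    cluster_of[n.id] = ci
                    placed = True
                    break
        if not placed:
            cluster_of[n.id] = len(clusters)
            clusters.append([n.id])

    def cluster_name(ci: int) -> str:
        return min(f"m{nid}" for nid in clusters[ci])

    edges = set()
    for ci, members in enumerate(clusters):
        oldest = min(members)
        parent = None
        for anc_id in _mutated_ancestors(result, result.node(oldest)):
            if cluster_of.get(anc_id) is not None and cluster_of[anc_id] != ci:
                parent = cluster_of[anc_id]
                break
        parent_name = lineage.ROOT_ID if parent is None else cluster_name(parent)
        edges.add((parent_name, cluster_name(ci)))
    return edges


def lineage_recovery(result: synthdata.EvolutionResult, tree) -> float:
    """Fraction of mutations whose ancestry the inferred tree recovers.

    A mutation's inferred ancestry (co-members of its cluster plus the
    members of every node on its path to the root) must be consistent
    with the true genealogy: it contains at least one true mutated
    ancestor (when a distinguishable one exists) and nothing that is
    neither ancestor nor descendant.  Mutations with identical true
    trajectories are markers of one genotype whose internal order is
    unidentifiable from frequency data, so the ancestor requirement is
    waived within such marker groups; a split or merged marker pair is
    thus not penalized when the genealogy is right.
    """
    node_of: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for tn in tree.nodes.values():
        ids = {m.mutation_id for m in tn.cluster.members} if tn.cluster else set()
        members[tn.node_id] = ids
        for mid in ids:
            node_of[mid] = tn.node_id

    def inferred_ancestors(mid: str) -> set[str]:
        tn = tree.nodes[node_of[mid]]
        out = set(members[tn.node_id]) - {mid}
        while tn.parent is not None:
            tn = tree.nodes[tn.parent]
            out |= members[tn.node_id]
        return out

    gens = list(result.config.sample_generations)
    vec = {
        n.id: np.array([result.mutation_frequency(n.id, g) for g in gens])
        for n in result.nodes
        if n.locus is not None
    }

    n_checked = 0
    n_ok = 0
    for node in result.nodes:
        if node.locus is None:
            continue
        mid = f"m{node.id}"
        n_checked += 1
        if mid not in node_of:
            continue  # dropped (e.g. never detected): counts as a miss
        true_anc = {f"m{i}" for i in _mutated_ancestors(result, node)}
        true_desc = {f"m{i}" for i in result.carrier_ids(node.id)} - {mid}
        co_markers = {
            f"m{i}"
            for i in vec
            if i != node.id and np.allclose(vec[i], vec[node.id], atol=1e-9)
        } & (true_anc | true_desc)
        inferred = inferred_ancestors(mid)
        ok = inferred <= true_anc | true_desc
        if true_anc - co_markers:
            ok = ok and bool(inferred & true_anc)
        n_ok += bool(ok)
    return n_ok / n_checked if n_checked else float("nan")


def _mutated_ancestors(result, node) -> list[int]:
    """Ids of mutated ancestors of ``node``, nearest first (excluding itself)."""
    out = []
    cur = node
    while cur.parent is not None:
        cur = result.node(cur.parent)
        if cur.locus is not None:
            out.append(cur.id)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Execute the enabled stages and write a reproducibility manifest.

    Returns the manifest dict (also written to ``manifest.json``): seed,
    validated parameters, per-stage summaries and a checksum for every
    output file.
    """
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "seed": seed,
        "config": cfg,
        "outputs": {},
        "stages": {},
    }
    files: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        files[name] = path

    stage = "simulate"
    try:
        if cfg["stages"]["simulate"]:
            manifest["stages"]["simulate"] = _stage_simulate(cfg, seed, out, record)
        stage = "fitness"
        if cfg["stages"]["fitness"]:
            manifest["stages"]["fitness"] = _stage_fitness(cfg, out, record)
        stage = "lineage"
        if cfg["stages"]["lineage"]:
            manifest["stages"]["lineage"] = _stage_lineage(cfg, out, record)
        stage = "variants"
        if cfg["stages"]["variants"]:
            manifest["stages"]["variants"] = _stage_variants(cfg, seed, out, record)
        stage = "enrich"
        if cfg["stages"]["enrich"]:
            manifest["stages"]["enrich"] = _stage_enrich(cfg, seed, out, record)
        stage = "landscape"
        if cfg["stages"]["landscape"]:
            manifest["stages"]["landscape"] = _stage_landscape(cfg, out, record)
    except (ConfigValidationError, StageError):
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    for name, path in files.items():
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(cfg, seed, out, record) -> dict:
    p = cfg["simulate"]
    sim_cfg = gnp_demo_sim_config(
        seed=seed,
        population_size=int(p["population_size"]),
        n_generations=int(p["n_generations"]),
    )
    result = synthdata.simulate_chemostat_evolution(sim_cfg)
    (out / "truth.json").write_text(result.to_json())
    record("truth", out / "truth.json")

    model = synthdata.ObservationModel(
        mode="sanger",
        noise_sd=float(p["noise_sd"]),
        detection_floor=float(p["detection_floor"]),
        read_depth=int(p["read_depth"]),
    )
    trajs = synthdata.observe_allele_frequencies(result, model, seed=seed + 1)
    io.write_trajectories(trajs, out / "trajectories.tsv")
    record("trajectories", out / "trajectories.tsv")

    # competition assays for all 2^3 combinations of the GNP alleles
    demo = landscape.gnp_sign_epistasis_landscape()
    rows = []
    for i, (combo, est) in enumerate(
        sorted(demo.estimates.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ):
        series = synthdata.simulate_competition(
            est.s, noise_sd=0.05, seed=seed + 10 + i,
            label="+".join(sorted(combo)) or "wt",
        )
        for t, r in zip(series.generations, series.ratio):
            rows.append(
                {"assay_id": series.label, "generation": t, "ratio": r,
                 "reference_genotype": "ancestor"}
            )
    pd.DataFrame(rows).to_csv(out / "assays.tsv", sep="\t", index=False)
    record("assays", out / "assays.tsv")

    expr, target = synthdata.simulate_expression(
        n_genes=int(p["n_genes"]),
        target_set_size=int(p["target_set_size"]),
        shift=float(p["expression_shift"]),
        noise_sd=float(p["expression_noise_sd"]),
        seed=seed + 2,
    )
    io.write_expression_matrix(expr, out / "expression.tsv")
    record("expression", out / "expression.tsv")
    (out / "target_set.txt").write_text("\n".join(target) + "\n")
    record("target_set", out / "target_set.txt")

    ann = synthdata.generate_annotation(seed=seed + 3)
    io.write_annotation_gff(ann, out / "annotation.gff")
    record("annotation", out / "annotation.gff")
    io.write_term_annotation(ann.terms, out / "terms.tsv")
    record("terms", out / "terms.tsv")

    calls, anc, other = synthdata.simulate_variant_panel(
        n_variants=int(p["n_variants"]),
        mean_depth=float(p["mean_depth"]),
        seed=seed + 4,
    )
    io.write_vcf(calls, out / "population_calls.vcf")
    record("population_calls", out / "population_calls.vcf")
    (out / "ancestor_calls.json").write_text(json.dumps(sorted(anc)))
    (out / "other_population_calls.json").write_text(json.dumps(sorted(other)))
    record("ancestor_calls", out / "ancestor_calls.json")
    record("other_population_calls", out / "other_population_calls.json")
    return {
        "n_mutations": sum(1 for n in result.nodes if n.locus),
        "n_trajectory_rows": int(len(trajs)),
        "n_assays": len(demo.estimates),
        "n_genes": int(p["n_genes"]),
        "n_variant_calls": len(calls),
    }


def _stage_fitness(cfg, out, record) -> dict:
    path = cfg["fitness"]["input"] or out / "assays.tsv"
    series = io.read_competitions(path)
    estimates = [fitness.estimate_selection_coefficient(s) for s in series]
    io.write_fitness_estimates(estimates, out / "fitness_estimates.tsv")
    record("fitness_estimates", out / "fitness_estimates.tsv")
    return {
        "n_assays": len(estimates),
        "s_range": [min(e.s for e in estimates), max(e.s for e in estimates)],
    }


def _stage_lineage(cfg, out, record) -> dict:
    p = cfg["lineage"]
    path = p["input"] or out / "trajectories.tsv"
    trajs = lineage.trajectories_from_table(io.read_trajectories(path))
    trajs = [t for t in trajs if not (t.is_constant() and t.values()[0] == 0.0)]
    clusters = lineage.cluster_trajectories(
        trajs,
        r_min=float(p["r_min"]),
        max_final_diff=float(p["max_final_diff"]),
    )
    tree = lineage.infer_genotype_nesting(
        clusters, containment_tol=float(p["containment_tol"])
    )
    lineage.estimate_introduction_times(
        tree, detection_floor=float(p["detection_floor"])
    )
    (out / "genotype_tree.json").write_text(tree.to_json())
    record("genotype_tree", out / "genotype_tree.json")
    (out / "genotype_tree.nwk").write_text(tree.to_newick() + "\n")
    record("genotype_tree_newick", out / "genotype_tree.nwk")
    muller = lineage.to_muller_table(tree)
    muller.to_csv(out / "muller.tsv", sep="\t", index=False)
    record("muller", out / "muller.tsv")
    return {"n_trajectories": len(trajs), "n_clusters": len(clusters),
            "n_edges": len(tree.edges())}


def _stage_variants(cfg, seed, out, record) -> dict:
    p = cfg["variants"]
    path = p["input"] or out / "population_calls.vcf"
    calls = io.read_vcf(path)
    anc = {
        tuple(k) for k in json.loads((out / "ancestor_calls.json").read_text())
    } if (out / "ancestor_calls.json").exists() else set()
    other = {
        tuple(k)
        for k in json.loads((out / "other_population_calls.json").read_text())
    } if (out / "other_population_calls.json").exists() else set()
    mean_depth = float(np.mean([c.total_count for c in calls])) if calls else 1.0
    fc = variants.FilterConfig(
        p_cutoff=float(p["p_cutoff"]),
        min_depth_fraction_of_mean=float(p["min_depth_fraction_of_mean"]),
        min_frequency=float(p["min_frequency"]),
    )
    retained, rejected = variants.filter_population_variants(
        calls, anc, other, mean_depth=mean_depth, config=fc
    )
    io.write_vcf(retained, out / "retained_calls.vcf")
    record("retained_calls", out / "retained_calls.vcf")
    pd.DataFrame(
        [
            {
                "chromosome": r["call"].chromosome,
                "position": r["call"].position,
                "alt": r["call"].alt,
                "reason": r["reason"],
            }
            for r in rejected
        ]
    ).to_csv(out / "rejected_calls.tsv", sep="\t", index=False)
    record("rejected_calls", out / "rejected_calls.tsv")

    spectrum = {
        "coding_bias_p_two_sided": variants.coding_bias_test(60, 72),
        "coding_bias_p_greater": variants.coding_bias_test(
            60, 72, alternative="greater"
        ),
        "nonsynonymous_p_two_sided": variants.nonsynonymous_fraction_test(52, 72),
        "mean_snps_per_clone": 72 / 18,
        "mean_indels_per_clone": 8 / 18,
        "expected_snp_burden": variants.expected_snp_burden(),
        "detection_power_160x_5pct": variants.detection_power(160, 0.05, 3),
    }
    (out / "mutation_spectrum.json").write_text(json.dumps(spectrum, indent=2))
    record("mutation_spectrum", out / "mutation_spectrum.json")
    return {"n_calls": len(calls), "n_retained": len(retained),
            "n_rejected": len(rejected)}


def _stage_enrich(cfg, seed, out, record) -> dict:
    p = cfg["enrich"]
    path = p["input"] or out / "expression.tsv"
    expr = io.read_expression_matrix(path)
    target = (out / "target_set.txt").read_text().split()
    profile = enrichxpr.ExpressionProfile(
        sample_id="sample1",
        environment="ammonium",
        log2_ratio=expr.iloc[:, 0],
    )
    gene_set = enrichxpr.GeneSet("target", target)
    div = enrichxpr.gene_set_divergence_test(
        profile, gene_set, n_perm=int(p["n_perm"]), seed=seed + 5
    )
    terms = io.read_term_annotation(out / "terms.tsv")
    universe = list(expr.index)
    # mutated loci: the target set's first few genes with one multi-allele locus
    locus_counts = {g: 1 for g in target[:5]}
    if target:
        locus_counts[target[0]] = 2
    annotated = set().union(*terms.values()) if terms else set()
    locus_counts = {g: c for g, c in locus_counts.items() if g in annotated}
    enr_summary: dict = {"divergence": div}
    if locus_counts:
        enr = enrichxpr.functional_enrichment(
            enrichxpr.EnrichmentInput(locus_counts=locus_counts, term_genes=terms),
            universe=universe,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        record("enrichment", out / "enrichment.tsv")
        enr_summary["n_terms_tested"] = int(len(enr))
    (out / "divergence.json").write_text(json.dumps(div, indent=2))
    record("divergence", out / "divergence.json")
    return enr_summary


def _stage_landscape(cfg, out, record) -> dict:
    p = cfg["landscape"]
    path = p["input"] or out / "fitness_estimates.tsv"
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"assay_id": "genotype"})
    tmp = out / "_landscape_input.tsv"
    df.to_csv(tmp, sep="\t", index=False)
    scape = io.read_landscape_table(tmp)
    tmp.unlink()
    alpha = float(p["alpha"])
    eps = landscape.epistasis_terms(scape)
    pd.DataFrame(
        [
            {"loci": "+".join(sorted(k)), "order": len(k),
             "epsilon": v["epsilon"], "se": v["se"]}
            for k, v in sorted(eps.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
    ).to_csv(out / "epistasis.tsv", sep="\t", index=False)
    record("epistasis", out / "epistasis.tsv")

    paths = landscape.accessible_paths(scape, alpha=alpha)
    rows = []
    for entry in paths["accessible"]:
        rows.append({"order": ">".join(entry["order"]), "accessible": True,
                     "first_blocking_step": ""})
    for entry in paths["blocked"]:
        rows.append({"order": ">".join(entry["order"]), "accessible": False,
                     "first_blocking_step": entry["first_blocking_step"]})
    pd.DataFrame(rows).to_csv(out / "paths.tsv", sep="\t", index=False)
    record("paths", out / "paths.tsv")

    graph = landscape.build_fitness_graph(scape, alpha=alpha)
    (out / "fitness_graph.dot").write_text(graph.to_dot() + "\n")
    record("fitness_graph", out / "fitness_graph.dot")
    graph.to_table().to_csv(out / "fitness_graph.tsv", sep="\t", index=False)
    record("fitness_graph_table", out / "fitness_graph.tsv")
    return {
        "n_accessible": len(paths["accessible"]),
        "n_blocked": len(paths["blocked"]),
        "n_edges": len(graph.edges),
    }
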