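"""Expression divergence, enrichment, and correlation statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from chemevolve import enrichxpr as ex
from chemevolve import synthdata as sd


def profile(values, sample="s1", env="ammonium", genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return ex.ExpressionProfile(
        sample_id=sample, environment=env,
        log2_ratio=pd.Series(values, index=genes, dtype=float),
    )


class TestAncestorNormalization:
    def test_clone_equal_to_ancestor_gives_zeros(self):
        p = profile([1.0, -0.5, 2.0])
        adj = ex.normalize_to_ancestor(p, p)
        assert (adj.log2_ratio == 0).all()

    def test_log_space_subtraction(self):
        clone = profile([2.0])
        anc = profile([0.5])
        assert ex.normalize_to_ancestor(clone, anc).log2_ratio.iloc[0] == 1.5

    def test_shared_environment_response_removed(self):
        rng = np.random.default_rng(0)
        env_effect = rng.normal(0, 1, 200)
        anc = profile(env_effect)
        c1 = profile(env_effect + rng.normal(0, 0.01, 200), sample="c1")
        c2 = profile(env_effect + rng.normal(0, 0.01, 200), sample="c2")
        a1 = ex.normalize_to_ancestor(c1, anc).log2_ratio
        a2 = ex.normalize_to_ancestor(c2, anc).log2_ratio
        # the large shared environmental component vanishes
        assert a1.var() < 0.001 and a2.var() < 0.001

    def test_environment_mismatch_errors(self):
        with pytest.raises(ValueError, match="environment"):
            ex.normalize_to_ancestor(
                profile([1.0], env="ammonium"), profile([1.0], env="proline")
            )


class TestDivergenceTest:
    def test_all_zero_profile_gives_p_one(self):
        p = profile([0.0] * 100)
        res = ex.gene_set_divergence_test(
            p, ex.GeneSet("s", [f"g{i}" for i in range(10)]), n_perm=200, seed=0
        )
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_strongly_shifted_set_attains_minimum_p(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.1, 500)
        vals[:38] += 2.0
        p = profile(vals)
        res = ex.gene_set_divergence_test(
            p, ex.GeneSet("s", [f"g{i}" for i in range(38)]), n_perm=999, seed=2
        )
        assert res["p"] == pytest.approx(1 / 1000)

    def test_small_case_agrees_with_exhaustive_subsets(self):
        vals = [0.1, 2.0, 0.3, 0.4, 1.5, 0.2]
        p = profile(vals)
        target = ["g1", "g4"]  # the two largest |log2|
        stat = np.mean([abs(vals[1]), abs(vals[4])])
        null = [
            np.mean([abs(vals[i]), abs(vals[j])])
            for i, j in itertools.combinations(range(6), 2)
        ]
        brute = sum(v >= stat for v in null) / len(null)
        res = ex.gene_set_divergence_test(
            p, ex.GeneSet("s", target), n_perm=4000, seed=3, add_one=False
        )
        se = math.sqrt(brute * (1 - brute) / 4000)
        assert abs(res["p"] - brute) < 4 * se + 1e-9

    def test_null_p_values_are_super_uniform(self):
        # under an i.i.d. background the add-one permutation p at nominal
        # 0.05 rejects at most ~5% of the time
        rng = np.random.default_rng(4)
        n_rej = 0
        n_rep = 300
        for i in range(n_rep):
            vals = rng.normal(0, 1, 120)
            genes = [f"g{j}" for j in range(120)]
            members = list(rng.choice(genes, size=10, replace=False))
            res = ex.gene_set_divergence_test(
                profile(vals, genes=genes), ex.GeneSet("s", members),
                n_perm=99, seed=int(rng.integers(2**31)),
            )
            n_rej += res["p"] <= 0.05
        assert n_rej / n_rep < 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_seeded_test_is_bit_reproducible(self):
        mat, target = sd.simulate_expression(n_genes=300, seed=7)
        p = profile(mat.iloc[:, 0].to_numpy(), genes=list(mat.index))
        run = lambda: ex.gene_set_divergence_test(
            p, ex.GeneSet("t", target), n_perm=200, seed=11
        )
        assert run() == run()

    def test_missing_members_listed(self):
        with pytest.raises(ValueError, match="ghost"):
            ex.gene_set_divergence_test(
                profile([1.0, 2.0]), ex.GeneSet("s", ["ghost"]), n_perm=10, seed=0
            )


class TestFunctionalEnrichment:
    def test_single_hit_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(10)]
        inp = ex.EnrichmentInput(
            locus_counts={"g0": 1},
            term_genes={"T": ["g0", "g1"]},
        )
        res = ex.functional_enrichment(inp, universe)
        expected = ss.hypergeom.sf(0, 10, 2, 1)  # P(X >= 1) = 0.2
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_term_size_bounds_exclude_terms(self):
        universe = [f"g{i}" for i in range(200)]
        inp = ex.EnrichmentInput(
            locus_counts={"g0": 1},
            term_genes={
                "tiny": ["g0"],
                "ok": ["g0", "g1", "g2"],
                "huge": [f"g{i}" for i in range(101)],
            },
        )
        res = ex.functional_enrichment(inp, universe)
        assert set(res["term"]) == {"ok"}

    def test_multi_allele_locus_counts_all_events(self):
        universe = [f"g{i}" for i in range(50)]
        inp = ex.EnrichmentInput(
            locus_counts={"g0": 3, "g1": 1},
            term_genes={"T": ["g0", "g1"], "U": ["g2", "g3"]},
        )
        res = ex.functional_enrichment(inp, universe).set_index("term")
        assert res.loc["T", "count"] == 4

    def test_bonferroni_is_min_one_p_times_m(self):
        universe = [f"g{i}" for i in range(30)]
        inp = ex.EnrichmentInput(
            locus_counts={"g0": 1, "g5": 1},
            term_genes={"A": ["g0", "g1"], "B": ["g5", "g6"], "C": ["g7", "g8"]},
        )
        res = ex.functional_enrichment(inp, universe)
        m = len(res)
        for _, row in res.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p"] * m))

    def test_unannotated_loci_excluded_and_empty_set_errors(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError, match="empty"):
            ex.functional_enrichment(
                ex.EnrichmentInput(locus_counts={}, term_genes={"T": ["g0", "g1"]}),
                universe,
            )
        with pytest.raises(ValueError, match="annotation"):
            ex.functional_enrichment(
                ex.EnrichmentInput(
                    locus_counts={"g9": 1}, term_genes={"T": ["g0", "g1"]}
                ),
                universe,
            )

    def test_fisher_p_equals_hypergeometric_summation_small_tables(self):
        # single-count hits: our one-tailed Fisher must equal the
        # hypergeometric tail for every configuration up to N = 12;
        # mutated loci without any annotation are dropped before testing,
        # so the oracle conditions on the annotated hits only
        for n_universe in (8, 12):
            universe = [f"g{i}" for i in range(n_universe)]
            for term_size in (2, 4):
                for n_hits in (1, 2, 3):
                    hits = {f"g{i}": 1 for i in range(n_hits)}
                    term = [f"g{i}" for i in range(term_size)]
                    inp = ex.EnrichmentInput(
                        locus_counts=hits, term_genes={"T": term}
                    )
                    res = ex.functional_enrichment(inp, universe)
                    annotated_hits = [g for g in hits if g in term]
                    k = len(annotated_hits)
                    expected = ss.hypergeom.sf(
                        k - 1, n_universe, term_size, len(annotated_hits)
                    )
                    assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)


class TestCorrelations:
    def test_perfect_copy_number_correlation(self):
        x = pd.Series([0.1, 0.5, -0.2, 1.0], index=list("abcd"))
        res = ex.copy_number_expression_correlation(x, x)
        assert res["r"] == pytest.approx(1.0)

    def test_constructed_correlation_recovered(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(1000)]
        cnv = pd.Series(rng.normal(0, 0.3, 1000), index=genes)
        sigma = 0.3 * math.sqrt(1 / 0.3**2 - 1)  # target r ~ 0.3
        expr = cnv + rng.normal(0, sigma, 1000)
        res = ex.copy_number_expression_correlation(cnv, pd.Series(expr, index=genes))
        assert abs(res["r"] - 0.3) < 0.05

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(2000)]
        a = pd.Series(rng.normal(size=2000), index=genes)
        b = pd.Series(rng.normal(size=2000), index=genes)
        res = ex.copy_number_expression_correlation(a, b)
        assert abs(res["r"]) < 0.06

    def test_zero_variance_reported_undefined(self):
        genes = list("abc")
        res = ex.copy_number_expression_correlation(
            pd.Series([1.0, 1.0, 1.0], index=genes),
            pd.Series([0.1, 0.2, 0.3], index=genes),
        )
        assert math.isnan(res["r"])


class TestTranscriptomeDivergence:
    def test_identical_profiles_fully_correlated(self):
        p = profile(list(np.random.default_rng(0).normal(size=50)))
        q = ex.ExpressionProfile("s2", p.environment, p.log2_ratio.copy())
        res = ex.transcriptome_divergence([p, q])
        assert res["correlations"] == [pytest.approx(1.0)]

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(1)
        profiles = [
            profile(list(rng.normal(size=40)), sample=f"s{i}") for i in range(5)
        ]
        res = ex.transcriptome_divergence(profiles)
        assert len(res["correlations"]) == 10

    def test_two_clusters_give_bimodal_correlations(self):
        rng = np.random.default_rng(2)
        base1, base2 = rng.normal(size=100), rng.normal(size=100)
        profs = [
            profile(list(base1 + rng.normal(0, 0.05, 100)), sample=f"a{i}")
            for i in range(3)
        ] + [
            profile(list(base2 + rng.normal(0, 0.05, 100)), sample=f"b{i}")
            for i in range(3)
        ]
        res = ex.transcriptome_divergence(profs)
        rs = np.array(res["correlations"])
        assert (rs > 0.9).sum() == 6  # within-cluster pairs
        assert (np.abs(rs) < 0.5).sum() == 9  # between-cluster pairs

    def test_fewer_than_two_profiles_errors(self):
        with pytest.raises(ValueError):
            ex.transcriptome_divergence([profile([1.0])])


class TestResponseFilter:
    def test_boundary_gene_dropped(self):
        mat = pd.DataFrame({"s1": [1.4, 1.6]}, index=["a", "b"])
        kept = ex.expression_response_filter(mat, ex.GeneSet("s", ["a", "b"]))
        assert kept == ["b"]

    def test_constructed_29_of_38_retained(self):
        rng = np.random.default_rng(3)
        genes = [f"n{i}" for i in range(38)]
        vals = np.full(38, 0.5)
        responsive = rng.choice(38, size=29, replace=False)
        vals[responsive] = rng.uniform(1.6, 4.0, 29) * rng.choice([-1, 1], 29)
        mat = pd.DataFrame({"s1": vals}, index=genes)
        kept = ex.expression_response_filter(mat, ex.GeneSet("ncr", genes))
        assert len(kept) == 29

    def test_threshold_is_strict_inequality_at_default(self):
        mat = pd.DataFrame({"s1": [1.5]}, index=["a"])
        assert ex.expression_response_filter(mat, ex.GeneSet("s", ["a"])) == []
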