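"""Rank tests, FDR control, enrichment and cohort contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genegravity import netio, setstats


# ---------------------------------------------------------------------------
# independent oracles


def rank_sum_enumeration_oracle(a, b, alternative="two-sided"):
    """Brute-force rank-sum p via explicit assignment enumeration, written
    from the definition (midranks, tail doubling) independently of the
    implementation's counting loop."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # midrank of the tied block
        i = j
    observed = ranks[: len(a)].sum()
    stats_all = [
        sum(ranks[list(combo)])
        for combo in itertools.combinations(range(len(pooled)), len(a))
    ]
    stats_all = np.array(stats_all)
    eps = 1e-9
    p_le = np.mean(stats_all <= observed + eps)
    p_ge = np.mean(stats_all >= observed - eps)
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


def hypergeom_enrichment_oracle(table, alternative="two-sided"):
    """Fisher p by direct hypergeometric enumeration with math.comb."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    def pmf(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )
    probs = {k: pmf(k) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in probs.items() if k <= a)
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-9)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


class TestWilcoxon:
    def test_identical_groups_exact_p_one(self):
        result = setstats.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert result.p == 1.0

    def test_complete_separation_minimum_p(self):
        a = list(range(11, 21))
        b = list(range(1, 11))
        result = setstats.wilcoxon_rank_sum(a, b)
        assert result.p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            setstats.wilcoxon_rank_sum([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle(self, alternative, rng):
        for _ in range(8):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 13 - n_a))
            # integer draws force ties
            a = rng.integers(0, 5, size=n_a).astype(float)
            b = rng.integers(0, 5, size=n_b).astype(float)
            result = setstats.wilcoxon_rank_sum(a, b, alternative=alternative)
            assert result.p == pytest.approx(
                rank_sum_enumeration_oracle(a, b, alternative), abs=1e-12
            )

    def test_two_sided_swap_invariance(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(loc=0.5, size=30)
        assert setstats.wilcoxon_rank_sum(a, b).p == pytest.approx(
            setstats.wilcoxon_rank_sum(b, a).p, rel=1e-12
        )

    def test_group_summaries_are_sem(self):
        result = setstats.wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        g = result.groups[0]
        assert g.mean == pytest.approx(2.0)
        assert g.sem == pytest.approx(np.std([1, 2, 3], ddof=1) / math.sqrt(3))


class TestBH:
    def test_single_p(self):
        assert setstats.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_forcing(self):
        np.testing.assert_allclose(
            setstats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_from_definition_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = setstats.bh_adjust(p)
            # from-definition step-up: q_(i) = min_{j>=i} p_(j) m / j
            order = np.argsort(p)
            m = len(p)
            sorted_q = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(sorted_q, 1.0)
            np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=25)
        assert (setstats.bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            setstats.bh_adjust([0.5, 1.5])

    def test_adjust_family_attaches_q(self):
        results = [
            setstats.TestResult("t1", 0.0, 0.01),
            setstats.TestResult("t2", 0.0, 0.04),
        ]
        adjusted = setstats.adjust_family(results, family="demo")
        assert [r.q for r in adjusted] == pytest.approx([0.02, 0.04])
        assert all(r.family == "demo" for r in adjusted)


class TestFisher:
    def test_degenerate_empty_set(self):
        assert setstats.fisher_enrichment(0, 0, 10, 100).p == 1.0

    def test_monotone_decreasing_in_overlap(self):
        ps = [setstats.fisher_enrichment(k, 50, 100, 1000).p for k in range(0, 20)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            setstats.fisher_enrichment(60, 50, 100, 1000)
        with pytest.raises(ValueError):
            setstats.fisher_enrichment(5, 50, 2000, 1000)

    def test_symmetric_2x2(self):
        assert setstats.fisher_2x2([[5, 5], [5, 5]]).p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            setstats.fisher_2x2([[0, 0], [3, 4]])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_2x2_matches_enumeration_oracle(self, alternative, rng):
        for _ in range(15):
            table = rng.integers(1, 15, size=(2, 2)).tolist()
            result = setstats.fisher_2x2(table, alternative=alternative)
            assert result.p == pytest.approx(
                hypergeom_enrichment_oracle(table, alternative), rel=1e-9
            )


class TestTopN:
    def frame(self, genes, avegs):
        return pd.DataFrame({"gene": genes, "aveg": avegs})

    def test_geneset_equals_topn_is_minimal_p(self):
        scores = self.frame([f"g{i}" for i in range(20)], np.arange(20.0))
        top5 = {f"g{i}" for i in range(15, 20)}
        p_best = setstats.topn_enrichment(scores, top5, n=5).p
        # any other 5-gene set cannot give a smaller p under the same margins
        other = {f"g{i}" for i in range(5)}
        assert p_best <= setstats.topn_enrichment(scores, other, n=5).p
        assert p_best == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_disjoint_geneset_p_one(self):
        scores = self.frame(list("abcdefgh"), range(8))
        assert setstats.topn_enrichment(scores, {"zz"}, n=3).p == 1.0

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            setstats.topn_enrichment(self.frame(["a", "b"], [1, 2]), {"a"}, n=5)


class TestXvsAutosomes:
    def frame(self, chroms, avegs):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(chroms))], "chromosome": chroms, "aveg": avegs}
        )

    def test_all_autosomal_rejected(self):
        scores = self.frame(["1", "2", "3", "4"], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="insufficient X-linked"):
            setstats.x_vs_autosomes(scores)

    def test_identical_values_p_one(self):
        scores = self.frame(["X", "X", "1", "2", "3"], [1.0] * 5)
        assert setstats.x_vs_autosomes(scores).p == 1.0

    def test_y_excluded(self):
        scores = self.frame(["X", "X", "Y", "1", "2"], [5.0, 6.0, 100.0, 1.0, 2.0])
        result = setstats.x_vs_autosomes(scores)
        assert result.groups[1].n == 2  # Y gene not in the autosome group


class TestMutationDensity:
    def test_all_samples_mutated_rejected(self):
        density = pd.Series({"s1": 1.0, "s2": 2.0})
        with pytest.raises(ValueError):
            setstats.mutation_density_compare(density, {"s1", "s2"})

    def test_enumeration_example(self):
        density = pd.Series(
            {"m1": 10.0, "m2": 10.0, "m3": 10.0, "w1": 1.0, "w2": 1.0, "w3": 1.0}
        )
        result = setstats.mutation_density_compare(density, {"m1", "m2", "m3"})
        assert result.p == pytest.approx(2 / math.comb(6, 3))
        assert result.groups[0].mean == pytest.approx(10.0)
        assert result.groups[1].mean == pytest.approx(1.0)

    def test_planted_mutator_detected(self, rng):
        carriers = [f"c{i}" for i in range(50)]
        wild = [f"w{i}" for i in range(450)]
        density = pd.Series(
            np.concatenate([rng.gamma(5.0, 1.0, size=50) * 5, rng.gamma(5.0, 1.0, size=450)]),
            index=carriers + wild,
        )
        result = setstats.mutation_density_compare(density, set(carriers))
        q = setstats.bh_adjust([result.p])[0]
        assert q < 0.1


class TestCovariateCorrelation:
    def frame(self, aveg, cov):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(aveg))], "aveg": aveg, "cdna_length": cov}
        )

    def test_self_correlation(self, rng):
        aveg = rng.uniform(size=20)
        r, _ = setstats.score_covariate_correlation(self.frame(aveg, aveg), "cdna_length")
        assert r == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self, rng):
        aveg = rng.uniform(size=1000)
        cov = rng.uniform(size=1000)
        r, _ = setstats.score_covariate_correlation(self.frame(aveg, cov), "cdna_length")
        assert abs(r) < 0.15

    def test_planted_dependence_detected(self, rng):
        length = rng.lognormal(np.log(2000), 0.5, size=300)
        aveg = length * rng.lognormal(0, 0.3, size=300)  # mass proportional to length
        r, p = setstats.score_covariate_correlation(self.frame(aveg, length), "cdna_length")
        assert r > 0 and p < 0.01

    def test_exclusions_applied_first(self, rng):
        aveg = np.concatenate([rng.uniform(size=30), [1000.0]])
        cov = np.concatenate([rng.uniform(size=30), [1e6]])
        frame = self.frame(aveg, cov)
        r_all, _ = setstats.score_covariate_correlation(frame, "cdna_length")
        r_excl, _ = setstats.score_covariate_correlation(frame, "cdna_length", exclusions={"g30"})
        assert r_all > 0.9 and abs(r_excl) < 0.9

    def test_constant_covariate_rejected(self, rng):
        frame = self.frame(rng.uniform(size=15), np.full(15, 3.0))
        with pytest.raises(ValueError, match="constant"):
            setstats.score_covariate_correlation(frame, "cdna_length")


class TestPPIEnrichment:
    def build_network(self):
        from genegravity import synthdata

        return synthdata.synth_network(100, mean_degree=4, seed=2)

    def test_deterministic_under_seed(self):
        network = self.build_network()
        m0 = pd.Series(1.0, index=network.sorted_nodes())
        a = setstats.ppi_pair_mutation_enrichment(network, m0, n_draws=500, seed=9)
        b = setstats.ppi_pair_mutation_enrichment(network, m0, n_draws=500, seed=9)
        assert a.p == b.p and a.statistic == b.statistic

    def test_clique_concentration_enriched(self):
        # masses concentrated on one hub's closed neighbourhood
        network = self.build_network()
        hub = max(network.sorted_nodes(), key=network.degree)
        member_set = {hub} | set(network.graph.neighbors(hub))
        m0 = pd.Series(
            [50.0 if g in member_set else 0.1 for g in network.sorted_nodes()],
            index=network.sorted_nodes(),
        )
        result = setstats.ppi_pair_mutation_enrichment(network, m0, n_draws=2000, seed=5)
        assert result.p < 0.01

    def test_uniform_mass_null_calibrated(self):
        network = self.build_network()
        m0 = pd.Series(
            np.random.default_rng(0).uniform(0.9, 1.1, size=network.n_nodes),
            index=network.sorted_nodes(),
        )
        ps = [
            setstats.ppi_pair_mutation_enrichment(network, m0, n_draws=300, seed=s).p
            for s in range(60)
        ]
        assert np.median(ps) > 0.3

    def test_complete_graph_rejected(self):
        import itertools as it

        network = netio.load_interactions(list(it.combinations("ABCD", 2)))
        m0 = pd.Series(1.0, index=list("ABCD"))
        with pytest.raises(ValueError, match="complete graph"):
            setstats.ppi_pair_mutation_enrichment(network, m0, n_draws=10, seed=0)


class TestExcludeSamples:
    def maf(self):
        return pd.DataFrame(
            {
                "Hugo_Symbol": ["A", "A", "B", "C"],
                "Tumor_Sample_Barcode": ["s1", "s2", "s1", "s3"],
                "Variant_Classification": ["Missense_Mutation"] * 4,
            }
        )

    def test_empty_list_is_identity(self):
        table, removed = setstats.exclude_samples(self.maf(), [])
        assert removed == 0 and len(table) == 4

    def test_excluding_all_of_a_genes_samples_zeroes_m0(self, path_graph):
        from genegravity import propagation as propagate

        maf = pd.DataFrame(
            {
                "Hugo_Symbol": ["A", "B"],
                "Tumor_Sample_Barcode": ["s1", "s2"],
                "Variant_Classification": ["Missense_Mutation"] * 2,
            }
        )
        filtered, removed = setstats.exclude_samples(maf, ["s1"])
        assert removed == 1
        m0 = propagate.build_m0(filtered, path_graph)
        assert m0.mass["A"] == 0 and m0.mass["B"] == 1

    def test_matches_filter_oracle(self, rng):
        maf = self.maf()
        excluded = {"s1", "s3"}
        table, removed = setstats.exclude_samples(maf, excluded)
        expected = maf[~maf["Tumor_Sample_Barcode"].isin(excluded)]
        assert removed == len(maf) - len(expected)
        assert list(table["Hugo_Symbol"]) == list(expected["Hugo_Symbol"])


class TestCatalog:
    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            setstats.GeneSetCatalog({"bad": frozenset()})

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            setstats.GeneSetCatalog({"big": frozenset(map(str, range(100)))}, universe=50)

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "set.txt"
        path.write_text("TP53\nKRAS\n\n")
        assert setstats.read_gene_set(path) == {"TP53", "KRAS"}
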