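"""Category statistics: bootstrap, rank tests, enrichment, codon usage."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from omegascreen.alignment import CodonAlignment
from omegascreen.categorystats import (
    bootstrap_category_rates,
    codon_usage_ca,
    compare_rate_distributions,
    enrichment_table,
    expected_counts,
    fisher_enrichment,
    regress_expression_rate,
    replicate_metric,
    rscu_matrix,
    wilcoxon_rank_sum,
)
from omegascreen.genetics import CODON_INDEX, SYNONYMOUS_FAMILIES
from omegascreen.synthgen import CodonSimScenario, simulate_codon_alignment
from omegascreen.trees import star_tree


class TestBootstrap:
    def test_identical_genes_give_identical_replicates(self, star4):
        scen = CodonSimScenario(tree=star4, omega_mode=0.2, n_codons=100, seed=3)
        aln = simulate_codon_alignment(scen).alignment
        alns = {f"g{i}": aln for i in range(5)}
        reps = bootstrap_category_rates(
            "c", list(alns), alns, star4, n_reps=3, genes_per_rep=3, seed=0
        )
        rates = [r.rates["global"] for r in reps]
        assert rates[0] == rates[1] == rates[2]

    def test_too_few_genes_rejected(self, star4):
        with pytest.raises(ValueError):
            bootstrap_category_rates("c", ["g1"], {}, star4, genes_per_rep=10)

    def test_seeded_reproducibility_and_recovery(self, star4):
        alns = {}
        for i in range(12):
            scen = CodonSimScenario(tree=star4, omega_mode=0.14, n_codons=150, seed=200 + i)
            alns[f"g{i}"] = simulate_codon_alignment(scen, f"g{i}").alignment
        reps1 = bootstrap_category_rates(
            "sexual", sorted(alns), alns, star4, n_reps=6, genes_per_rep=5, seed=9
        )
        reps2 = bootstrap_category_rates(
            "sexual", sorted(alns), alns, star4, n_reps=6, genes_per_rep=5, seed=9
        )
        assert [r.rates for r in reps1] == [r.rates for r in reps2]
        omegas = replicate_metric(reps1, "dN/dS")
        assert abs(omegas.mean() - 0.14) < 0.05
        # dN/dS consistency within each replicate
        for r in reps1:
            dn, ds, w = r.rates["global"]
            assert dn / ds == pytest.approx(w, rel=1e-6)


class TestWilcoxon:
    def test_fully_separated_small_samples_exact(self):
        u, p = wilcoxon_rank_sum(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_asymptotic_close_to_exact_for_small_n(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 7)
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(exact - approx) < 0.03

    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_rank_sum(x, x)
        assert p == 1.0

    def test_pairwise_table_with_bh(self):
        reps = {
            "a": [_FakeRep({"global": (0.1, 1.0, 0.1)}) for _ in range(5)],
            "b": [_FakeRep({"global": (0.2 + i / 100, 1.0, 0.2 + i / 100)}) for i in range(5)],
            "c": [_FakeRep({"global": (0.5 + i / 100, 1.0, 0.5 + i / 100)}) for i in range(5)],
        }
        table = compare_rate_distributions(reps, "dN/dS", "global")
        assert len(table) == 3
        assert (table["p_adj"] >= table["p"] - 1e-12).all()


class _FakeRep:
    def __init__(self, rates):
        self.rates = rates


class TestFisher:
    def test_worked_examples_from_rapid_gene_counts(self):
        """Sexual 26/99 vs constitutive 112/627 and vs vegetative 15/94."""
        a = fisher_enrichment(np.array([[26, 73], [112, 515]]), alternative="greater")
        assert a.p == pytest.approx(0.036, abs=5e-4)
        b = fisher_enrichment(np.array([[26, 73], [15, 79]]), alternative="greater")
        assert b.p == pytest.approx(0.057, abs=5e-4)
        # the two-sided convention on the same tables
        assert fisher_enrichment([[26, 73], [112, 515]]).p == pytest.approx(0.0538, abs=5e-4)

    def test_perfect_independence(self):
        assert fisher_enrichment(np.array([[5, 5], [5, 5]])).p == 1.0

    def test_two_sided_matches_exhaustive_enumeration(self, rng):
        """Sum of point probabilities <= observed, over all margin-fixed tables."""
        for _ in range(10):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n, r1, c1 = a + b + c + d, a + b, a + c
            pobs = hypergeom.pmf(a, n, r1, c1)
            total = sum(
                hypergeom.pmf(x, n, r1, c1)
                for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                if hypergeom.pmf(x, n, r1, c1) <= pobs * (1 + 1e-7)
            )
            got = fisher_enrichment(np.array([[a, b], [c, d]])).p
            assert got == pytest.approx(min(total, 1.0), abs=1e-9)
            assert got >= pobs - 1e-12  # two-tailed p >= point probability

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(np.array([[0, 0], [3, 4]]))


class TestExpectedCounts:
    #: phylogenetic-specificity observed counts (classes x categories)
    PHYLO_TABLE = np.array(
        [
            [100, 656, 54],    # most lineage-specific class
            [206, 1771, 117],
            [6, 91, 9],
            [68, 582, 73],
            [77, 1448, 290],   # broadest core class
            [17, 90, 17],
            [35, 387, 29],
        ]
    )

    def test_published_independence_arithmetic(self):
        exp = expected_counts(self.PHYLO_TABLE)
        assert exp[0, 0] == pytest.approx(67.3, abs=0.05)
        assert exp[4, 0] == pytest.approx(150.9, abs=0.05)

    def test_uniform_table_expected_equals_observed(self):
        obs = np.full((2, 2), 7.0)
        np.testing.assert_allclose(expected_counts(obs), obs)

    def test_margins_preserved(self):
        exp = expected_counts(self.PHYLO_TABLE)
        np.testing.assert_allclose(exp.sum(), self.PHYLO_TABLE.sum())
        np.testing.assert_allclose(exp.sum(axis=1), self.PHYLO_TABLE.sum(axis=1))

    def test_zero_grand_total_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(np.zeros((2, 2)))

    def test_enrichment_table_per_cell_tests(self):
        obs = pd.DataFrame(
            self.PHYLO_TABLE,
            index=[f"class{i}" for i in range(7)],
            columns=["sexual", "constitutive", "vegetative"],
        )
        table = enrichment_table(obs)
        assert len(table) == 21
        row = table[(table["row"] == "class0") & (table["column"] == "sexual")].iloc[0]
        assert row["expected"] == pytest.approx(67.3)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()


class TestCodonUsage:
    def test_equal_family_usage_gives_rscu_one(self):
        # one of each sense codon -> every family is used uniformly
        codes = np.arange(61)
        rscu = rscu_matrix({"g1": codes, "g2": codes})
        np.testing.assert_allclose(rscu.to_numpy(), 1.0, atol=1e-12)

    def test_rscu_definition_on_skewed_family(self):
        # Lys family (AAA, AAG): 3 of one, 1 of the other
        codes = np.array(
            [CODON_INDEX["AAA"]] * 3 + [CODON_INDEX["AAG"]] + [CODON_INDEX["GGG"]] * 26
        )
        rscu = rscu_matrix({"g": codes})
        assert rscu.loc["g", "AAA"] == pytest.approx(1.5)
        assert rscu.loc["g", "AAG"] == pytest.approx(0.5)

    def test_identical_genes_zero_inertia(self, rng):
        codes = rng.integers(0, 61, size=40)
        ca = codon_usage_ca({"g1": codes, "g2": codes, "g3": codes})
        assert ca.total_inertia < 1e-20
        np.testing.assert_allclose(ca.row_coords.to_numpy(), 0.0, atol=1e-9)

    def test_disjoint_usage_separates_on_axis_one(self):
        a = np.array([CODON_INDEX["AAA"]] * 30)  # Lys via AAA only
        b = np.array([CODON_INDEX["AAG"]] * 30)  # Lys via AAG only
        ca = codon_usage_ca({"g1": a, "g2": b})
        coords = ca.row_coords["axis1"]
        assert np.sign(coords["g1"]) != np.sign(coords["g2"])
        assert ca.inertia[0] / ca.total_inertia > 0.99

    def test_inertia_decomposition_sums_to_total_chisquare(self, rng):
        seqs = {f"g{i}": rng.integers(0, 61, size=100) for i in range(6)}
        ca = codon_usage_ca(seqs, n_axes=5)
        X = ca.rscu.to_numpy()
        P = X / X.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        assert ca.total_inertia == pytest.approx((S**2).sum(), abs=1e-8)

    def test_coordinates_orthogonal_in_chisquare_metric(self, rng):
        seqs = {f"g{i}": rng.integers(0, 61, size=100) for i in range(6)}
        ca = codon_usage_ca(seqs, n_axes=3)
        F = ca.row_coords.to_numpy()
        X = ca.rscu.to_numpy()
        r = (X / X.sum()).sum(axis=1)
        gram = F.T @ (r[:, None] * F)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_short_genes_rejected(self):
        with pytest.raises(ValueError):
            codon_usage_ca({"g1": np.arange(10), "g2": np.arange(10)})


class TestRegression:
    def test_exact_linear_relation(self):
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "expression": [1.0, 2, 3, 4, 5, 6],
                "cds_length": [300] * 6,
                "omega": [2.0, 4, 6, 8, 10, 12],
                "category": ["constitutive"] * 6,
            }
        )
        out = regress_expression_rate(t)
        row = out[(out["predictor"] == "expression") & (out["group"] == "all")].iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["r2"] == pytest.approx(1.0)
        # constant cds_length predictor is skipped, not an error
        assert not (
            (out["predictor"] == "cds_length") & (out["kind"] == "regression")
        ).any()

    def test_order_invariance(self, rng):
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "expression": rng.lognormal(5, 1, 20),
                "cds_length": rng.integers(200, 2000, 20).astype(float),
                "omega": rng.uniform(0.01, 0.5, 20),
                "category": ["sexual"] * 10 + ["vegetative"] * 10,
            }
        )
        a = regress_expression_rate(t)
        b = regress_expression_rate(t.sample(frac=1, random_state=1))
        merged = a.merge(b, on=["kind", "predictor", "group"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], atol=1e-10)

    def test_independent_rate_shows_no_association(self, rng):
        """omega simulated independently of expression: R^2 stays near zero."""
        n = 300
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "expression": rng.lognormal(6, 1, n),
                "cds_length": rng.integers(300, 3000, n).astype(float),
                "omega": rng.gamma(2.0, 0.06, n),
                "category": ["constitutive"] * n,
            }
        )
        out = regress_expression_rate(t)
        reg = out[(out["kind"] == "regression") & (out["group"] == "all")]
        assert (reg["r2"] < 0.05).all()

    def test_too_few_genes_rejected(self):
        t = pd.DataFrame(
            {
                "gene_id": ["g1"], "expression": [1.0], "cds_length": [10.0],
                "omega": [0.1], "category": ["sexual"],
            }
        )
        with pytest.raises(ValueError):
            regress_expression_rate(t)
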