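"""Synthetic-data generators: codon alignments, gene sets, microarrays."""

import numpy as np
import pytest
from scipy import stats

from omegascreen.codonmodel.frequencies import CodonFrequencies
from omegascreen.codonmodel.ratematrix import CodonRateMatrix
from omegascreen.genetics import MISSING, STOP_CODONS
from omegascreen.synthgen import (
    ArraySimScenario,
    CodonSimScenario,
    simulate_codon_alignment,
    simulate_gene_set,
    simulate_microarray,
)
from omegascreen.trees import Tree, star_tree


class TestCodonSimulator:
    def test_zero_length_branches_copy_root(self):
        tree = star_tree(["a", "b", "c"], 0.0)
        sim = simulate_codon_alignment(
            CodonSimScenario(tree=tree, omega_mode=0.5, n_codons=50, seed=3)
        )
        codes = sim.alignment.codes
        assert (codes == codes[0]).all()

    def test_identical_seeds_reproduce_identical_output(self, star4):
        scen = CodonSimScenario(tree=star4, omega_mode=0.3, n_codons=100, seed=42)
        a = simulate_codon_alignment(scen).alignment.codes
        b = simulate_codon_alignment(scen).alignment.codes
        np.testing.assert_array_equal(a, b)

    def test_no_stop_codons_in_fasta_output(self, star4, tmp_path):
        scen = CodonSimScenario(tree=star4, omega_mode=5.0, n_codons=200, seed=1)
        sim = simulate_codon_alignment(scen)
        path = tmp_path / "g.fasta"
        sim.alignment.write_fasta(path)
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                continue
            codons = {line[i : i + 3] for i in range(0, len(line) - 2, 3)}
            assert not codons & set(STOP_CODONS)

    def test_long_branch_converges_to_stationary_frequencies(self):
        """Chi-square goodness of fit to pi after t=10 substitutions/codon."""
        tree = Tree.from_newick("(a:5.0,b:5.0);")
        scen = CodonSimScenario(tree=tree, omega_mode=1.0, n_codons=10_000, seed=5)
        sim = simulate_codon_alignment(scen)
        counts = np.bincount(sim.alignment.codes[1], minlength=61)
        chi2, p = stats.chisquare(counts, f_exp=np.full(61, counts.sum() / 61))
        assert p > 0.01

    def test_pairwise_identity_matches_transition_matrix(self):
        """Mean codon identity over reps tracks the analytic P(t) diagonal."""
        tree = Tree.from_newick("(a:2.5,b:2.5);")
        pi = CodonFrequencies.equal().pi
        P = CodonRateMatrix(2.0, 1.0, pi).transition_probabilities(5.0)
        expected = float(pi @ np.diag(P))
        n_codons, reps = 200, 50
        idents = []
        for r in range(reps):
            scen = CodonSimScenario(tree=tree, omega_mode=1.0, n_codons=n_codons, seed=100 + r)
            codes = simulate_codon_alignment(scen).alignment.codes
            idents.append((codes[0] == codes[1]).mean())
        se = np.std(idents, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(idents) - expected) < 4 * se + 1e-3

    def test_site_mixture_records_truth_labels(self, star4):
        mix = [(0.6, 0.05), (0.3, 1.0), (0.1, 5.0)]
        scen = CodonSimScenario(tree=star4, omega_mode=mix, n_codons=2000, seed=8)
        sim = simulate_codon_alignment(scen)
        assert sorted(set(sim.site_omegas)) == [0.05, 1.0, 5.0]
        fractions = np.bincount(sim.site_classes, minlength=3) / 2000
        np.testing.assert_allclose(fractions, [0.6, 0.3, 0.1], atol=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_codons": 0},
            {"kappa": -1.0},
            {"omega_mode": -0.5},
            {"omega_mode": [(0.5, 0.1), (0.4, 1.0)]},  # proportions sum != 1
            {"omega_mode": [(1.2, 0.1), (-0.2, 1.0)]},  # negative proportion
        ],
    )
    def test_invalid_scenarios_rejected(self, star4, kwargs):
        with pytest.raises(ValueError):
            CodonSimScenario(tree=star4, **kwargs)

    def test_invalid_frequency_vector_rejected(self, star4):
        with pytest.raises(ValueError):
            CodonFrequencies("custom", np.full(61, 0.5))


class TestGeneSet:
    def test_counts_and_files(self, star4, tmp_path):
        scen = CodonSimScenario(tree=star4, omega_mode=0.2, n_codons=60, seed=0)
        meta, alns = simulate_gene_set(
            {"sexual": 4, "vegetative": 3, "constitutive": 3},
            {c: scen for c in ("sexual", "vegetative", "constitutive")},
            seed=1,
            out_dir=tmp_path,
        )
        assert len(meta) == 10 and len(alns) == 10
        assert meta["category"].value_counts().to_dict() == {
            "constitutive": 3, "sexual": 4, "vegetative": 3
        }
        assert len(list(tmp_path.glob("*.fasta"))) == 10
        assert (tmp_path / "metadata.tsv").exists()
        # truth labels live in the metadata, not in FASTA headers
        fasta = (tmp_path / meta["gene_id"].iloc[0]).with_suffix(".fasta").read_text()
        assert "sexual" not in fasta and "omega" not in fasta

    def test_empty_scenario_map_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_set({"sexual": 2}, {})

    def test_planted_enrichment_detected_and_null_calibrated(self, star4):
        """Odds ratio 5 on the lineage-specific class is detected; odds
        ratio 1 rejects near the nominal rate."""
        import pandas as pd

        from omegascreen.categorystats import fisher_enrichment

        scen = CodonSimScenario(tree=star4, omega_mode=0.2, n_codons=6, seed=0)
        scens = {c: scen for c in ("sexual", "constitutive")}
        counts = {"sexual": 100, "constitutive": 500}

        def cell_p(meta):
            a = ((meta["category"] == "sexual") & (meta["phylo_class"] == "lineage_specific")).sum()
            b = (meta["category"] == "sexual").sum() - a
            c = ((meta["category"] != "sexual") & (meta["phylo_class"] == "lineage_specific")).sum()
            d = (meta["category"] != "sexual").sum() - c
            return fisher_enrichment(np.array([[a, b], [c, d]])).p

        detected = 0
        for rep in range(15):
            meta, _ = simulate_gene_set(counts, scens, enrichment_odds=5.0, seed=rep)
            detected += cell_p(meta) < 0.05
        assert detected >= 14  # strong planted signal is almost always found

        null_rejections = 0
        n_null = 60
        for rep in range(n_null):
            meta, _ = simulate_gene_set(counts, scens, enrichment_odds=1.0, seed=1000 + rep)
            null_rejections += cell_p(meta) < 0.05
        # exact test is conservative; rate must not exceed ~nominal
        assert null_rejections / n_null <= 0.09


class TestMicroarray:
    def test_design_structure(self):
        scen = ArraySimScenario(n_genes=50, n_arrays=4, seed=0)
        intens, truth = simulate_microarray(scen)
        assert len(intens) == 50 * 4
        assert set(intens["dye_orientation"]) == {"forward", "swap"}
        assert (intens["dye_orientation"] == "swap").sum() == 100
        assert len(truth) == 50
        const = truth[truth["category"] == "constitutive"]
        assert (const["true_log2_fold"] == 0).all()
        assert (truth.loc[truth["category"] == "sexual", "true_log2_fold"] > 0).all()
        assert (truth.loc[truth["category"] == "vegetative", "true_log2_fold"] < 0).all()

    def test_odd_array_count_rejected(self):
        with pytest.raises(ValueError):
            ArraySimScenario(n_arrays=3)

    def test_category_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ArraySimScenario(category_fractions=(0.5, 0.2, 0.2))

    def test_seed_reproducibility(self):
        scen = ArraySimScenario(n_genes=20, seed=7)
        a, _ = simulate_microarray(scen)
        b, _ = simulate_microarray(scen)
        assert a.equals(b)
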