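"""Expression analysis: normalization, posteriors, categories, q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omegascreen.expression import (
    GeneCategoryAssignment,
    absolute_expression,
    categorize_genes,
    estimate_qvalues,
    gibbs_posterior_draws,
    normalize_arrays,
    posterior_relative_expression,
    _gene_posterior,
)
from omegascreen.synthgen import ArraySimScenario, simulate_microarray


def _intensity_rows(gene_ids, array_id, orientation, sex_signal, veg_signal, bg=100.0):
    ch1, ch2 = (sex_signal, veg_signal) if orientation == "forward" else (veg_signal, sex_signal)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "array_id": array_id,
            "dye_orientation": orientation,
            "ch1_fg": bg + np.asarray(ch1, float),
            "ch1_bg": bg,
            "ch2_fg": bg + np.asarray(ch2, float),
            "ch2_bg": bg,
        }
    )


class TestNormalization:
    def test_dye_swap_symmetry(self):
        """A forward and a swap array carrying the same true ratios agree."""
        genes = [f"g{i}" for i in range(5)]
        sex = np.array([400.0, 200.0, 100.0, 50.0, 25.0])
        veg = np.array([25.0, 50.0, 100.0, 200.0, 400.0])  # log2 ratios symmetric
        table = pd.concat(
            [
                _intensity_rows(genes, "a1", "forward", sex, veg),
                _intensity_rows(genes, "a2", "swap", sex, veg),
            ]
        )
        norm = normalize_arrays(table)
        for g in genes:
            r = norm.ratios[g]
            assert len(r) == 2
            assert r[0] == pytest.approx(r[1], abs=1e-12)

    def test_all_background_spots_leave_nothing_well_measured(self):
        table = _intensity_rows(["g1", "g2"], "a1", "forward", [0.0, 0.0], [0.0, 0.0])
        with pytest.warns(UserWarning):
            norm = normalize_arrays(table)
        assert norm.ratios == {}
        assert norm.excluded_arrays == ["a1"]

    def test_per_array_median_is_centered(self):
        intens, _ = simulate_microarray(ArraySimScenario(n_genes=300, seed=2))
        norm = normalize_arrays(intens)
        med = norm.per_array.groupby("array_id")["log2_ratio"].median()
        np.testing.assert_allclose(med.to_numpy(), 0.0, atol=1e-9)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            normalize_arrays(pd.DataFrame({"gene_id": ["g"]}))


class TestPosterior:
    def test_symmetric_zero_data(self):
        mean, lo, hi, p = _gene_posterior(np.zeros(4))
        assert mean == 0.0 and p == 1.0
        assert lo <= mean <= hi

    def test_zero_variance_replicates_give_vanishing_p(self):
        mean, lo, hi, p = _gene_posterior(np.ones(4))
        assert mean == 1.0
        assert p < 1e-10  # sd floored at 1e-6, documented regularization

    def test_closed_form_is_student_t(self):
        y = np.array([0.5, 1.0, 1.5, 2.0])
        from scipy import stats

        mean, lo, hi, p = _gene_posterior(y)
        scale = y.std(ddof=1) / 2
        assert mean == pytest.approx(y.mean())
        assert (lo, hi) == pytest.approx(stats.t.interval(0.95, 3, y.mean(), scale))
        assert p == pytest.approx(2 * stats.t.sf(y.mean() / scale, 3))

    def test_gibbs_sampler_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        for i in range(3):
            y = rng.normal(0.5, 0.8, size=4)
            mean, lo, hi, _ = _gene_posterior(y)
            draws = gibbs_posterior_draws(y, n_draws=50_000, seed=i)
            qlo, qhi = np.quantile(draws, [0.025, 0.975])
            assert abs(qlo - lo) < 0.02 * max(1, abs(lo) / 0.5)
            assert abs(qhi - hi) < 0.02 * max(1, abs(hi) / 0.5)

    def test_single_measurement_is_not_analyzable(self):
        from omegascreen.expression import NormalizedRatios

        norm = NormalizedRatios({"g1": np.array([0.3])}, 4, [])
        post = posterior_relative_expression(norm)
        assert np.isnan(post.loc[0, "p"])


class TestCategorization:
    def _posterior_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "n_well_measured", "posterior_mean", "ci_lo", "ci_hi", "p"]
        )

    def test_boundary_rules(self):
        post = self._posterior_frame(
            [
                ("below", 4, 0.8, 0.1, 1.5, 0.049),   # p < alpha, mean > 0
                ("exact", 4, 0.8, 0.0, 1.6, 0.05),    # p == alpha: strict inequality
                ("down", 4, -0.8, -1.5, -0.1, 0.01),
                ("flat", 4, 0.0, -0.5, 0.5, 0.9),
                ("na", 1, np.nan, np.nan, np.nan, np.nan),
            ]
        )
        cats = categorize_genes(post).table.set_index("gene_id")["category"]
        assert cats["below"] == "sexual"
        assert cats["exact"] == "constitutive"
        assert cats["down"] == "vegetative"
        assert cats["flat"] == "constitutive"
        assert cats["na"] == "n/a"

    def test_categories_exhaustive_and_exclusive(self):
        intens, _ = simulate_microarray(ArraySimScenario(n_genes=400, seed=3))
        post = posterior_relative_expression(normalize_arrays(intens))
        table = categorize_genes(post).table
        assert set(table["category"]) <= {"sexual", "vegetative", "constitutive", "n/a"}
        assert (table.loc[table["in_sexual_q10"], "category"] == "sexual").all()
        assert len(table) == table["gene_id"].nunique()

    def test_noiseless_limit_recovers_truth_exactly(self):
        scen = ArraySimScenario(
            n_genes=200, log2_effect=2.0, noise_sd=0.0, dropout_rate=0.0, seed=5
        )
        intens, truth = simulate_microarray(scen)
        post = posterior_relative_expression(normalize_arrays(intens))
        table = categorize_genes(post).table.set_index("gene_id")
        for _, row in truth.iterrows():
            assert table.loc[row["gene_id"], "category"] == row["category"]

    def test_null_false_positive_rate_is_nominal(self):
        """No differential expression: ~5% of genes leave 'constitutive'."""
        rates = []
        for rep in range(10):
            scen = ArraySimScenario(
                n_genes=2000, log2_effect=0.0,
                category_fractions=(0.0, 0.0, 1.0), dropout_rate=0.0, seed=rep,
            )
            intens, _ = simulate_microarray(scen)
            table = categorize_genes(
                posterior_relative_expression(normalize_arrays(intens))
            ).table
            measured = table[table["category"] != "n/a"]
            rates.append((measured["category"] != "constitutive").mean())
        assert 0.040 < np.mean(rates) < 0.060


class TestQValues:
    def test_single_p_of_one(self):
        assert estimate_qvalues(np.array([1.0])).tolist() == [1.0]

    def test_bh_arithmetic_with_pi0_one(self):
        q = estimate_qvalues(np.array([0.01, 0.02, 0.03, 0.9]), pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9], atol=1e-12)

    def test_null_pi0_estimate_near_one(self):
        from omegascreen.expression import estimate_pi0

        p = np.random.default_rng(0).uniform(size=5000)
        assert 0.9 <= estimate_pi0(p) <= 1.0
        q = estimate_qvalues(p)
        assert 0.9 < q.max() <= 1.0

    @given(st.permutations(list(range(8))))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance(self, perm):
        p = np.array([0.001, 0.02, 0.1, 0.3, 0.5, 0.6, 0.8, 0.99])
        base = estimate_qvalues(p)
        perm = np.array(perm)
        shuffled = estimate_qvalues(p[perm])
        np.testing.assert_allclose(shuffled, base[perm])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=500)
        q = estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= 0.0).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_qvalues(np.array([]))
        with pytest.raises(ValueError):
            estimate_qvalues(np.array([1.2]))


class TestAbsoluteExpression:
    def test_single_spot_arithmetic(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g1"], "array_id": ["a1"], "dye_orientation": ["forward"],
                "ch1_fg": [100.0], "ch1_bg": [40.0], "ch2_fg": [100.0], "ch2_bg": [40.0],
            }
        )
        out = absolute_expression(table)
        assert out.loc[0, "mean_intensity"] == pytest.approx(60.0)

    def test_unmeasured_gene_is_missing(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g1"], "array_id": ["a1"], "dye_orientation": ["forward"],
                "ch1_fg": [10.0], "ch1_bg": [40.0], "ch2_fg": [100.0], "ch2_bg": [40.0],
            }
        )
        out = absolute_expression(table)
        assert np.isnan(out.loc[0, "mean_intensity"])

    def test_category_restricts_channel(self):
        genes = ["g1"]
        table = pd.concat(
            [
                _intensity_rows(genes, "a1", "forward", [300.0], [100.0]),
                _intensity_rows(genes, "a2", "swap", [500.0], [200.0]),
            ]
        )
        assign = GeneCategoryAssignment(
            pd.DataFrame(
                {"gene_id": ["g1"], "category": ["sexual"], "p": [0.01],
                 "q": [0.01], "in_sexual_q10": [True]}
            )
        )
        out = absolute_expression(table, assign).set_index("gene_id")
        assert out.loc["g1", "mean_intensity"] == pytest.approx((300 + 500) / 2)
        # overall mean uses both channels
        out_all = absolute_expression(table).set_index("gene_id")
        assert out_all.loc["g1", "mean_intensity"] == pytest.approx(
            (300 + 500 + 100 + 200) / 4
        )
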