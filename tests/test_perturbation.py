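"""The per-perturbagen discriminative screen and its controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omniarch.perturbation import (
    DiscriminativePerturbationModel, PerturbationPanel, aggregate_signatures,
    discriminative_test, normal_upper_tail, proportion_ztest,
    random_set_control, response_correlation, variance_test,
)


def make_panel(z, perturbagens=None, genes=None):
    z = np.asarray(z, dtype=float)
    perturbagens = perturbagens or [f"pert{i}" for i in range(z.shape[0])]
    genes = genes or [f"g{i}" for i in range(z.shape[1])]
    return PerturbationPanel("TEST", "knockdown",
                             pd.DataFrame(z, index=perturbagens, columns=genes))


@pytest.fixture()
def toy_panel():
    rng = np.random.default_rng(1)
    return make_panel(rng.standard_normal((5, 40)))


CORE = [f"g{i}" for i in range(15)]
PERI = [f"g{i}" for i in range(15, 40)]


class TestAggregateSignatures:
    def test_mean_and_identity(self):
        assert aggregate_signatures([[1, 2], [3, 4]]).tolist() == [2.0, 3.0]
        np.testing.assert_array_equal(aggregate_signatures([[5.0, 6.0]]), [5.0, 6.0])
        v = [1.0, 2.0, 3.0]
        np.testing.assert_allclose(aggregate_signatures([v] * 4), v)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_signatures([[1, 2], [1, 2, 3]])


class TestDiscriminativeScreen:
    def test_exact_separation_is_significant(self):
        z = np.zeros((1, 40))
        z[0, :15] = 2.0
        res = discriminative_test(make_panel(z), CORE, PERI)
        row = res.frame.iloc[0]
        assert row["mean_diff"] == pytest.approx(2.0)
        assert row["p_mean"] < 1e-10

    def test_class_swap_symmetry(self, toy_panel):
        r1 = discriminative_test(toy_panel, CORE, PERI).frame
        r2 = discriminative_test(toy_panel, PERI, CORE).frame
        np.testing.assert_allclose(r1["mean_diff"], -r2["mean_diff"])
        np.testing.assert_allclose(r1["t_stat"], -r2["t_stat"])
        np.testing.assert_allclose(r1["p_mean"], r2["p_mean"], rtol=1e-9)
        np.testing.assert_allclose(r1["f_stat"], 1.0 / r2["f_stat"], rtol=1e-9)

    def test_matches_scipy_welch_per_perturbagen(self, toy_panel):
        # independent route: scipy per row, with manual self-exclusion
        res = discriminative_test(toy_panel, CORE, PERI).frame
        z = toy_panel.z
        for i, pert in enumerate(toy_panel.perturbagens):
            core = [g for g in CORE if g != pert]
            peri = [g for g in PERI if g != pert]
            ref = stats.ttest_ind(z.loc[pert, core], z.loc[pert, peri],
                                  equal_var=False)
            assert res["t_stat"].iloc[i] == pytest.approx(ref.statistic, rel=1e-9)
            assert res["p_mean"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_self_gene_excluded_from_its_own_test(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((1, 40))
        panel = make_panel(z, perturbagens=["g0"])  # perturbagen is a core gene
        res = discriminative_test(panel, CORE, PERI).frame
        assert res["n_core"].iloc[0] == len(CORE) - 1
        ref = stats.ttest_ind(z[0, 1:15], z[0, 15:], equal_var=False)
        assert res["t_stat"].iloc[0] == pytest.approx(ref.statistic, rel=1e-9)

    def test_column_order_invariance(self, toy_panel):
        shuffled = PerturbationPanel(
            "TEST", "knockdown",
            toy_panel.z[list(np.random.default_rng(5).permutation(toy_panel.z.columns))])
        r1 = discriminative_test(toy_panel, CORE, PERI).frame
        r2 = discriminative_test(shuffled, CORE, PERI).frame
        np.testing.assert_allclose(r1["t_stat"], r2["t_stat"], rtol=1e-9)

    def test_class_floor_enforced_with_name(self, toy_panel):
        with pytest.raises(ValueError, match="core"):
            discriminative_test(toy_panel, CORE[:3], PERI)

    def test_summary_mentions_test_choice(self, toy_panel):
        assert "Welch" in discriminative_test(toy_panel, CORE, PERI).summary()


class TestVarianceTest:
    def test_scaling_gives_exact_f(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(15)
        z = np.concatenate([2 * base, base, base[:10]])[None, :]
        panel = make_panel(z)
        res = variance_test(panel, CORE, [f"g{i}" for i in range(15, 30)],
                            exclude_self=False)
        # core sample is the peripheral sample scaled by 2 -> F = 4
        assert res["f_stat"].iloc[0] == pytest.approx(4.0)

    def test_zero_peripheral_variance_rejected(self):
        z = np.zeros((1, 40))
        z[0, :15] = np.random.default_rng(0).standard_normal(15)
        with pytest.raises(ValueError, match="variance"):
            variance_test(make_panel(z), CORE, PERI)

    def test_equal_variance_gives_median_p(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((200, 40))
        res = variance_test(make_panel(z), CORE, PERI)
        assert np.median(res["p_var"]) == pytest.approx(0.5, abs=0.1)


class TestRandomSetControl:
    def test_deterministic_under_seed(self, toy_panel):
        f1 = random_set_control(toy_panel, toy_panel.measured_genes, 15,
                                n_reps=3, seed=11)
        f2 = random_set_control(toy_panel, toy_panel.measured_genes, 15,
                                n_reps=3, seed=11)
        np.testing.assert_array_equal(f1, f2)
        assert len(random_set_control(toy_panel, toy_panel.measured_genes, 15,
                                      n_reps=1, seed=0)) == 1

    def test_oversized_set_rejected(self, toy_panel):
        with pytest.raises(ValueError):
            random_set_control(toy_panel, toy_panel.measured_genes, 100, n_reps=1)


class TestProportionZtest:
    def test_reported_pair(self):
        # the upper normal tail at Z = 1.66 prints as p = 0.048
        assert round(normal_upper_tail(1.66), 3) == 0.048

    def test_equal_proportions(self):
        z, p = proportion_ztest(3, 10, 6, 20)
        assert z == pytest.approx(0.0) and p == pytest.approx(0.5)

    def test_pooled_formula(self):
        z, p = proportion_ztest(8, 10, 5, 10)
        phat = 13 / 20
        z_ref = (0.8 - 0.5) / np.sqrt(phat * (1 - phat) * (1 / 10 + 1 / 10))
        assert z == pytest.approx(z_ref)
        assert z == pytest.approx(1.407, abs=1e-3)
        assert p == pytest.approx(0.080, abs=1e-3)

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest
        z, p = proportion_ztest(30, 100, 20, 120, alternative="greater")
        z_ref, p_ref = proportions_ztest([30, 20], [100, 120], alternative="larger")
        assert z == pytest.approx(z_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning):
            _, p = proportion_ztest(0, 10, 0, 10)
        assert p == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            proportion_ztest(5, 3, 1, 10)


class TestResponseCorrelation:
    def test_identical_and_reversed_vectors(self):
        v = np.arange(10.0)
        z = np.vstack([v, v, v[::-1]])
        panel = make_panel(z, genes=[f"g{i}" for i in range(10)])
        core = [f"g{i}" for i in range(10)]
        summ = response_correlation(panel, core, panel.perturbagens,
                                    thresholds=(0.25, 0.5))
        # pairs: (0,1) rho=1, (0,2) rho=-1, (1,2) rho=-1
        assert summ.n_pairs == 3
        assert summ.frac_above == pytest.approx(1 / 3)
        assert summ.frac_below == pytest.approx(2 / 3)

    def test_constant_vector_excluded(self):
        z = np.vstack([np.arange(10.0), np.ones(10), np.arange(10.0) ** 2])
        panel = make_panel(z, genes=[f"g{i}" for i in range(10)])
        summ = response_correlation(panel, [f"g{i}" for i in range(10)],
                                    panel.perturbagens)
        assert summ.n_excluded == 2  # the two pairs touching the constant row
        assert summ.n_pairs == 1

    def test_null_vectors_rarely_correlate(self):
        rng = np.random.default_rng(17)
        z = rng.standard_normal((50, 100))
        panel = make_panel(z, genes=[f"g{i}" for i in range(100)])
        summ = response_correlation(panel, [f"g{i}" for i in range(100)],
                                    panel.perturbagens)
        assert summ.frac_above <= 0.01


class TestPanelValidation:
    def test_duplicate_perturbagens_rejected(self):
        z = pd.DataFrame(np.zeros((2, 3)), index=["a", "a"], columns=list("xyz"))
        with pytest.raises(ValueError):
            PerturbationPanel("c", "kd", z)

    def test_nonfinite_rejected(self):
        z = pd.DataFrame([[np.nan, 0.0]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError):
            PerturbationPanel("c", "kd", z)
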