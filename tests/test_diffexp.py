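import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusegrn import diffexp
from fusegrn.diffexp import (
    b_statistic,
    b_to_probability,
    compute_probabilities,
    fit_variance_prior,
    moderated_stats,
    supply_probabilities,
)
from fusegrn.io import ConditionDataset
from fusegrn.simulate import simulate_study, simulate_truth

from conftest import toy_condition


class TestBToProbability:
    def test_zero_log_odds_is_half(self):
        assert b_to_probability(0.0) == pytest.approx(0.5)

    def test_log3_gives_three_quarters(self):
        assert b_to_probability(np.log(3.0)) == pytest.approx(0.75)

    def test_large_b_saturates_without_overflow(self):
        assert b_to_probability(100.0) == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(b_to_probability(10_000.0))

    def test_strictly_increasing(self):
        b = np.linspace(-30, 30, 301)
        assert np.all(np.diff(b_to_probability(b)) > 0)


class TestBStatistic:
    def test_matches_t_density_ratio_oracle(self):
        # independent oracle: B is the log posterior odds
        # p*f1(t) / ((1-p)*f0(t)) with f0 the t_df density and f1 the
        # density of sqrt(r) * t_df (the DE component)
        df, v, v0, p = 7.0, 1.25, 3.0, 0.05
        r = (v + v0) / v
        t = np.array([-4.0, -1.3, 0.0, 0.2, 2.5, 6.0])
        f0 = stats.t.pdf(t, df)
        f1 = stats.t.pdf(t / np.sqrt(r), df) / np.sqrt(r)
        expected = np.log(p / (1 - p)) + np.log(f1) - np.log(f0)
        np.testing.assert_allclose(b_statistic(t, df, v, v0, p), expected,
                                   rtol=1e-10)

    def test_monotone_in_absolute_t(self):
        t = np.linspace(0, 12, 200)
        b = b_statistic(t, df=5.0, v=1.25, v0=2.0, prior_p=0.01)
        assert np.all(np.diff(b) > 0)
        np.testing.assert_allclose(
            b_statistic(-t, 5.0, 1.25, 2.0, 0.01), b, rtol=1e-12
        )


class TestModeratedStats:
    def _dataset(self, treat, ctrl, genes=None):
        genes = genes or [f"g{i + 1}" for i in range(len(treat))]
        tf = pd.DataFrame(np.asarray(treat, float), index=genes,
                          columns=[f"t{j + 1}" for j in range(np.shape(treat)[1])])
        cf = pd.DataFrame(np.asarray(ctrl, float), index=genes,
                          columns=[f"c{j + 1}" for j in range(np.shape(ctrl)[1])])
        return ConditionDataset("cond", tf, cf)

    def test_requires_two_control_columns(self):
        ds = self._dataset([[1.0, 2.0]], [[1.0]])
        with pytest.raises(ValueError, match="supply_probabilities"):
            moderated_stats(ds)

    def test_null_contrast_has_minimal_b(self):
        # gene 1's treatment equals its control mean -> contrast 0; with
        # equal variances its B is the smallest and pr below the prior level
        ctrl = np.array([[7.0, 8.0, 9.0], [7.0, 8.0, 9.0], [7.0, 8.0, 9.0],
                         [6.5, 8.0, 9.5], [7.5, 8.0, 8.5]])
        treat = np.array([[8.0], [9.5], [10.5], [9.0], [6.0]])
        ms = moderated_stats(self._dataset(treat, ctrl), prior_p=0.01)
        assert ms.contrast[0, 0] == pytest.approx(0.0)
        assert np.argmin(ms.b[:, 0]) == 0
        assert b_to_probability(ms.b[0, 0]) < 0.01

    def test_larger_contrast_gives_larger_b_at_equal_variance(self):
        ctrl = np.tile([7.0, 8.0, 9.0], (2, 1))
        treat = np.array([[11.0], [9.0]])  # |contrast| 3 vs 1
        ms = moderated_stats(self._dataset(treat, ctrl))
        assert ms.b[0, 0] > ms.b[1, 0]

    def test_matches_direct_posterior_odds_on_hand_set_hyperparameters(self):
        # hand-set hyperparameters: bypass estimation, evaluate the
        # posterior-odds closed form independently from the fitted pieces
        rng = np.random.default_rng(5)
        ctrl = rng.normal(8.0, 0.5, size=(5, 4))
        treat = rng.normal(8.0, 1.0, size=(5, 3))
        ds = self._dataset(treat, ctrl)
        ms = moderated_stats(ds, prior_p=0.02, v0=2.5)
        # independent recomputation from the dataset alone
        s2 = ctrl.var(axis=1, ddof=1)
        d = ctrl.shape[1] - 1
        s2_post = (ms.d0 * ms.s0_sq + d * s2) / (ms.d0 + d)
        v = 1.0 + 1.0 / ctrl.shape[1]
        tstat = (treat - ctrl.mean(axis=1)[:, None]) / np.sqrt(s2_post[:, None] * v)
        df = ms.d0 + d
        r = (v + 2.5) / v
        f0 = stats.t.pdf(tstat, df)
        f1 = stats.t.pdf(tstat / np.sqrt(r), df) / np.sqrt(r)
        expected = np.log(0.02 / 0.98) + np.log(f1) - np.log(f0)
        np.testing.assert_allclose(ms.b, expected, rtol=1e-8)

    def test_posterior_variance_between_prior_and_sample(self):
        ds = toy_condition(n_genes=50, n_times=3, n_control=5, seed=11)
        ms = moderated_stats(ds)
        lo = np.minimum(ms.s2, ms.s0_sq)
        hi = np.maximum(ms.s2, ms.s0_sq)
        assert np.all(ms.s2_post >= lo - 1e-12)
        assert np.all(ms.s2_post <= hi + 1e-12)

    def test_shift_equivariance(self):
        # adding a constant to a gene's treatment AND control leaves B unchanged
        ds = toy_condition(n_genes=6, n_times=4, n_control=4, seed=2)
        shifted = ConditionDataset(
            ds.name, ds.treatment + 5.0, ds.control + 5.0
        )
        a = moderated_stats(ds, v0=1.0)
        b = moderated_stats(shifted, v0=1.0)
        np.testing.assert_allclose(a.b, b.b, rtol=1e-9)


class TestVariancePriorRecovery:
    def test_hyperparameters_recovered_from_synthetic_variances(self):
        # s_g^2 ~ s0^2 * (d0/chi2_d0) * (chi2_d / d): scaled inv-chi-square
        # gene variances with known hyperparameters
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 6.0, 0.4, 3
        n_genes = 2000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n_genes)
        s2 = sigma2 * rng.chisquare(d, n_genes) / d
        d0_hat, s0_hat = fit_variance_prior(s2, float(d))
        assert abs(d0_hat - d0_true) / d0_true < 0.25
        assert abs(s0_hat - s0_true) / s0_true < 0.25


class TestComputeProbabilities:
    def test_structure_one_matrix_per_condition(self, small_study):
        probs = compute_probabilities(small_study)
        assert len(probs) == small_study.k
        for pr, cond in zip(probs, small_study.conditions):
            assert pr.values.shape == cond.treatment.shape
            assert pr.genes == small_study.genes

    def test_perturbed_genes_score_higher(self):
        truth = simulate_truth(seed=21)
        study = simulate_study(truth, seed=22)
        pr = compute_probabilities(study)[0]
        perturbed = truth.perturbed[0]
        quiet = [g for g in truth.tf_ids if g not in perturbed]
        mean_pert = np.mean([pr.profile(g).mean() for g in perturbed])
        mean_quiet = np.mean([pr.profile(g).mean() for g in quiet])
        assert mean_pert > mean_quiet

    def test_global_null_probabilities_below_half(self):
        # treatment identical to a control replicate: no real signal
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        ctrl = pd.DataFrame(rng.normal(8, 0.5, size=(40, 4)), index=genes,
                            columns=list("abcd"))
        treat = ctrl.iloc[:, :2].copy()
        treat.columns = ["t1", "t2"]
        ds = ConditionDataset("null", treat, ctrl)
        from fusegrn.diffexp import probabilities_for

        pr = probabilities_for(moderated_stats(ds, prior_p=0.01))
        assert (pr.values.to_numpy() < 0.5).all()


class TestSupplyProbabilities:
    def test_accepts_extremes_and_round_trips(self, tmp_path):
        from conftest import probability_matrix

        pr = probability_matrix([[0.0, 1.0], [1.0, 0.0]])
        diffexp.write_probabilities(pr, tmp_path / "p.tsv")
        back = supply_probabilities(tmp_path / "p.tsv")
        np.testing.assert_allclose(back.values, pr.values, atol=1e-12)

    def test_out_of_range_value_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("gene\tt1\ng1\t1.2\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            supply_probabilities(tmp_path / "p.tsv")
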